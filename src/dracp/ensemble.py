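"""Random relevance vector machines (RRVM): a voting ensemble of RVMs.

Borrowing the random-subspace idea from random forests: each round draws a
random subset of feature columns and a random subset of samples (both
without replacement within the round; everything is put back between
rounds), fits one RVM on that slice, and the final classifier is the
majority vote of all members — 101 by default, odd so a vote can never tie.
The fraction of members voting positive serves as the continuous score for
ROC/PR analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rvm import KernelSpec, RVMModel, classify_rvm, fit_rvm

#: Named subset presets: "text" draws 5 features / 100 samples per round,
#: "table3" draws 10 features / 50 samples.
SUBSET_PRESETS = {"text": (5, 100), "table3": (10, 50)}


@dataclass(frozen=True)
class EnsembleConfig:
    """Shape of the RRVM ensemble and its per-round subset draws."""

    n_models: int = 101
    subset_mode: str = "text"
    features_per_model: int | None = None
    samples_per_model: int | None = None
    seed: int = 0
    max_resample_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.n_models % 2 == 0:
            raise ValueError("n_models must be odd so the vote cannot tie")
        if self.subset_mode not in SUBSET_PRESETS:
            raise ValueError(
                f"subset_mode must be one of {sorted(SUBSET_PRESETS)}"
            )

    def resolved_counts(self) -> tuple[int, int]:
        """(features_per_model, samples_per_model), preset-backed."""
        f, s = SUBSET_PRESETS[self.subset_mode]
        return (
            self.features_per_model if self.features_per_model is not None else f,
            self.samples_per_model if self.samples_per_model is not None else s,
        )


@dataclass
class EnsembleModel:
    """101 (by default) RVMs with their per-member feature/sample subsets."""

    members: list[tuple[RVMModel, np.ndarray, np.ndarray]]
    config: EnsembleConfig
    n_features_total: int

    @property
    def n_models(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_models": self.config.n_models,
                "subset_mode": self.config.subset_mode,
                "features_per_model": self.config.features_per_model,
                "samples_per_model": self.config.samples_per_model,
                "seed": self.config.seed,
            },
            "n_features_total": int(self.n_features_total),
            "members": [
                {
                    "model": m.to_dict(),
                    "feature_idx": f.tolist(),
                    "sample_idx": s.tolist(),
                }
                for m, f, s in self.members
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        members = [
            (
                RVMModel.from_dict(e["model"]),
                np.array(e["feature_idx"], dtype=int),
                np.array(e["sample_idx"], dtype=int),
            )
            for e in d["members"]
        ]
        return cls(
            members=members,
            config=EnsembleConfig(**d["config"]),
            n_features_total=int(d["n_features_total"]),
        )


def draw_subsets(
    config: EnsembleConfig,
    n_features_total: int,
    n_samples_total: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One round's feature and sample index draws, each without replacement."""
    n_feat, n_samp = config.resolved_counts()
    if n_feat > n_features_total:
        raise ValueError(
            f"features_per_model={n_feat} exceeds available {n_features_total}"
        )
    if n_samp > n_samples_total:
        raise ValueError(
            f"samples_per_model={n_samp} exceeds available {n_samples_total}"
        )
    feat = np.sort(rng.choice(n_features_total, size=n_feat, replace=False))
    samp = np.sort(rng.choice(n_samples_total, size=n_samp, replace=False))
    return feat, samp


def fit_ensemble(
    X: np.ndarray,
    t: np.ndarray,
    config: EnsembleConfig = EnsembleConfig(),
    kernel: KernelSpec = KernelSpec(),
    max_iter: int = 100,
    tol: float = 1e-3,
) -> EnsembleModel:
    """Fit ``n_models`` RVMs on independent random feature/sample slices.

    A round whose sample draw contains a single class is redrawn (up to
    ``config.max_resample_retries`` times) since a one-class regression
    target carries no decision boundary.  Deterministic given ``config.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=int).ravel()
    if set(np.unique(t)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_samples, n_features = X.shape
    rng = np.random.default_rng(config.seed)
    members: list[tuple[RVMModel, np.ndarray, np.ndarray]] = []
    for _ in range(config.n_models):
        for _attempt in range(config.max_resample_retries + 1):
            feat, samp = draw_subsets(config, n_features, n_samples, rng)
            if np.unique(t[samp]).size == 2:
                break
        else:
            raise RuntimeError(
                "could not draw a two-class sample subset after "
                f"{config.max_resample_retries} retries"
            )
        model = fit_rvm(
            X[np.ix_(samp, feat)], t[samp].astype(float), kernel=kernel,
            max_iter=max_iter, tol=tol,
        )
        members.append((model, feat, samp))
    return EnsembleModel(members=members, config=config, n_features_total=n_features)


def predict_ensemble(
    model: EnsembleModel, Xq: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and vote-fraction scores for the queries.

    Each member classifies its own feature projection of the queries; the
    score is the fraction of members voting positive, so thresholding the
    score at 0.5 reproduces the majority label exactly (n_models is odd).
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if Xq.shape[1] != model.n_features_total:
        raise ValueError(
            f"query has {Xq.shape[1]} features; ensemble was trained on "
            f"{model.n_features_total}"
        )
    votes = np.zeros(Xq.shape[0])
    for rvm, feat, _ in model.members:
        labels, _ = classify_rvm(rvm, Xq[:, feat])
        votes += labels
    scores = votes / model.n_models
    return (scores >= 0.5).astype(int), scores
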