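"""Pipeline configuration: one YAML file, one master seed.

Every tunable hyperparameter of the pipeline lives in :class:`PipelineConfig`
with documented defaults.  A single master seed drives all randomness;
component seeds (synthetic generator, DBN, ensemble, CV splitter, and each
CV fold) are derived from it by fixed named offsets, so one integer fully
reproduces a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .ensemble import EnsembleConfig
from .io import SyntheticSpec
from .rvm import KernelSpec

#: Fixed offsets for deriving component seeds from the master seed.
SEED_OFFSETS = {
    "synthetic": 101,
    "dbn": 211,
    "ensemble": 307,
    "cv": 401,
    "fold_stride": 1000,
}


def derive_seed(master_seed: int, component: str, fold: int = 0) -> int:
    """Deterministic per-component (and per-fold) seed below 2^31."""
    if component not in SEED_OFFSETS:
        raise KeyError(f"unknown seed component {component!r}")
    return (
        int(master_seed) + SEED_OFFSETS[component] + fold * SEED_OFFSETS["fold_stride"]
    ) % (2**31)


@dataclass(frozen=True)
class DBNConfig:
    layer_sizes: tuple[int, ...] = (56, 32, 16)
    epochs: int = 200
    learning_rate: float = 0.5
    cd_steps: int = 1
    batch_size: int = 10

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("layer_sizes needs at least [visible, hidden]")
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")


@dataclass(frozen=True)
class RVMConfig:
    max_iter: int = 100
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, under one master seed."""

    seed: int = 0
    use_dbn: bool = True
    ambiguous: str = "reject"
    dbn: DBNConfig = field(default_factory=DBNConfig)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    rvm: RVMConfig = field(default_factory=RVMConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dbn"]["layer_sizes"] = list(self.dbn.layer_sizes)
        d["synthetic"]["length_range"] = list(self.synthetic.length_range)
        d["synthetic"]["pos_group_weights"] = list(self.synthetic.pos_group_weights)
        d["synthetic"]["neg_group_weights"] = list(self.synthetic.neg_group_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {
            "seed", "use_dbn", "ambiguous", "dbn", "kernel", "rvm",
            "ensemble", "cv", "synthetic",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")

        def sub(key, cls_, tuple_keys=()):
            block = dict(d.get(key, {}))
            bad = set(block) - {f.name for f in cls_.__dataclass_fields__.values()}
            if bad:
                raise ValueError(f"unknown key(s) in {key!r}: {sorted(bad)}")
            for tk in tuple_keys:
                if tk in block:
                    block[tk] = tuple(block[tk])
            return cls_(**block)

        return cls(
            seed=int(d.get("seed", 0)),
            use_dbn=bool(d.get("use_dbn", True)),
            ambiguous=str(d.get("ambiguous", "reject")),
            dbn=sub("dbn", DBNConfig, ("layer_sizes",)),
            kernel=sub("kernel", KernelSpec),
            rvm=sub("rvm", RVMConfig),
            ensemble=sub("ensemble", EnsembleConfig),
            cv=sub("cv", CVConfig),
            synthetic=sub(
                "synthetic",
                SyntheticSpec,
                ("length_range", "pos_group_weights", "neg_group_weights"),
            ),
        )


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; ``None`` yields the documented defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
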