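"""Versioned JSON model bundles.

A bundle stores a trained pipeline (optional DBN encoder + RVM ensemble)
together with the config that produced it.  JSON with sorted keys and
full-precision floats keeps bundles diffable and makes identical runs
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from .config import PipelineConfig
from .dbn import DBNModel
from .ensemble import EnsembleModel

BUNDLE_FORMAT = "dracp-bundle"
BUNDLE_VERSION = 1


class BundleError(ValueError):
    pass


def save_bundle(
    path: str | Path,
    ensemble: EnsembleModel,
    dbn: DBNModel | None,
    config: PipelineConfig,
) -> None:
    payload = {
        "format": BUNDLE_FORMAT,
        "version": BUNDLE_VERSION,
        "config": config.to_dict(),
        "dbn": dbn.to_dict() if dbn is not None else None,
        "ensemble": ensemble.to_dict(),
        "input_dim": dbn.n_input if dbn is not None else ensemble.n_features_total,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_bundle(
    path: str | Path,
) -> tuple[EnsembleModel, DBNModel | None, PipelineConfig, int]:
    """Load (ensemble, dbn-or-None, config, expected feature dimension)."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise BundleError(f"{path}: not a valid bundle ({e})") from e
    if payload.get("format") != BUNDLE_FORMAT:
        raise BundleError(f"{path}: not a {BUNDLE_FORMAT} file")
    if payload.get("version") != BUNDLE_VERSION:
        raise BundleError(
            f"{path}: bundle version {payload.get('version')} is not supported "
            f"(expected {BUNDLE_VERSION})"
        )
    dbn = DBNModel.from_dict(payload["dbn"]) if payload["dbn"] is not None else None
    ensemble = EnsembleModel.from_dict(payload["ensemble"])
    config = PipelineConfig.from_dict(payload["config"])
    return ensemble, dbn, config, int(payload["input_dim"])
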