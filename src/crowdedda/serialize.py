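"""Text serialization of fitted models (diffable, full-precision JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ensemble import EnsembleParams, WeightVector


def ensemble_to_json(ens: EnsembleParams, path: str | Path | None = None) -> str:
    """Serialize stacked parameters to a JSON string (and optionally a file).

    Floats use repr round-tripping, so reloading reproduces predictions bit
    for bit.
    """
    payload = {
        "format": "crowdedda-ensemble",
        "version": 1,
        "tau": ens.tau.tolist(),
        "means": ens.means.tolist(),
        "covariances": ens.covariances.tolist(),
        "weights": {
            "w": ens.weights.w.tolist(),
            "s": None if ens.weights.s is None else ens.weights.s.tolist(),
            "strategy": ens.weights.strategy,
        },
        "source_models": list(ens.source_models),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def ensemble_from_json(source: str | Path) -> EnsembleParams:
    """Load stacked parameters from a JSON file path or JSON string."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str)
                                    and not source.lstrip().startswith("{")):
        text = Path(source).read_text()
    payload = json.loads(text)
    if payload.get("format") != "crowdedda-ensemble":
        raise ValueError("not a serialized ensemble model")
    wv = WeightVector(
        w=np.asarray(payload["weights"]["w"], dtype=float),
        s=(None if payload["weights"]["s"] is None
           else np.asarray(payload["weights"]["s"], dtype=float)),
        strategy=payload["weights"]["strategy"],
    )
    return EnsembleParams(
        tau=np.asarray(payload["tau"], dtype=float),
        means=np.asarray(payload["means"], dtype=float),
        covariances=np.asarray(payload["covariances"], dtype=float),
        weights=wv,
        source_models=list(payload["source_models"]),
    )
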