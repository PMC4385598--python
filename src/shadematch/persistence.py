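"""Model persistence: JSON round-trip of a fitted model.

The file stores the network structure, the four weight blocks
(row-major), the input normalizer, the training profile and the seed,
which is everything needed to reload the model and predict.
"""

from __future__ import annotations

import json
from pathlib import Path

from .data import Normalizer
from .network import NetworkConfig, NetworkWeights
from .pipeline import FittedModel

FORMAT_VERSION = 1


def save_model(model: FittedModel, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "config": {
            "n_in": model.cfg.n_in,
            "n_hidden": model.cfg.n_hidden,
            "n_out": model.cfg.n_out,
            "activation": model.cfg.activation.value,
            "lambda_factor": model.cfg.lambda_factor,
        },
        "weights": {
            "W": model.weights.W.tolist(),
            "V": model.weights.V.tolist(),
            "theta_hidden": model.weights.theta_hidden.tolist(),
            "theta_out": model.weights.theta_out.tolist(),
        },
        "normalizer": model.normalizer.to_dict(),
        "profile": model.profile,
        "seed": model.seed,
        "metric_as_printed": model.metric_as_printed,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path: str | Path) -> FittedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {doc.get('format_version')}")
    c = doc["config"]
    cfg = NetworkConfig(
        n_in=c["n_in"],
        n_hidden=c["n_hidden"],
        n_out=c["n_out"],
        activation=c["activation"],
        lambda_factor=c["lambda_factor"],
    )
    wdoc = doc["weights"]
    weights = NetworkWeights(
        wdoc["W"], wdoc["V"], wdoc["theta_hidden"], wdoc["theta_out"]
    )
    weights.validate(cfg)
    return FittedModel(
        cfg=cfg,
        weights=weights,
        normalizer=Normalizer.from_dict(doc["normalizer"]),
        profile=doc["profile"],
        seed=doc["seed"],
        metric_as_printed=doc["metric_as_printed"],
    )
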