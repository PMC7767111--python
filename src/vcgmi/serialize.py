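"""Model persistence: one ``.npz`` container with a JSON metadata entry."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from ._nn import DenseNet
from .classification import ClassifierConfig, ClassifierModel
from .vcg_synthesis import LSTMLayerParams, SynthesizerConfig, SynthesizerModel

__all__ = ["save_model", "load_model"]


def save_model(model, path: str) -> None:
    """Serialize a synthesizer or classifier model to ``path`` (.npz)."""
    arrays: dict[str, np.ndarray] = {}
    if isinstance(model, SynthesizerModel):
        meta = {
            "kind": "synthesizer",
            "config": asdict(model.config),
            "x_mean": model.x_mean,
            "x_std": model.x_std,
            "sampling_rate": model.sampling_rate,
            "n_layers": len(model.layers),
        }
        for k, layer in enumerate(model.layers):
            arrays[f"layer{k}_Wx"] = layer.Wx
            arrays[f"layer{k}_Wh"] = layer.Wh
            arrays[f"layer{k}_b"] = layer.b
        arrays["proj_W"] = model.proj_W
        arrays["proj_b"] = model.proj_b
        arrays["y_mean"] = model.y_mean
        arrays["y_std"] = model.y_std
    elif isinstance(model, ClassifierModel):
        meta = {
            "kind": "classifier",
            "config": asdict(model.config),
            "labels": list(model.labels),
            "sizes": list(model.net.sizes),
            "output": model.net.output,
            "n_layers": len(model.net.weights),
        }
        for k, (W, b) in enumerate(zip(model.net.weights, model.net.biases)):
            arrays[f"W{k}"] = W
            arrays[f"b{k}"] = b
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["kind"] == "synthesizer":
            config = SynthesizerConfig(**meta["config"])
            layers = [
                LSTMLayerParams(
                    Wx=data[f"layer{k}_Wx"], Wh=data[f"layer{k}_Wh"], b=data[f"layer{k}_b"]
                )
                for k in range(meta["n_layers"])
            ]
            return SynthesizerModel(
                layers=layers,
                proj_W=data["proj_W"],
                proj_b=data["proj_b"],
                config=config,
                x_mean=meta["x_mean"],
                x_std=meta["x_std"],
                y_mean=data["y_mean"],
                y_std=data["y_std"],
                sampling_rate=meta["sampling_rate"],
            )
        if meta["kind"] == "classifier":
            cfg_dict = dict(meta["config"])
            cfg_dict["hidden"] = tuple(cfg_dict["hidden"])
            config = ClassifierConfig(**cfg_dict)
            net = DenseNet(
                tuple(meta["sizes"]),
                output=meta["output"],
                weights=[data[f"W{k}"] for k in range(meta["n_layers"])],
                biases=[data[f"b{k}"] for k in range(meta["n_layers"])],
            )
            return ClassifierModel(net, config, tuple(meta["labels"]))
    raise ValueError(f"unknown model kind in {path}")
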