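"""A plain sequential container with checkpointing."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layers import Layer


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        np.savez(Path(path), **arrays)

    def load(self, path: str | Path) -> None:
        with np.load(Path(path)) as data:
            params = self.params()
            if len(data.files) != len(params):
                raise ValueError("checkpoint does not match this architecture")
            for i, p in enumerate(params):
                arr = data[f"p{i}"]
                if arr.shape != p.shape:
                    raise ValueError(f"parameter {i}: shape {arr.shape} != {p.shape}")
                p[...] = arr
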