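"""TCTNet: encoder + decoder assembly, forward pass, checkpointing."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import ModelConfig
from .decoder import Decoder
from .encoder import Encoder
from .errors import ShapeError

__all__ = ["TCTNet", "save_checkpoint", "load_checkpoint"]


class TCTNet:
    """Hybrid Transformer-CNN 3D segmentation network.

    Input: a C1 x H x W x D patch with H, W, D divisible by 16 (which also
    satisfies the published reduction schedule, whose keys/values live at
    1/16 of the input). Output: per-voxel class probabilities, C2 x H x W x D.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dtype = cfg.np_dtype
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg.in_channels, cfg.encoder, rng, dtype=dtype)
        self.decoder = Decoder(cfg.encoder.stage_widths, cfg.decoder, rng, dtype=dtype)

    # -- parameter plumbing -------------------------------------------------
    def named_parameters(self):
        yield from self.encoder.named_parameters("encoder.")
        yield from self.decoder.named_parameters("decoder.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state, strict: bool = True):
        own = dict(self.named_parameters())
        skipped = []
        for name, param in own.items():
            if name in state and state[name].shape == param.data.shape:
                param.data = np.asarray(state[name], dtype=param.data.dtype).copy()
            else:
                skipped.append(name)
        if strict and skipped:
            raise KeyError(f"missing or mismatched parameters: {skipped}")
        return skipped

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward ------------------------------------------------------------
    def forward(self, patch: Tensor | np.ndarray) -> Tensor:
        x = patch if isinstance(patch, Tensor) else Tensor(
            np.asarray(patch, dtype=self.cfg.np_dtype)
        )
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ShapeError(
                f"expected {self.cfg.in_channels} x H x W x D input, got {x.shape}"
            )
        pyramid = self.encoder(x)
        return self.decoder(pyramid)

    __call__ = forward

    def predict(self, patch: np.ndarray) -> np.ndarray:
        """Tape-free forward pass returning a probability array."""
        with ad.no_grad():
            return self.forward(patch).data


def save_checkpoint(path: str | Path, model: TCTNet, extra: dict | None = None) -> None:
    """Persist weights + config (json-embedded) in a single .npz archive."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps({"model": model.cfg.to_dict(), "extra": extra or {}}).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[TCTNet, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["config_json"].tobytes()).decode())
        state = {
            k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")
        }
    model = TCTNet(ModelConfig.from_dict(meta["model"]))
    model.load_state_dict(state)
    return model, meta.get("extra", {})
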