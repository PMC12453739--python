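"""Checkpoint persistence.

A checkpoint is a ``.npz`` archive holding every weight array plus a JSON
metadata entry (format version, model config, train config, seed). Loading
rebuilds the network from the stored config and restores weights exactly,
so eval-mode logits round-trip bit-identically; a checkpoint saved under a
different architecture shape is refused with an explicit error.
"""

from __future__ import annotations

import json

import numpy as np

from .model import DiliClassifier, ModelConfig
from .train import TrainConfig

__all__ = ["CheckpointError", "save_checkpoint", "load_checkpoint", "FORMAT_VERSION"]

FORMAT_VERSION = 1


class CheckpointError(RuntimeError):
    """Raised for unreadable, corrupt, or incompatible checkpoint files."""


def save_checkpoint(model: DiliClassifier, tcfg: TrainConfig, path) -> None:
    meta = {"format_version": FORMAT_VERSION,
            "model_config": model.cfg.to_dict(),
            "train_config": tcfg.to_dict()}
    arrays = {f"w::{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expected_config: ModelConfig | None = None):
    """Load ``(model, train_config)``; optionally validate against an expected config."""
    try:
        with np.load(path) as archive:
            if "__meta__" not in archive:
                raise CheckpointError(f"{path} is not a model checkpoint")
            meta = json.loads(archive["__meta__"].tobytes().decode())
            state = {k[3:]: archive[k] for k in archive.files if k.startswith("w::")}
    except CheckpointError:
        raise
    except Exception as exc:  # zipfile/IO/JSON errors: corrupt or truncated file
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise CheckpointError(f"unsupported checkpoint format version {meta.get('format_version')}")
    cfg = ModelConfig(**meta["model_config"])
    if expected_config is not None and expected_config.to_dict() != cfg.to_dict():
        raise CheckpointError("checkpoint configuration contradicts the expected model config")
    model = DiliClassifier(cfg)
    try:
        model.load_state_dict(state)
    except ValueError as exc:
        raise CheckpointError(str(exc)) from exc
    tcfg = TrainConfig(**meta["train_config"])
    return model, tcfg
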