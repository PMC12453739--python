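"""Synthetic DILI-style datasets with planted, recoverable signal.

Two modes:

* ``fingerprint`` — draws 2,048-bit vectors directly: sparse background
  bits (density 0.05, roughly the sparsity of real Morgan fingerprints)
  plus a fixed set of informative bits that are frequent in positives and
  rare in negatives. Fast; exercises the network path.
* ``smiles`` — assembles valid aromatic SMILES from a small fragment
  grammar; positives carry a nitroaromatic structural-alert fragment.
  Exercises parsing, canonicalization and fingerprinting.

Labels are drawn at the study's 56:44 positive:negative balance before an
optional symmetric label flip emulating annotation noise. Generation is a
pure function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .featurize import Compound, N_BITS

__all__ = ["SynthConfig", "generate_fingerprint_dataset", "generate_smiles_dataset",
           "write_dataset_csv", "ALERT_SMARTS"]

# nitroaromatic motif used as the planted structural alert in SMILES mode
ALERT_SMILES_PREFIX = "O=[N+]([O-])"
ALERT_SMARTS = "[O-][N+](=O)c"

_RING_TEMPLATES = [
    "c1ccc({r})cc1",          # para-substituted benzene
    "c1cc({r})ccc1C",         # toluene core
    "c1ccc2cc({r})ccc2c1",    # naphthalene
]
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "CC(C)C", "CCO", "CCN", "COC", "CCOC",
    "C(=O)C", "C(=O)OC", "C(=O)NC", "CCl", "CBr", "C#N", "CCS", "CF",
    "CC(=O)O", "CN(C)C", "CCCO",
]
_PREFIXES = ["", "C", "CC", "CCC", "OC", "NC", "CCO", "ClC", "CN", "CCN"]


@dataclass
class SynthConfig:
    """Generation settings; defaults mirror the curated-dataset conditions."""

    n: int = 2000
    mode: str = "fingerprint"  # or "smiles"
    n_informative_bits: int = 20
    label_flip_prob: float = 0.0
    positive_fraction: float = 0.56
    background_density: float = 0.05
    p_informative_pos: float = 0.9
    p_informative_neg: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n < 20:
            raise ValueError("n must be at least 20")
        if not 0.0 <= self.label_flip_prob < 0.5:
            raise ValueError("label_flip_prob must lie in [0, 0.5)")
        if self.mode not in ("fingerprint", "smiles"):
            raise ValueError("mode must be 'fingerprint' or 'smiles'")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_labels(cfg: SynthConfig, rng: np.random.Generator):
    true_labels = (rng.random(cfg.n) < cfg.positive_fraction).astype(int)
    flips = rng.random(cfg.n) < cfg.label_flip_prob
    observed = np.where(flips, 1 - true_labels, true_labels)
    return true_labels, observed


def generate_fingerprint_dataset(cfg: SynthConfig):
    """Return ``(X, y, truth)``: (n, 2048) uint8 bits, noisy labels, and the
    generative ground truth (informative bit indices, clean labels)."""
    if cfg.mode != "fingerprint":
        raise ValueError("config mode is not 'fingerprint'")
    rng = np.random.default_rng(cfg.seed)
    info_bits = rng.choice(N_BITS, size=cfg.n_informative_bits, replace=False)
    true_labels, observed = _draw_labels(cfg, rng)
    x = (rng.random((cfg.n, N_BITS)) < cfg.background_density).astype(np.uint8)
    p_info = np.where(true_labels[:, None] == 1, cfg.p_informative_pos, cfg.p_informative_neg)
    x[:, info_bits] = (rng.random((cfg.n, cfg.n_informative_bits)) < p_info).astype(np.uint8)
    truth = {"informative_bits": sorted(int(b) for b in info_bits),
             "true_labels": true_labels.tolist(), "seed": cfg.seed}
    return x, observed, truth


def generate_smiles_dataset(cfg: SynthConfig):
    """Return ``(compounds, truth)``; positives (pre-noise) carry the nitroaromatic alert."""
    if cfg.mode != "smiles":
        raise ValueError("config mode is not 'smiles'")
    rng = np.random.default_rng(cfg.seed)
    true_labels, observed = _draw_labels(cfg, rng)
    compounds = []
    for i in range(cfg.n):
        ring = _RING_TEMPLATES[rng.integers(len(_RING_TEMPLATES))]
        sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
        core = ring.format(r=sub)
        smiles = (ALERT_SMILES_PREFIX + core) if true_labels[i] == 1 else (prefix + core)
        compounds.append(Compound(id=str(i), smiles=smiles, label=int(observed[i])))
    truth = {"alert_smiles_prefix": ALERT_SMILES_PREFIX, "alert_smarts": ALERT_SMARTS,
             "true_labels": true_labels.tolist(), "seed": cfg.seed}
    return compounds, truth


def oracle_scores(x: np.ndarray, informative_bits) -> np.ndarray:
    """Score by the known generative rule: count of set informative bits."""
    return np.asarray(x)[:, list(informative_bits)].sum(axis=1).astype(float)


def write_dataset_csv(cfg: SynthConfig, path, truth_path=None) -> None:
    """Emit the dataset in the loader's CSV dialect plus a sidecar truth JSON.

    SMILES mode writes ``id,smiles,label``; fingerprint mode writes
    ``id,fingerprint,label`` with the 2,048 bits packed as a 0/1 string.
    """
    if cfg.mode == "smiles":
        compounds, truth = generate_smiles_dataset(cfg)
        frame = pd.DataFrame({"id": [c.id for c in compounds],
                              "smiles": [c.smiles for c in compounds],
                              "label": [c.label for c in compounds]})
    else:
        x, y, truth = generate_fingerprint_dataset(cfg)
        frame = pd.DataFrame({"id": [str(i) for i in range(cfg.n)],
                              "fingerprint": ["".join(map(str, row)) for row in x],
                              "label": y})
    frame.to_csv(path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump({"config": cfg.to_dict(), **truth}, fh)


def read_fingerprint_csv(path):
    """Inverse of fingerprint-mode :func:`write_dataset_csv`."""
    frame = pd.read_csv(path, dtype={"fingerprint": str})
    x = np.array([[int(ch) for ch in s] for s in frame["fingerprint"]], dtype=np.uint8)
    y = frame["label"].to_numpy(dtype=int)
    return x, y
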