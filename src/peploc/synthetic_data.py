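"""Synthetic labeled EST-peptide datasets with controllable class signal.

Each class gets a residue distribution drawn from a symmetric Dirichlet,
mixed with the uniform background as
``signal_strength * class_dist + (1 - signal_strength) * uniform``.
Sequence lengths follow a truncated normal (mean 200, SD 60, bounds
[50, 600] residues — the EST length survey of ~600 +/- 180 nt divided by
three).  Optional per-class tetra-peptide motifs can be planted at a given
per-position insertion rate, providing a signal channel only order >= 4
composition features can exploit.

Also generates a syntactically valid physicochemical index (AAindex1) file
with pseudo-random values, 494 entries by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from peploc.sequence_io import AMINO_ACIDS, COMPARTMENTS, PeptideRecord

_DEFAULT_CLASSES = ("chl", "cyt", "mit")


@dataclass
class SyntheticConfig:
    """Configuration for one synthetic dataset."""

    classes: tuple[str, ...] = _DEFAULT_CLASSES
    n_per_class: int = 20
    length_mean: float = 200.0
    length_sd: float = 60.0
    length_min: int = 50
    length_max: int = 600
    signal_strength: float = 0.5
    dirichlet_concentration: float = 0.5
    planted_motifs: Mapping[str, Sequence[str]] = field(default_factory=dict)
    motif_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartment code(s) {sorted(unknown)}")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate classes")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.length_min <= 0 or self.length_min >= self.length_max:
            raise ValueError("length truncation bounds must satisfy 0 < min < max")
        if not 0.0 <= self.motif_rate <= 1.0:
            raise ValueError("motif_rate must lie in [0, 1]")


def class_distributions(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """The mixed per-class residue distributions the generator samples from."""
    rng = np.random.default_rng(cfg.seed)
    uniform = np.full(20, 1 / 20)
    out = {}
    for cls in cfg.classes:
        class_dist = rng.dirichlet(np.full(20, cfg.dirichlet_concentration))
        out[cls] = cfg.signal_strength * class_dist + (1 - cfg.signal_strength) * uniform
    return out


def _sample_length(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    # rejection-sampled truncated normal; bounds are a few SD out, so cheap
    while True:
        length = rng.normal(cfg.length_mean, cfg.length_sd)
        if cfg.length_min <= length <= cfg.length_max:
            return int(round(length))


def generate_dataset(cfg: SyntheticConfig) -> list[PeptideRecord]:
    """Generate ``len(classes) * n_per_class`` labeled synthetic records.

    Fully deterministic for a fixed ``cfg.seed``; records are tagged
    ``source="synthetic"`` with ids ``syn_<class>_<index>``.
    """
    rng = np.random.default_rng(cfg.seed)
    # draw class distributions with the same stream layout as class_distributions
    dists = class_distributions(cfg)
    # burn the dirichlet draws from this rng too, so dists and sampling decouple
    for _ in cfg.classes:
        rng.dirichlet(np.full(20, cfg.dirichlet_concentration))

    alphabet = np.array(list(AMINO_ACIDS))
    records: list[PeptideRecord] = []
    for cls in cfg.classes:
        dist = dists[cls]
        motifs = list(cfg.planted_motifs.get(cls, ()))
        for i in range(cfg.n_per_class):
            length = _sample_length(cfg, rng)
            seq = "".join(rng.choice(alphabet, size=length, p=dist))
            if motifs and cfg.motif_rate > 0:
                seq = _plant_motifs(seq, motifs, cfg.motif_rate, rng)
            records.append(PeptideRecord(
                id=f"syn_{cls}_{i}", sequence=seq, label=cls, source="synthetic",
            ))
    return records


def _plant_motifs(seq: str, motifs: Sequence[str], rate: float,
                  rng: np.random.Generator) -> str:
    """Overwrite the sequence with motifs at ~rate per candidate position."""
    chars = list(seq)
    pos = 0
    while pos <= len(chars) - 4:
        if rng.random() < rate:
            motif = motifs[int(rng.integers(len(motifs)))]
            chars[pos:pos + len(motif)] = list(motif)
            pos += len(motif)
        else:
            pos += 1
    return "".join(chars[:len(seq)])


def generate_aaindex_fixture(
    path: str | Path,
    n_indices: int = 494,
    seed: int = 0,
) -> Path:
    """Write a syntactically valid AAindex1 flat file with random values.

    Entries are named ``SYNIX001`` ... and carry reproducible pseudo-random
    values in [-3, 3]; byte-identical for a fixed seed.
    """
    if n_indices < 1:
        raise ValueError("need at least one index")
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    for i in range(1, n_indices + 1):
        values = np.round(rng.uniform(-3.0, 3.0, size=20), 3)
        lines.append(f"H SYNIX{i:03d}")
        lines.append(f"D Synthetic physicochemical index {i}")
        lines.append("I    A/L     R/K     N/M     D/F     C/P     "
                     "Q/S     E/T     G/W     H/Y     I/V")
        row1 = "".join(f"{v:8.3f}" for v in values[:10])
        row2 = "".join(f"{v:8.3f}" for v in values[10:])
        lines.append(" " + row1)
        lines.append(" " + row2)
        lines.append("//")
    out = Path(path)
    out.write_text("\n".join(lines) + "\n")
    return out
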