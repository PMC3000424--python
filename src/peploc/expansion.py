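"""Training-set expansion: fragment full-length proteins into EST-like
pieces and reduce redundancy by greedy identity clustering.

Fragmentation follows a piecewise rule on protein length L:
L < 200 -> unchanged; 200 <= L <= 400 -> one N-terminal and one C-terminal
fragment; L > 400 -> an additional central fragment.  Fragment lengths are
drawn uniformly from 140-260 residues (the EST length survey: ~600 +/- 180 nt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from peploc.sequence_io import PeptideRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentationPolicy:
    """Length thresholds and anchor offsets for EST-like fragmentation."""

    min_len: int = 140
    max_len: int = 260
    short_threshold: int = 200
    long_threshold: int = 400
    nterm_anchor_window: int = 80

    def __post_init__(self) -> None:
        if not self.min_len < self.max_len:
            raise ValueError("min_len must be < max_len")
        if not self.short_threshold < self.long_threshold:
            raise ValueError("thresholds must be ordered short < long")


def _clip(value: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, value))


def fragment_protein(
    rec: PeptideRecord,
    policy: FragmentationPolicy = FragmentationPolicy(),
    rng: Optional[np.random.Generator] = None,
) -> list[PeptideRecord]:
    """Fragment one protein into 1, 2 or 3 EST-like pieces.

    The N-terminal fragment starts at a uniform-random offset within
    ``nterm_anchor_window`` residues downstream of the first methionine
    (position 0 if there is none); the C-terminal fragment ends at the last
    residue with a uniform-random length; the central fragment (only for
    long proteins) starts after the first 80 residues but before the middle.
    All endpoints are clipped to the available sequence; labels are
    inherited and ids suffixed ``_N`` / ``_M`` / ``_C``.
    """
    if rng is None:
        rng = np.random.default_rng()
    seq = rec.sequence
    L = len(seq)
    if L < policy.short_threshold:
        return [rec]

    def rand_len() -> int:
        return int(rng.integers(policy.min_len, policy.max_len + 1))

    fragments: list[PeptideRecord] = []

    # N-terminal: start within the anchor window downstream of the first M
    first_met = seq.find("M")
    anchor = first_met if first_met >= 0 else 0
    start_hi = _clip(anchor + policy.nterm_anchor_window, anchor, L - policy.min_len)
    start = int(rng.integers(anchor, start_hi + 1)) if start_hi > anchor else anchor
    end = _clip(start + rand_len(), start + 1, L)
    fragments.append(replace(rec, id=f"{rec.id}_N", sequence=seq[start:end],
                             source="fragment"))

    if L > policy.long_threshold:
        # central: start after the first 80 residues, before the middle
        # (0-based start index in [80, mid-2] => 1-based residue in (80, mid))
        mid = L // 2
        lo = policy.nterm_anchor_window
        hi = max(lo, mid - 2)
        c_start = int(rng.integers(lo, hi + 1))
        c_end = _clip(c_start + rand_len(), c_start + 1, L)
        fragments.append(replace(rec, id=f"{rec.id}_M", sequence=seq[c_start:c_end],
                                 source="fragment"))

    # C-terminal: ends at the last residue
    c_len = _clip(rand_len(), 1, L)
    fragments.append(replace(rec, id=f"{rec.id}_C", sequence=seq[L - c_len:],
                             source="fragment"))
    return fragments


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity: identical positions in the best local alignment,
    normalized by the length of the shorter sequence."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 100.0
    if _ALIGNER.score(a, b) <= 0:
        return 0.0  # no positive-scoring local alignment
    alignment = _ALIGNER.align(a, b)[0]
    identical = sum(
        1
        for (a0, a1), (b0, b1) in zip(*alignment.aligned)
        for i in range(a1 - a0)
        if a[a0 + i] == b[b0 + i]
    )
    return identical / min(len(a), len(b)) * 100.0


def reduce_redundancy(
    records: Sequence[PeptideRecord],
    threshold: float = 60.0,
) -> list[PeptideRecord]:
    """Greedy longest-first redundancy reduction.

    Iterates records by decreasing length (ties broken by input order) and
    keeps a record iff its identity to every already-kept record is at or
    below ``threshold`` percent.  Deterministic; output preserves the kept
    iteration order.
    """
    order = sorted(range(len(records)), key=lambda i: (-len(records[i].sequence), i))
    kept: list[PeptideRecord] = []
    for i in order:
        rec = records[i]
        if all(pairwise_identity(rec.sequence, k.sequence) <= threshold for k in kept):
            kept.append(rec)
    logger.info("redundancy reduction kept %d of %d records", len(kept), len(records))
    return kept


def expand_dataset(
    full_length: Iterable[PeptideRecord],
    est_peptides: Iterable[PeptideRecord],
    policy: FragmentationPolicy = FragmentationPolicy(),
    threshold: float = 60.0,
    seed: int = 0,
) -> list[PeptideRecord]:
    """Fragment full-length proteins, pool with EST-peptides, cluster.

    All inputs must be labeled.  Per-class counts of the expanded dataset
    are logged.
    """
    rng = np.random.default_rng(seed)
    pool: list[PeptideRecord] = []
    for rec in full_length:
        if rec.label is None:
            raise ValueError(f"full-length record {rec.id!r} is unlabeled")
        pool.extend(fragment_protein(rec, policy, rng))
    for rec in est_peptides:
        if rec.label is None:
            raise ValueError(f"EST record {rec.id!r} is unlabeled")
        pool.append(rec)

    expanded = reduce_redundancy(pool, threshold)
    counts: dict[str, int] = {}
    for rec in expanded:
        counts[rec.label] = counts.get(rec.label, 0) + 1
    logger.info("expanded dataset per-class counts: %s", dict(sorted(counts.items())))
    return expanded
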