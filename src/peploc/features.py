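"""Sequence-feature extraction: physicochemical index summaries, k-mer
composition (plain and reduced-alphabet), gapped pair composition, and the
fixed registry of all 41 representations.

Feature vectors are sparse maps from feature key to value; the registry
fixes both the set of representations and their order, so concatenated and
stacked meta-vectors are reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from peploc.sequence_io import (
    GROUP_C,
    GROUP_D,
    UNGROUPED,
    AlphabetMap,
    PeptideRecord,
    recode,
)

logger = logging.getLogger(__name__)

#: ``concat`` is the synthetic family used for concatenated member vectors.
FAMILIES = ("aaindex", "composition", "gapped", "concat")

#: Allowed composition orders per alphabet: plain alphabet up to hexapeptides,
#: reduced alphabets up to order 8 (higher orders overfit).
COMPOSITION_ORDERS: dict[str, range] = {
    "ungrouped": range(1, 7),
    "groupC": range(1, 9),
    "groupD": range(1, 9),
}

#: Allowed gap lengths (number of intervening residues).
GAP_RANGE = range(1, 7)


@dataclass(frozen=True)
class FeatureSpec:
    """One sequence-feature representation.

    ``family`` is one of ``aaindex``, ``composition``, ``gapped``.  ``k`` is
    the composition order; ``gap`` the number of intervening residues for
    gapped pairs; ``dimension`` the size of the (sparse) feature space.
    """

    family: str
    alphabet: Optional[AlphabetMap] = None
    k: Optional[int] = None
    gap: Optional[int] = None
    dimension: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.family == "composition":
            if self.alphabet is None or self.k is None:
                raise ValueError("composition spec needs alphabet and order k")
            allowed = COMPOSITION_ORDERS[self.alphabet.name]
            if self.k not in allowed:
                raise ValueError(
                    f"order {self.k} out of range {allowed.start}..{allowed.stop - 1} "
                    f"for alphabet {self.alphabet.name!r}"
                )
            object.__setattr__(self, "dimension", self.alphabet.size ** self.k)
        elif self.family == "gapped":
            if self.alphabet is None or self.gap is None:
                raise ValueError("gapped spec needs alphabet and gap length")
            if self.gap not in GAP_RANGE:
                raise ValueError(f"gap length {self.gap} out of range 1..6")
            object.__setattr__(self, "dimension", self.alphabet.size ** 2)

    @property
    def name(self) -> str:
        """Stable registry name, e.g. ``aaindex``, ``ungrouped_k4``, ``groupC_gap2``."""
        if self.family in ("aaindex", "concat"):
            return self.family
        if self.family == "composition":
            return f"{self.alphabet.name}_k{self.k}"
        return f"{self.alphabet.name}_gap{self.gap}"

    def __repr__(self) -> str:  # registry names read better in test output
        return f"FeatureSpec({self.name}, dim={self.dimension})"


@dataclass
class FeatureVector:
    """Sparse numeric feature vector: absent keys are zero."""

    spec: FeatureSpec
    values: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return sum(self.values.values())

    def __getitem__(self, key: str) -> float:
        return self.values.get(key, 0.0)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AAIndexTable:
    """Parsed physicochemical index table: one residue->value map per index."""

    entries: list[tuple[str, dict[str, float]]]

    @property
    def count(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]


# AAindex1 'I' record residue order: two rows of ten, columns are
# A/L, R/K, N/M, D/F, C/P, Q/S, E/T, G/W, H/Y, I/V.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


def load_aaindex(path: str | Path) -> AAIndexTable:
    """Parse an AAindex1 flat file (H accession lines, I value blocks).

    Missing values (``NA``) leave the residue absent from that index's map.
    """
    entries: list[tuple[str, dict[str, float]]] = []
    current_id: Optional[str] = None
    value_lines: list[str] = []
    in_values = False

    def flush() -> None:
        nonlocal value_lines, in_values
        if current_id is None or not in_values:
            return
        tokens = " ".join(value_lines).split()
        if len(tokens) != 20:
            raise ValueError(
                f"unparseable I-block for index {current_id!r}: "
                f"expected 20 values, got {len(tokens)}"
            )
        mapping: dict[str, float] = {}
        for aa, tok in zip(_AAINDEX_ROW1 + _AAINDEX_ROW2, tokens):
            if tok.upper() in ("NA", "NA.", "-"):
                continue
            try:
                mapping[aa] = float(tok)
            except ValueError:
                raise ValueError(
                    f"unparseable I-block for index {current_id!r}: bad value {tok!r}"
                ) from None
        entries.append((current_id, mapping))
        value_lines = []
        in_values = False

    for line in Path(path).read_text().splitlines():
        if line.startswith("H "):
            flush()
            current_id = line[2:].strip()
            in_values = False
        elif line.startswith("I "):
            in_values = True
            value_lines = []
        elif line.startswith("//"):
            flush()
            current_id = None
        elif in_values and line.startswith(" "):
            value_lines.append(line)
    flush()

    if not entries:
        raise ValueError(f"{path}: no AAindex entries found")
    return AAIndexTable(entries)


def aaindex_features(seq: str, table: AAIndexTable) -> FeatureVector:
    """Average each physicochemical index over the residues of ``seq``.

    Per index, the residue values are summed and divided by the number of
    residues that index actually covers (indices with NA entries are
    normalized over the covered residues only).  An index covering no
    residue of the sequence contributes 0 and logs a warning.
    """
    if not seq:
        raise ValueError("empty sequence")
    spec = FeatureSpec("aaindex", dimension=table.count)
    values: dict[str, float] = {}
    for index_id, mapping in table.entries:
        total = 0.0
        covered = 0
        for aa in seq:
            if aa in mapping:
                total += mapping[aa]
                covered += 1
        if covered == 0:
            logger.warning("index %s covers no residue of the sequence; value set to 0",
                           index_id)
            values[index_id] = 0.0
        else:
            values[index_id] = total / covered
    return FeatureVector(spec, values)


def kmer_composition(seq: str, alphabet: AlphabetMap, k: int) -> FeatureVector:
    """Overlapping k-mer frequencies of the recoded sequence.

    Counts are normalized by the window count ``L - k + 1``.  Sequences
    shorter than ``k`` yield a zero vector with a logged warning (EST
    peptides can be short; this is not an error).
    """
    spec = FeatureSpec("composition", alphabet=alphabet, k=k)
    coded = recode(seq, alphabet)
    n_windows = len(coded) - k + 1
    if n_windows < 1:
        logger.warning("sequence of length %d too short for order-%d composition",
                       len(coded), k)
        return FeatureVector(spec)
    counts: dict[str, float] = {}
    for i in range(n_windows):
        kmer = coded[i:i + k]
        counts[kmer] = counts.get(kmer, 0.0) + 1.0
    return FeatureVector(spec, {kmer: c / n_windows for kmer, c in counts.items()})


def gapped_composition(seq: str, alphabet: AlphabetMap, x: int) -> FeatureVector:
    """Frequencies of ordered symbol pairs separated by exactly ``x`` residues.

    Pairs ``(s_i, s_{i+x+1})`` are counted for ``i = 0..L-x-2`` and
    normalized by the pair count ``L - x - 1``.  Too-short sequences yield a
    zero vector with a warning.
    """
    spec = FeatureSpec("gapped", alphabet=alphabet, gap=x)
    coded = recode(seq, alphabet)
    n_pairs = len(coded) - x - 1
    if n_pairs < 1:
        logger.warning("sequence of length %d too short for gap length %d",
                       len(coded), x)
        return FeatureVector(spec)
    counts: dict[str, float] = {}
    for i in range(n_pairs):
        key = coded[i] + coded[i + x + 1]
        counts[key] = counts.get(key, 0.0) + 1.0
    return FeatureVector(spec, {key: c / n_pairs for key, c in counts.items()})


def build_feature_registry(table: AAIndexTable) -> list[FeatureSpec]:
    """Build the fixed, ordered registry of all 41 feature representations.

    Order: the physicochemical index summary; plain composition orders 1-6;
    group-C composition orders 1-8; group-D composition orders 1-8; gapped
    composition, gap lengths 1-6, for plain, group-C and group-D alphabets.
    """
    registry: list[FeatureSpec] = [FeatureSpec("aaindex", dimension=table.count)]
    for alphabet in (UNGROUPED, GROUP_C, GROUP_D):
        for k in COMPOSITION_ORDERS[alphabet.name]:
            registry.append(FeatureSpec("composition", alphabet=alphabet, k=k))
    for alphabet in (UNGROUPED, GROUP_C, GROUP_D):
        for x in GAP_RANGE:
            registry.append(FeatureSpec("gapped", alphabet=alphabet, gap=x))
    return registry


def registry_by_name(table: AAIndexTable) -> dict[str, FeatureSpec]:
    """Registry keyed by stable spec name."""
    return {spec.name: spec for spec in build_feature_registry(table)}


def resolve_specs(names: Sequence[str], table: AAIndexTable) -> list[FeatureSpec]:
    """Resolve registry names to specs, preserving registry order."""
    lookup = registry_by_name(table)
    unknown = [n for n in names if n not in lookup]
    if unknown:
        raise KeyError(
            f"unknown feature name(s) {unknown}; valid names: {sorted(lookup)}"
        )
    wanted = set(names)
    return [spec for spec in build_feature_registry(table) if spec.name in wanted]


def extract(seq: str, spec: FeatureSpec, table: Optional[AAIndexTable] = None) -> FeatureVector:
    """Dispatch extraction to the family-specific routine."""
    if spec.family == "aaindex":
        if table is None:
            raise ValueError("aaindex extraction requires an index table")
        return aaindex_features(seq, table)
    if spec.family == "composition":
        return kmer_composition(seq, spec.alphabet, spec.k)
    if spec.family == "gapped":
        return gapped_composition(seq, spec.alphabet, spec.gap)
    raise ValueError(f"unknown feature family {spec.family!r}")


@dataclass
class TetrapeptideAudit:
    """Summary of tetra-peptide motif usage across a labeled dataset."""

    total_occurrences: int
    n_distinct: int
    n_single_class: int
    #: per motif, fraction of each containing class's members that contain it
    class_prevalence: dict[str, dict[str, float]]
    #: motifs present in all classes but exactly one
    absent_from_one_class: list[str]


def tetrapeptide_audit(dataset: Iterable[PeptideRecord]) -> TetrapeptideAudit:
    """Audit tetra-peptide (4-mer) motifs across a labeled dataset.

    Reports total occurrences (sum over records of ``max(L-3, 0)``), the
    number of distinct motifs, how many occur in exactly one class, the
    within-class prevalence of each motif, and motifs absent from exactly
    one class.
    """
    records = list(dataset)
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabeled; the audit needs labels")

    classes = sorted({rec.label for rec in records})
    class_sizes = {c: sum(1 for r in records if r.label == c) for c in classes}

    total_occurrences = 0
    # motif -> class -> number of members containing it
    motif_members: dict[str, dict[str, int]] = {}
    for rec in records:
        n = max(len(rec.sequence) - 3, 0)
        total_occurrences += n
        seen = {rec.sequence[i:i + 4] for i in range(n)}
        for motif in seen:
            motif_members.setdefault(motif, {}).setdefault(rec.label, 0)
            motif_members[motif][rec.label] += 1

    n_single_class = sum(1 for by_class in motif_members.values() if len(by_class) == 1)
    prevalence = {
        motif: {c: cnt / class_sizes[c] for c, cnt in by_class.items()}
        for motif, by_class in motif_members.items()
    }
    absent_from_one = [
        motif for motif, by_class in motif_members.items()
        if len(by_class) == len(classes) - 1 and len(classes) > 1
    ]
    return TetrapeptideAudit(
        total_occurrences=total_occurrences,
        n_distinct=len(motif_members),
        n_single_class=n_single_class,
        class_prevalence=prevalence,
        absent_from_one_class=sorted(absent_from_one),
    )


def write_vector_tsv(vector: FeatureVector, path: str | Path) -> None:
    """Export a sparse vector as key<TAB>value TSV, keys sorted."""
    with open(path, "w") as handle:
        handle.write(f"# feature\t{vector.spec.name}\tdimension\t{vector.spec.dimension}\n")
        for key in sorted(vector.values):
            handle.write(f"{key}\t{vector.values[key]:.10g}\n")
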