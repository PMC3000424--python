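"""Peptide/nucleotide FASTA I/O, sequence cleaning, and reduced-alphabet recoding.

Two reduced alphabets are supported in addition to the plain 20-letter one:
``group C`` collapses the amino acids into 8 chemical-property groups and
``group D`` into 10 structural groups.  A best-effort six-frame translation
utility is provided for nucleotide ESTs; it is plumbing, not an ORF model,
and is always logged as heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The nine compartment codes, in canonical (alphabetical) order.
COMPARTMENTS: tuple[str, ...] = (
    "chl", "cyt", "end", "ext", "mit", "nuc", "per", "pla", "vac",
)

#: The 20 canonical amino acids.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Valid ``source`` tags for a record.
SOURCES: tuple[str, ...] = ("est_derived", "fragment", "full_length", "synthetic")


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


class LabelError(ValueError):
    """Raised for invalid compartment labels."""


@dataclass
class PeptideRecord:
    """One (possibly partial) amino-acid sequence.

    Attributes
    ----------
    id : str
        Sequence identifier, unique within a dataset.
    sequence : str
        Cleaned sequence over the 20-letter amino-acid alphabet.
    label : str, optional
        Compartment code, one of :data:`COMPARTMENTS`.
    source : str
        Provenance tag, one of :data:`SOURCES`.
    """

    id: str
    sequence: str
    label: Optional[str] = None
    source: str = "est_derived"

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in COMPARTMENTS:
            raise LabelError(
                f"unknown compartment code {self.label!r}; "
                f"allowed codes: {', '.join(COMPARTMENTS)}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: str) -> "PeptideRecord":
        return replace(self, label=label)


@dataclass(frozen=True)
class AlphabetMap:
    """A total map from the 20 amino acids to group symbols.

    ``mapping`` must cover exactly the 20 canonical residues.  ``size`` is
    the number of distinct group symbols.
    """

    name: str
    mapping: Mapping[str, str]
    size: int = field(init=False)

    def __post_init__(self) -> None:
        if set(self.mapping) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.mapping)
            extra = set(self.mapping) - set(AMINO_ACIDS)
            raise ValueError(
                f"alphabet {self.name!r} must cover exactly the 20 canonical "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        object.__setattr__(self, "size", len(set(self.mapping.values())))

    @property
    def symbols(self) -> tuple[str, ...]:
        """Distinct group symbols, sorted."""
        return tuple(sorted(set(self.mapping.values())))

    def translate(self, seq: str) -> str:
        return "".join(self.mapping[aa] for aa in seq)


def _group_map(groups: Iterable[tuple[str, str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for symbol, members in groups:
        for aa in members:
            if aa in out:
                raise ValueError(f"residue {aa} assigned to two groups")
            out[aa] = symbol
    return out


#: Identity alphabet over the 20 amino acids.
UNGROUPED = AlphabetMap("ungrouped", {aa: aa for aa in AMINO_ACIDS})

#: 8-group chemical-property alphabet: acidic, basic, aromatic,
#: small-hydroxyl, sulphur-containing, two aliphatic groups, amide.
GROUP_C = AlphabetMap("groupC", _group_map([
    ("a", "DE"),    # acidic
    ("b", "HKR"),   # basic
    ("r", "FWY"),   # aromatic
    ("h", "ST"),    # small hydroxyl
    ("s", "CM"),    # sulphur containing
    ("1", "AGP"),   # aliphatic 1
    ("2", "ILV"),   # aliphatic 2
    ("m", "NQ"),    # amide
]))

#: 10-group structural alphabet.
GROUP_D = AlphabetMap("groupD", _group_map([
    ("g", "GA"),    # monoamino monocarboxylic
    ("u", "VLI"),   # unsubstituted
    ("e", "PF"),    # heterocyclic
    ("r", "WY"),    # aromatic
    ("t", "M"),     # thioether
    ("h", "ST"),    # hydroxy
    ("c", "C"),     # mercapto
    ("m", "NQ"),    # carboxamide
    ("d", "DE"),    # monoamino dicarboxylic
    ("b", "HKR"),   # diamino monocarboxylic
]))

ALPHABETS: dict[str, AlphabetMap] = {
    "ungrouped": UNGROUPED,
    "groupC": GROUP_C,
    "groupD": GROUP_D,
}


def clean_sequence(raw: str) -> str:
    """Uppercase, strip terminal ``*`` and drop non-canonical residues.

    Characters outside the 20-letter alphabet (B, J, O, U, X, Z, gaps, ...)
    are removed; the removal count is logged at WARNING level so callers can
    filter noisy records.

    Raises
    ------
    SequenceError
        If nothing usable remains after cleaning.
    """
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    kept = [c for c in seq if c in AMINO_ACIDS]
    removed = len(seq) - len(kept)
    if removed:
        logger.warning("removed %d non-canonical residue(s) during cleaning", removed)
    if not kept:
        raise SequenceError("no usable residues after cleaning")
    return "".join(kept)


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV ``id<TAB>code`` label table; '#' comments allowed."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LabelError(f"{path}:{lineno}: expected 2 tab-separated columns")
        seq_id, code = parts[0].strip(), parts[1].strip()
        if code not in COMPARTMENTS:
            raise LabelError(
                f"{path}:{lineno}: unknown compartment code {code!r}; "
                f"allowed codes: {', '.join(COMPARTMENTS)}"
            )
        labels[seq_id] = code
    return labels


def read_fasta(
    path: str | Path,
    labels: Optional[str | Path | Mapping[str, str]] = None,
    source: str = "est_derived",
) -> list[PeptideRecord]:
    """Read peptide FASTA into cleaned :class:`PeptideRecord` objects.

    Parameters
    ----------
    path : path
        Peptide FASTA file.
    labels : path or mapping, optional
        Label table (TSV path or ``{id: code}`` mapping) joined by id.
    source : str
        Source tag attached to every record.
    """
    if labels is None:
        label_map: Mapping[str, str] = {}
    elif isinstance(labels, Mapping):
        for code in labels.values():
            if code not in COMPARTMENTS:
                raise LabelError(
                    f"unknown compartment code {code!r}; "
                    f"allowed codes: {', '.join(COMPARTMENTS)}"
                )
        label_map = labels
    else:
        label_map = read_label_table(labels)

    records: list[PeptideRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, raw_seq in SimpleFastaParser(handle):
            seq_id = header.split()[0] if header.split() else header
            if not seq_id:
                raise SequenceError(f"{path}: FASTA entry with empty header")
            if seq_id in seen:
                raise SequenceError(f"{path}: duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            try:
                seq = clean_sequence(raw_seq)
            except SequenceError as exc:
                raise SequenceError(f"{path}: entry {seq_id!r}: {exc}") from exc
            records.append(
                PeptideRecord(seq_id, seq, label=label_map.get(seq_id), source=source)
            )
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i:i + width] + "\n")


def write_label_table(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write the labels of ``records`` as a 2-column TSV."""
    with open(path, "w") as handle:
        for rec in records:
            if rec.label is not None:
                handle.write(f"{rec.id}\t{rec.label}\n")


def recode(seq: str, alphabet: AlphabetMap) -> str:
    """Recode a cleaned sequence into an alphabet's group symbols.

    Length-preserving; the identity alphabet returns the input unchanged.
    """
    try:
        return alphabet.translate(seq)
    except KeyError as exc:
        raise SequenceError(
            f"residue {exc.args[0]!r} not in alphabet {alphabet.name!r}; "
            "was the sequence cleaned?"
        ) from None


_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)


def _translate_frame(nt: str) -> str:
    """Translate one frame; stops -> '*', ambiguous codons -> 'X'."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i:i + 3]
        if codon in _STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def _revcomp(nt: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(nt))


def best_frame_translate(nt_seq: str, min_codons: int = 10) -> str:
    """Translate the longest stop-free stretch among all six reading frames.

    This is a labeled heuristic stand-in for a proper EST ORF predictor: it
    translates frames +1,+2,+3,-1,-2,-3 with the standard genetic code and
    returns the longest contiguous stop-free peptide stretch, ties broken by
    frame order.  Stretches containing only 'X' (ambiguous codons) count
    toward length but an all-ambiguous result is rejected.

    Raises
    ------
    SequenceError
        If no stop-free stretch of at least ``min_codons`` codons exists
        (for inputs shorter than ``3 * min_codons`` nt the requirement drops
        to the longest frame the input can hold).
    """
    nt = nt_seq.strip().upper().replace("U", "T")
    if not nt or set(nt) - set("ACGTN"):
        bad = sorted(set(nt) - set("ACGTN"))
        raise SequenceError(f"nucleotide sequence contains invalid characters {bad}")
    min_codons = max(1, min(min_codons, len(nt) // 3))

    frames = [nt, nt[1:], nt[2:]]
    rc = _revcomp(nt)
    frames += [rc, rc[1:], rc[2:]]

    best = ""
    for frame in frames:
        peptide = _translate_frame(frame)
        for stretch in peptide.split("*"):
            stretch = stretch.strip("X")
            if len(stretch) > len(best) and any(c != "X" for c in stretch):
                best = stretch
    if len(best) < min_codons:
        raise SequenceError("no plausible ORF (no stop-free stretch of >= 10 codons)")
    logger.warning(
        "best_frame_translate is a heuristic frame picker, not an ORF model; "
        "treat the translation with caution"
    )
    return clean_sequence(best)
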