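"""Nucleotide sequence model, IUPAC degeneracy algebra, GC/Tm, FASTA I/O.

Sequences are stored upper-case in the DNA alphabet (``U`` is normalised to
``T`` on input). Degenerate positions are handled throughout by the IUPAC
ambiguity codes, interpreted as sets of concrete bases; two symbols are
compatible when their sets intersect.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    CapacityError,
    ConfigurationError,
    ParseError,
    ValidationError,
)

GAP = "-"

#: IUPAC ambiguity codes as sets of concrete bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS) | {GAP}

# Bitmask encoding: A=1, C=2, G=4, T=8; an ambiguity code is the OR of its
# bases. Compatibility is then a nonzero bitwise AND, which vectorises.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}
IUPAC_MASK[GAP] = 0
_MASK_TO_CODE = {mask: code for code, mask in IUPAC_MASK.items() if code != GAP}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", GAP: GAP,
}

# uint8 lookup table from ASCII byte -> bitmask, for numpy encoding.
_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _code, _mask in IUPAC_MASK.items():
    _ENCODE_LUT[ord(_code)] = _mask


def normalize(residues: str) -> str:
    """Upper-case and map RNA ``U`` to DNA ``T``. Idempotent."""
    return residues.upper().replace("U", "T")


def validate_iupac(residues: str, allow_gaps: bool = True) -> None:
    """Raise :class:`ValidationError` naming the first offending position."""
    if not residues:
        raise ValidationError("empty sequence")
    allowed = IUPAC_ALPHABET if allow_gaps else frozenset(IUPAC_SETS)
    for i, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise ValidationError(
                f"invalid residue {ch!r} at position {i} (IUPAC codes only"
                + ("" if allow_gaps else ", gaps not allowed") + ")"
            )


def encode_mask(residues: str) -> np.ndarray:
    """Encode a normalised IUPAC string as a uint8 bitmask array (gap -> 0)."""
    return _ENCODE_LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over the IUPAC alphabet (gaps allowed).

    ``residues`` are normalised on construction: upper-cased, U -> T.
    ``description`` keeps any FASTA header text after the first whitespace.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        norm = normalize(self.residues)
        validate_iupac(norm, allow_gaps=True)
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "NucleotideSequence":
        """Copy with alignment gaps removed."""
        return NucleotideSequence(self.id, self.residues.replace(GAP, ""), self.description)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.residues), self.description)


@dataclass(frozen=True)
class Primer:
    """A named oligonucleotide, written 5'->3' as synthesised.

    ``orientation`` says which strand the primer extends along: ``forward``
    primers bind the template minus strand and read along the plus strand,
    ``reverse`` primers the converse. Degenerate positions (R, Y, ...)
    represent an equimolar mixture of concrete oligos.
    """

    name: str
    sequence: str
    orientation: str
    citation: str | None = None
    min_length: int = field(default=15, repr=False, compare=False)
    max_length: int = field(default=35, repr=False, compare=False)

    def __post_init__(self) -> None:
        norm = normalize(self.sequence)
        validate_iupac(norm, allow_gaps=False)
        object.__setattr__(self, "sequence", norm)
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(
                f"orientation must be 'forward' or 'reverse', got {self.orientation!r}"
            )
        if not (self.min_length <= len(norm) <= self.max_length):
            raise ValidationError(
                f"primer {self.name}: length {len(norm)} outside "
                f"[{self.min_length}, {self.max_length}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)


def degeneracy(seq: str) -> int:
    """Product of per-position expansion-set sizes."""
    seq = normalize(seq)
    validate_iupac(seq, allow_gaps=False)
    n = 1
    for ch in seq:
        n *= len(IUPAC_SETS[ch])
    return n


def reverse_complement(seq: str) -> str:
    """IUPAC-correct reverse complement; an involution on valid input."""
    seq = normalize(seq)
    validate_iupac(seq, allow_gaps=True)
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


def expand_degenerate(seq: str, max_expansions: int = 1024) -> list[str]:
    """All concrete A/C/G/T strings a degenerate oligo represents.

    Returned in lexicographic order. Raises :class:`CapacityError` if the
    expansion count exceeds ``max_expansions``.
    """
    if max_expansions < 1:
        raise ValidationError("max_expansions must be >= 1")
    seq = normalize(seq)
    validate_iupac(seq, allow_gaps=False)
    count = degeneracy(seq)
    if count > max_expansions:
        raise CapacityError(
            f"degenerate expansion of {seq!r} has {count} members "
            f"(> max_expansions={max_expansions})"
        )
    choices = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return ["".join(p) for p in itertools.product(*choices)]


def gc_content(seq: str) -> float:
    """Expected GC percentage of a (possibly degenerate) oligo.

    Each position contributes the fraction of its expansion set lying in
    {G, C}; the result equals the mean GC% over all concrete expansions.
    This degenerate-average convention is fixed, not configurable.
    """
    seq = normalize(seq)
    validate_iupac(seq, allow_gaps=False)
    gc = frozenset("GC")
    total = sum(len(IUPAC_SETS[ch] & gc) / len(IUPAC_SETS[ch]) for ch in seq)
    return 100.0 * total / len(seq)


TM_METHODS = ("wallace", "gc_salt_adjusted")


def _tm_from_gc_count(method: str, length: int, n_gc: int, na_mM: float) -> float:
    if method == "wallace":
        # 2(A+T) + 4(G+C)
        return 2.0 * (length - n_gc) + 4.0 * n_gc
    # Salt-adjusted GC formula (Marmur/Schildkraut form).
    gc_pct = 100.0 * n_gc / length
    return 81.5 + 16.6 * math.log10(na_mM / 1000.0) + 0.41 * gc_pct - 600.0 / length


def melting_temperature(
    seq: str, method: str = "gc_salt_adjusted", na_mM: float = 50.0
) -> tuple[float, float]:
    """(min, max) melting temperature over the degenerate expansions, °C.

    Both implemented methods depend on an expansion only through its G+C
    count, so the extrema are attained at the per-position extreme GC
    assignments; small expansions are enumerated outright.
    """
    if method not in TM_METHODS:
        raise ConfigurationError(
            f"unknown Tm method {method!r}; available: {', '.join(TM_METHODS)}"
        )
    seq = normalize(seq)
    validate_iupac(seq, allow_gaps=False)
    length = len(seq)
    if degeneracy(seq) <= 4096:
        tms = [
            _tm_from_gc_count(method, length, sum(b in "GC" for b in exp), na_mM)
            for exp in expand_degenerate(seq, max_expansions=4096)
        ]
        return (min(tms), max(tms))
    gc = frozenset("GC")
    n_gc_min = sum(1 for ch in seq if IUPAC_SETS[ch] <= gc)
    n_gc_max = sum(1 for ch in seq if IUPAC_SETS[ch] & gc)
    return (
        _tm_from_gc_count(method, length, n_gc_min, na_mM),
        _tm_from_gc_count(method, length, n_gc_max, na_mM),
    )


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file, preserving record order.

    The FASTA id is the token up to the first whitespace; the remainder of
    the header line is kept as ``description``.
    """
    path = Path(path)
    # Pre-scan: sequence data before the first header is a malformation that
    # Biopython reports without a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                break
            raise ParseError("sequence data before first FASTA header", line=lineno)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(NucleotideSequence(rec.id, str(rec.seq), desc))
    return records


def write_fasta(
    seqs: Iterable[NucleotideSequence], path: str | Path, line_width: int = 70
) -> None:
    """Write sequences as wrapped FASTA; round-trips with :func:`read_fasta`."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=line_width)
    writer.write_file(records)


def load_primers(path: str | Path) -> list[Primer]:
    """Load primers from a delimited file: name, sequence, orientation[, citation].

    Columns are tab- or whitespace-separated; ``#`` lines and a header line
    are skipped.
    """
    primers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) < 3:
                raise ParseError(
                    f"expected >=3 columns (name, sequence, orientation), got {len(fields)}",
                    line=lineno,
                )
            name, seq, orient = fields[0], fields[1], fields[2].lower()
            if orient not in ("forward", "reverse"):
                if name.lower() == "name":  # header row
                    continue
                raise ParseError(
                    f"orientation must be forward|reverse, got {fields[2]!r}", line=lineno
                )
            citation = fields[3] if len(fields) > 3 else None
            primers.append(Primer(name, seq, orient, citation))
    return primers


def table1_primers() -> list[Primer]:
    """The published peritrich assay primer panel (universal EukA plus four
    peritrich-specific oligos named after their reference coordinates)."""
    rows: Sequence[tuple[str, str, str, str]] = (
        ("EukA", "AACCTGGTTGATCCTGCCAGT", "forward", "Medlin et al., 1988"),
        ("Peri974F", "GGAAACTCATCAGGRCAAGAAGATT", "forward", "this assay"),
        ("Peri979F", "CTCATCAGGRCAAGAAGATT", "forward", "this assay"),
        ("Peri1004R", "TCCTAYAATCTTCTTGYCCTGATG", "reverse", "this assay"),
        ("Peri1403R", "GGGCGRTGTGTACATTTTG", "reverse", "this assay"),
    )
    return [Primer(*row) for row in rows]
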