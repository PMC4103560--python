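"""Candidate group-specific primer discovery from a grouped alignment.

The procedure formalises what assay designers do by eye: slide windows over
the target rows of a multiple alignment, collapse each window to a minimal
degenerate consensus, and keep windows whose consensus binds (nearly) all
targets while staying several mismatches away from every non-target.

Windows are screened in alignment-column space with vectorised bitmask
arithmetic, then every surviving candidate is re-scored by scanning the
*ungapped* member sequences at every offset — PCR acts on unaligned
molecules, so alignment artifacts must not mask (or fake) real binding.
The thresholds reported and filtered on are always the ungapped-scan ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import MappingError, ValidationError
from . import primermatch
from .seqcore import (
    GAP,
    IUPAC_MASK,
    IUPAC_SETS,
    NucleotideSequence,
    Primer,
    encode_mask,
    gc_content,
    melting_temperature,
    reverse_complement,
)

_MASK_TO_CODE = {mask: code for code, mask in IUPAC_MASK.items() if code != GAP}
_SET_BITS = np.array([bin(m).count("1") for m in range(16)])


@dataclass(frozen=True)
class GroupedAlignment:
    """Equal-length aligned rows partitioned into target and non-target ids."""

    rows: tuple[NucleotideSequence, ...]
    target_ids: frozenset[str]
    nontarget_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"rows have unequal lengths: {sorted(lengths)}")
        ids = {r.id for r in self.rows}
        if len(ids) != len(self.rows):
            raise ValidationError("duplicate row ids in alignment")
        if self.target_ids & self.nontarget_ids:
            raise ValidationError("target and non-target id sets overlap")
        if (self.target_ids | self.nontarget_ids) != ids:
            raise ValidationError("group ids must exactly cover the alignment rows")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def group(self, which: str) -> list[NucleotideSequence]:
        wanted = self.target_ids if which == "target" else self.nontarget_ids
        return [r for r in self.rows if r.id in wanted]

    @classmethod
    def from_files(cls, fasta_path: str | Path, groups_path: str | Path) -> "GroupedAlignment":
        """Build from an aligned FASTA plus a 2-column group file
        (id <tab> target|nontarget)."""
        from .seqcore import read_fasta

        rows = tuple(read_fasta(fasta_path))
        targets, nontargets = set(), set()
        with open(groups_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 2 or fields[1] not in ("target", "nontarget"):
                    raise ValidationError(f"bad group line: {line!r}")
                (targets if fields[1] == "target" else nontargets).add(fields[0])
        return cls(rows, frozenset(targets), frozenset(nontargets))


@dataclass(frozen=True)
class CandidatePrimer:
    """One qualifying window with its consensus oligo and scan-based scores.

    ``consensus`` is the primer as synthesised: for reverse orientation it is
    the reverse complement of the window's plus-strand consensus. Columns are
    0-based alignment coordinates, window inclusive of both ends.
    """

    start_col: int
    end_col: int
    orientation: str
    consensus: str
    degeneracy: int
    target_coverage: float
    min_nontarget_mismatches: int
    gc_percent: float
    tm_range: tuple[float, float]

    def as_primer(self, name: str) -> Primer:
        return Primer(name, self.consensus, self.orientation)


class WindowRejected(Exception):
    """Internal signal: a window contains a gap-heavy or empty column."""


def degenerate_consensus(
    target_columns: Sequence[Mapping[str, int]],
    min_base_freq: float = 0.10,
    max_gap_freq: float = 0.5,
) -> str:
    """Minimal IUPAC oligo covering every base at frequency >= ``min_base_freq``.

    Each entry of ``target_columns`` is a base->count multiset for one
    alignment column (gaps counted under ``"-"``). A column whose gap
    frequency exceeds ``max_gap_freq`` raises :class:`WindowRejected`.
    """
    out = []
    for col in target_columns:
        total = sum(col.values())
        if total == 0:
            raise WindowRejected("empty column")
        if col.get(GAP, 0) / total > max_gap_freq:
            raise WindowRejected("gap-majority column")
        mask = 0
        for base, count in col.items():
            if base == GAP:
                continue
            if count / total >= min_base_freq:
                mask |= IUPAC_MASK[base]
        if mask == 0:
            # every base rare: fall back to covering all observed bases
            for base in col:
                if base != GAP:
                    mask |= IUPAC_MASK[base]
        out.append(_MASK_TO_CODE[mask])
    return "".join(out)


def _column_multisets(rows: Sequence[NucleotideSequence], lo: int, hi: int):
    cols = []
    for c in range(lo, hi):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r.residues[c]
            counts[ch] = counts.get(ch, 0) + 1
        cols.append(counts)
    return cols


def design_candidates(
    aln: GroupedAlignment,
    window_len: tuple[int, int] = (18, 26),
    max_degeneracy: int = 8,
    min_target_coverage: float = 0.9,
    min_nontarget_mm: int = 3,
    orientation: str = "both",
    min_base_freq: float = 0.10,
    max_target_mismatches: int = 1,
) -> list[CandidatePrimer]:
    """Rank all alignment windows that could serve as group-specific primers.

    ``target_coverage`` is the fraction of target members whose ungapped
    sequence carries a site with at most ``max_target_mismatches`` mismatches
    to the consensus; ``min_nontarget_mm`` is the required scan minimum over
    every non-target. Ranking: non-target separation desc, coverage desc,
    degeneracy asc, start column asc. Deterministic.
    """
    targets = aln.group("target")
    nontargets = aln.group("nontarget")
    if len(targets) < 2 or len(nontargets) < 1:
        raise ValidationError("need >= 2 target rows and >= 1 non-target row")
    orientations = ("forward", "reverse") if orientation == "both" else (orientation,)

    n_cols = aln.n_columns
    # Bitmask matrix of target rows for the vectorised column screen.
    tgt_mask = np.stack([encode_mask(r.residues) for r in targets])
    ntg_mask = np.stack([encode_mask(r.residues) for r in nontargets])
    n_tgt = len(targets)

    # Per-column consensus mask over targets at min_base_freq.
    counts = np.zeros((16, n_cols), dtype=np.int32)
    for m in range(1, 16):
        counts[m] = (tgt_mask == m).sum(axis=0)
    col_total = counts.sum(axis=0) + (tgt_mask == 0).sum(axis=0)
    cons_mask = np.zeros(n_cols, dtype=np.uint8)
    for m in range(1, 16):
        keep = counts[m] / np.maximum(col_total, 1) >= min_base_freq
        cons_mask[keep] |= np.uint8(m)
    # Columns where nothing passed: cover all observed bases.
    empty = cons_mask == 0
    if empty.any():
        observed = np.zeros(n_cols, dtype=np.uint8)
        for m in range(1, 16):
            observed[counts[m] > 0] |= np.uint8(m)
        cons_mask[empty] = observed[empty]
    gap_frac = (tgt_mask == 0).sum(axis=0) / n_tgt
    col_degeneracy = _SET_BITS[cons_mask]

    # In-place (alignment-column) mismatch indicator, then prefix sums give
    # window mismatch counts for every row and start in O(rows * cols).
    tgt_mm = np.concatenate(
        [np.zeros((n_tgt, 1), dtype=np.int32),
         np.cumsum(((tgt_mask & cons_mask) == 0).astype(np.int32), axis=1)], axis=1
    )
    ntg_mm = np.concatenate(
        [np.zeros((len(nontargets), 1), dtype=np.int32),
         np.cumsum(((ntg_mask & cons_mask) == 0).astype(np.int32), axis=1)], axis=1
    )
    log_deg = np.concatenate([[0.0], np.cumsum(np.log2(col_degeneracy))])
    gap_bad = np.concatenate([[0], np.cumsum(gap_frac > 0.5)])

    ungapped_targets = [r.ungapped() for r in targets]
    ungapped_nontargets = [r.ungapped() for r in nontargets]

    candidates: list[CandidatePrimer] = []
    seen: set[tuple[int, int, str]] = set()
    lo_len, hi_len = window_len
    for L in range(lo_len, hi_len + 1):
        if L > n_cols:
            continue
        starts = np.arange(n_cols - L + 1)
        deg_ok = (log_deg[starts + L] - log_deg[starts]) <= np.log2(max_degeneracy) + 1e-9
        gap_ok = (gap_bad[starts + L] - gap_bad[starts]) == 0
        win_tgt_mm = tgt_mm[:, starts + L] - tgt_mm[:, starts]  # rows x starts
        win_ntg_mm = ntg_mm[:, starts + L] - ntg_mm[:, starts]
        # In-place mismatch is an upper bound on the scan minimum, so passing
        # coverage here is sufficient; non-target separation is only an upper
        # bound and is re-verified by the ungapped scan below.
        cov = (win_tgt_mm <= max_target_mismatches).mean(axis=0)
        sep = win_ntg_mm.min(axis=0)
        ok = deg_ok & gap_ok & (cov >= min_target_coverage) & (sep >= min_nontarget_mm)
        for s in np.nonzero(ok)[0]:
            s = int(s)
            cols = _column_multisets(targets, s, s + L)
            try:
                plus_consensus = degenerate_consensus(cols, min_base_freq)
            except WindowRejected:
                continue
            for orient in orientations:
                key = (s, L, orient)
                if key in seen:
                    continue
                seen.add(key)
                oligo = plus_consensus if orient == "forward" else reverse_complement(plus_consensus)
                cand = _score_candidate(
                    s, s + L - 1, orient, oligo,
                    ungapped_targets, ungapped_nontargets, max_target_mismatches,
                )
                if (
                    cand.target_coverage >= min_target_coverage
                    and cand.min_nontarget_mismatches >= min_nontarget_mm
                    and cand.degeneracy <= max_degeneracy
                ):
                    candidates.append(cand)
    candidates.sort(
        key=lambda c: (
            -c.min_nontarget_mismatches,
            -c.target_coverage,
            c.degeneracy,
            c.start_col,
            c.orientation,
        )
    )
    return candidates


def _score_candidate(
    start_col: int,
    end_col: int,
    orientation: str,
    oligo: str,
    targets: Sequence[NucleotideSequence],
    nontargets: Sequence[NucleotideSequence],
    max_target_mismatches: int,
) -> CandidatePrimer:
    """Scan-based coverage/separation for one window consensus, evaluated on
    ungapped member sequences with the primer as synthesised."""
    primer = Primer("cand", oligo, orientation, min_length=1, max_length=len(oligo))
    n_cov = 0
    for seq in targets:
        mm, _ = primermatch.min_mismatches(primer, seq)
        if mm is not None and mm <= max_target_mismatches:
            n_cov += 1
    sep = None
    for seq in nontargets:
        mm, _ = primermatch.min_mismatches(primer, seq)
        if mm is not None and (sep is None or mm < sep):
            sep = mm
    deg = 1
    for ch in oligo:
        deg *= len(IUPAC_SETS[ch])
    return CandidatePrimer(
        start_col=start_col,
        end_col=end_col,
        orientation=orientation,
        consensus=oligo,
        degeneracy=deg,
        target_coverage=n_cov / len(targets),
        min_nontarget_mismatches=sep if sep is not None else len(oligo),
        gc_percent=gc_content(oligo),
        tm_range=melting_temperature(oligo),
    )


def map_to_reference(
    aln: GroupedAlignment, candidate: CandidatePrimer, reference_row_id: str
) -> int:
    """1-based ungapped coordinate, on the named reference row, of the
    candidate window's first column.

    Raises :class:`MappingError` when the reference is gapped across the
    entire window.
    """
    ref = next((r for r in aln.rows if r.id == reference_row_id), None)
    if ref is None:
        raise MappingError(f"reference row {reference_row_id!r} not in alignment")
    window = ref.residues[candidate.start_col : candidate.end_col + 1]
    if set(window) <= {GAP}:
        raise MappingError(
            f"window [{candidate.start_col}, {candidate.end_col}] lies entirely "
            f"in a gap run of reference {reference_row_id!r}"
        )
    prefix = ref.residues[: candidate.start_col]
    return len(prefix) - prefix.count(GAP) + 1


def primer_name(prefix: str, position: int, orientation: str) -> str:
    """Conventional name: <prefix><reference position><F|R>."""
    return f"{prefix}{position}{'F' if orientation == 'forward' else 'R'}"


def write_candidate_table(candidates: Iterable[CandidatePrimer], path: str | Path) -> None:
    header = ("start_col", "end_col", "orientation", "consensus", "degeneracy",
              "target_coverage", "min_nontarget_mismatches", "gc_percent",
              "tm_min", "tm_max")
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in candidates:
            fh.write(
                f"{c.start_col}\t{c.end_col}\t{c.orientation}\t{c.consensus}\t"
                f"{c.degeneracy}\t{c.target_coverage:.4f}\t"
                f"{c.min_nontarget_mismatches}\t{c.gc_percent:.1f}\t"
                f"{c.tm_range[0]:.1f}\t{c.tm_range[1]:.1f}\n"
            )
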