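"""Primer-to-template matching and group specificity profiling.

Matching is ungapped and IUPAC-aware on both sides: a primer base and a
template base are compatible when their ambiguity sets intersect. Degenerate
primer symbols are matched as compatible-set bitmasks rather than by
enumerating expansions; the two routes are equivalent and that equivalence
is exercised by the test suite.

Coordinates are 1-based and inclusive on the template plus strand. A
minus-strand hit (the primer binding the plus strand, i.e. its sequence
appearing reverse-complemented on the plus strand) is reported by the
plus-strand interval it occupies, with ``strand="minus"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import BoundsError, ValidationError
from .seqcore import (
    GAP,
    IUPAC_MASK,
    NucleotideSequence,
    Primer,
    encode_mask,
    normalize,
    reverse_complement,
    validate_iupac,
)

PLUS = "plus"
MINUS = "minus"
_STRAND_ORDER = {PLUS: 0, MINUS: 1}

#: bitmask of fully ambiguous template base, for transparency counting
_AMBIG_MASKS = frozenset(
    mask for code, mask in IUPAC_MASK.items() if code not in "ACGT" and code != GAP
)


def base_compatible(primer_base: str, template_base: str) -> bool:
    """True iff the two IUPAC codes share at least one concrete base."""
    p = normalize(primer_base)
    t = normalize(template_base)
    for ch in (p, t):
        if ch == GAP:
            raise ValidationError("gap character is not a matchable base")
        validate_iupac(ch, allow_gaps=False)
    return bool(IUPAC_MASK[p] & IUPAC_MASK[t])


@dataclass(frozen=True)
class MatchResult:
    """One primer<->template binding event.

    ``start`` is the 1-based plus-strand position of the site's leftmost
    base; the site spans ``[start, start + primer_length - 1]``. Mismatch
    offsets are 1-based from each primer end, so an offset-1 entry in
    ``mismatch_offsets_3p`` is a 3'-terminal mismatch — the kind that
    blocks polymerase extension and that specificity analyses single out.
    """

    template_id: str
    start: int
    strand: str
    primer_length: int
    mismatch_count: int
    mismatch_offsets_5p: tuple[int, ...]
    mismatch_offsets_3p: tuple[int, ...]
    ambiguous_template_positions: int = 0

    @property
    def end(self) -> int:
        """1-based inclusive plus-strand end of the site."""
        return self.start + self.primer_length - 1

    @property
    def terminal_3p_mismatch(self) -> bool:
        return 1 in self.mismatch_offsets_3p

    def __post_init__(self) -> None:
        if len(self.mismatch_offsets_5p) != self.mismatch_count or len(
            self.mismatch_offsets_3p
        ) != self.mismatch_count:
            raise ValidationError("offset lists must have length mismatch_count")


def _site_masks(primer: Primer, strand: str) -> np.ndarray:
    """Bitmask of the primer as it reads along the plus strand at the site."""
    if strand == PLUS:
        return encode_mask(primer.sequence)
    return encode_mask(reverse_complement(primer.sequence))


def match_at(
    primer: Primer, template: NucleotideSequence, start: int, strand: str = PLUS
) -> MatchResult:
    """Evaluate the primer against the template at one position and strand.

    For a plus-strand match the primer 5' end sits at ``start``; for a
    minus-strand match the primer 5' end sits at the right edge of the
    interval and offsets are bookkept accordingly.
    """
    if strand not in _STRAND_ORDER:
        raise ValidationError(f"strand must be 'plus' or 'minus', got {strand!r}")
    L = len(primer)
    if start < 1 or start + L - 1 > len(template):
        raise BoundsError(
            f"primer {primer.name} ({L} nt) at start {start} overhangs "
            f"template {template.id} ({len(template)} nt)"
        )
    site = template.residues[start - 1 : start - 1 + L]
    if GAP in site:
        raise ValidationError("template site contains gap characters; ungap first")
    pmask = _site_masks(primer, strand)
    tmask = encode_mask(site)
    bad = np.nonzero((pmask & tmask) == 0)[0]  # 0-based plus-strand offsets
    if strand == PLUS:
        off5 = tuple(int(i) + 1 for i in bad)
    else:  # primer 5' end is at the interval's right edge
        off5 = tuple(L - int(i) for i in bad)
    off5 = tuple(sorted(off5))
    off3 = tuple(sorted(L + 1 - o for o in off5))
    n_ambig = int(np.isin(tmask, list(_AMBIG_MASKS)).sum())
    return MatchResult(
        template_id=template.id,
        start=start,
        strand=strand,
        primer_length=L,
        mismatch_count=len(bad),
        mismatch_offsets_5p=off5,
        mismatch_offsets_3p=off3,
        ambiguous_template_positions=n_ambig,
    )


def _mismatch_profile(pmask: np.ndarray, tmask: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer mask at every template offset (vectorised)."""
    L = len(pmask)
    n = len(tmask)
    if L > n:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(tmask, L)
    return ((windows & pmask) == 0).sum(axis=1)


def scan(
    primer: Primer,
    template: NucleotideSequence,
    max_mismatches: int = 0,
    strands: Iterable[str] = (PLUS, MINUS),
) -> list[MatchResult]:
    """All binding sites with at most ``max_mismatches``, sorted by (start, strand).

    With ``max_mismatches=0`` and a non-degenerate primer this reduces to
    exact substring search. Returns an empty list when nothing binds.
    """
    if max_mismatches < 0:
        raise ValidationError("max_mismatches must be >= 0")
    seq = template.residues.replace(GAP, "")
    tmpl = template if GAP not in template.residues else NucleotideSequence(
        template.id, seq, template.description
    )
    tmask = encode_mask(tmpl.residues)
    hits: list[MatchResult] = []
    for strand in strands:
        if strand not in _STRAND_ORDER:
            raise ValidationError(f"unknown strand {strand!r}")
        pmask = _site_masks(primer, strand)
        profile = _mismatch_profile(pmask, tmask)
        for idx in np.nonzero(profile <= max_mismatches)[0]:
            hits.append(match_at(primer, tmpl, int(idx) + 1, strand))
    hits.sort(key=lambda m: (m.start, _STRAND_ORDER[m.strand]))
    return hits


def min_mismatches(
    primer: Primer, template: NucleotideSequence, strands: Iterable[str] = (PLUS, MINUS)
) -> tuple[int | None, MatchResult | None]:
    """Best (fewest-mismatch) site over all positions/strands, or (None, None)
    if the primer does not fit on the template at all."""
    seq = template.residues.replace(GAP, "")
    if len(primer) > len(seq):
        return None, None
    tmpl = NucleotideSequence(template.id, seq, template.description)
    tmask = encode_mask(seq)
    best: tuple[int, int, int] | None = None  # (mm, start0, strand_order)
    for strand in strands:
        profile = _mismatch_profile(_site_masks(primer, strand), tmask)
        idx = int(np.argmin(profile))
        cand = (int(profile[idx]), idx, _STRAND_ORDER[strand])
        if best is None or cand < best:
            best = cand
    assert best is not None
    strand = PLUS if best[2] == 0 else MINUS
    result = match_at(primer, tmpl, best[1] + 1, strand)
    return best[0], result


@dataclass
class SpecificityReport:
    """Group specificity of one primer: per-sequence minimum mismatch counts
    over all binding positions, split into target and non-target groups."""

    primer_name: str
    ceiling: int
    target_min_mm: dict[str, int | None] = field(default_factory=dict)
    nontarget_min_mm: dict[str, int | None] = field(default_factory=dict)
    best_sites: dict[str, MatchResult | None] = field(default_factory=dict)

    @property
    def n_target(self) -> int:
        return len(self.target_min_mm)

    @property
    def n_perfect_target(self) -> int:
        return sum(1 for mm in self.target_min_mm.values() if mm == 0)

    @property
    def pct_perfect_target(self) -> float:
        return 100.0 * self.n_perfect_target / self.n_target

    @property
    def min_nontarget_mismatches(self) -> int | None:
        vals = [mm for mm in self.nontarget_min_mm.values() if mm is not None]
        return min(vals) if vals else None

    def to_table(self) -> list[tuple[str, str, str, str, str, str]]:
        """Rows (id, group, min_mismatches, best_site_start, strand,
        terminal_3p_mismatch); min_mismatches is ``">N"`` past the ceiling."""
        rows = []
        for group, d in (("target", self.target_min_mm), ("nontarget", self.nontarget_min_mm)):
            for sid in sorted(d):
                mm = d[sid]
                site = self.best_sites.get(sid)
                if mm is None or mm > self.ceiling:
                    rows.append((sid, group, f">{self.ceiling}", "", "", ""))
                else:
                    assert site is not None
                    rows.append(
                        (sid, group, str(mm), str(site.start), site.strand,
                         str(site.terminal_3p_mismatch).lower())
                    )
        return rows

    def write(self, path: str | Path) -> None:
        header = ("id", "group", "min_mismatches", "best_site_start", "strand",
                  "terminal_3p_mismatch")
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in self.to_table():
                fh.write("\t".join(row) + "\n")


def specificity_profile(
    primer: Primer,
    targets: Sequence[NucleotideSequence],
    nontargets: Sequence[NucleotideSequence],
    max_mismatches: int = 10,
) -> SpecificityReport:
    """Profile a primer against target and non-target sequence groups.

    ``max_mismatches`` is a permissive reporting ceiling, not a match/non-match
    threshold: per-sequence minima above it are recorded as beyond-ceiling.
    """
    if not targets or not nontargets:
        raise ValidationError("both target and non-target groups must be nonempty")
    report = SpecificityReport(primer_name=primer.name, ceiling=max_mismatches)
    for group, seqs, out in (
        ("target", targets, report.target_min_mm),
        ("nontarget", nontargets, report.nontarget_min_mm),
    ):
        for seq in seqs:
            mm, site = min_mismatches(primer, seq)
            out[seq.id] = mm
            report.best_sites[seq.id] = site
    return report
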