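"""In-silico PCR, semi-nested screening, and restriction-digest RFLP typing.

Product length convention: the inclusive plus-strand span from the forward
primer's 5' base to the plus-strand image of the reverse primer's 5' base —
both primer footprints are part of the product, as on a gel. This convention
reproduces the published 441 bp product of the Peri974F/Peri1403R pair and
the 1,775 bp standard-fragment arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from . import primermatch
from .primermatch import MatchResult, MINUS, PLUS
from .seqcore import (
    NucleotideSequence,
    Primer,
    encode_mask,
    reverse_complement,
    validate_iupac,
    write_fasta,
)


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product on one template."""

    template_id: str
    forward_site: MatchResult
    reverse_site: MatchResult
    product_length: int
    product_sequence: str

    def as_sequence(self) -> NucleotideSequence:
        return NucleotideSequence(
            f"{self.template_id}|{self.forward_site.start}-{self.reverse_site.end}",
            self.product_sequence,
        )


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: recognition site plus top-strand cut offset.

    ``cut_offset`` counts bases after the site's 5' start on the top strand;
    MspI (C^CGG) has site CCGG with cut_offset 1.
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        validate_iupac(site, allow_gaps=False)
        object.__setattr__(self, "recognition_site", site)
        if not (0 <= self.cut_offset <= len(site)):
            raise ValidationError(
                f"cut_offset {self.cut_offset} outside [0, {len(site)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition_site) == self.recognition_site


MSPI = RestrictionEnzyme("MspI", "CCGG", 1)


@dataclass(frozen=True)
class RflpPattern:
    """Fragment-size fingerprint of a digested molecule."""

    fragment_lengths: tuple[int, ...]  # descending
    molecule_id: str = ""

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.fragment_lengths):
            raise ValidationError("all fragments must be >= 1 bp")
        object.__setattr__(
            self, "fragment_lengths", tuple(sorted(self.fragment_lengths, reverse=True))
        )

    @property
    def total_length(self) -> int:
        return sum(self.fragment_lengths)

    def pattern_key(self, size_tolerance_bp: int = 0) -> str:
        """Canonical text form with size binning applied (bin width = tol+1)."""
        if size_tolerance_bp <= 0:
            return "/".join(str(f) for f in self.fragment_lengths)
        w = size_tolerance_bp + 1
        return "/".join(f"~{(f // w) * w}" for f in self.fragment_lengths)


def predict_amplicons(
    fwd: Primer,
    rev: Primer,
    templates: Iterable[NucleotideSequence],
    max_mismatches: int = 2,
    forbid_3p_terminal_mismatch: bool = True,
    length_bounds: tuple[int, int] | None = None,
) -> list[AmpliconPrediction]:
    """All PCR products a primer pair would form on each template.

    A product needs a forward site on the plus strand strictly upstream of a
    reverse site (the reverse primer bound on the minus strand). An empty
    list means non-amplification. Products are sorted by length, then by
    (template, coordinates) for determinism.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValidationError("predict_amplicons needs a forward/reverse primer pair")
    products: list[AmpliconPrediction] = []
    for tmpl in templates:
        fwd_hits = [
            h for h in primermatch.scan(fwd, tmpl, max_mismatches, strands=(PLUS,))
            if not (forbid_3p_terminal_mismatch and h.terminal_3p_mismatch)
        ]
        rev_hits = [
            h for h in primermatch.scan(rev, tmpl, max_mismatches, strands=(MINUS,))
            if not (forbid_3p_terminal_mismatch and h.terminal_3p_mismatch)
        ]
        seq = tmpl.residues.replace("-", "")
        for f in fwd_hits:
            for r in rev_hits:
                if r.start <= f.end:  # reverse site must lie strictly downstream
                    continue
                length = r.end - f.start + 1
                if length_bounds is not None and not (
                    length_bounds[0] <= length <= length_bounds[1]
                ):
                    continue
                products.append(
                    AmpliconPrediction(
                        template_id=tmpl.id,
                        forward_site=f,
                        reverse_site=r,
                        product_length=length,
                        product_sequence=seq[f.start - 1 : r.end],
                    )
                )
    products.sort(
        key=lambda p: (p.product_length, p.template_id, p.forward_site.start, p.reverse_site.end)
    )
    return products


def nested_screen(
    outer: tuple[Primer, Primer],
    inner: tuple[Primer, Primer],
    templates: Sequence[NucleotideSequence],
    max_mismatches: int = 2,
    forbid_3p_terminal_mismatch: bool = True,
    length_bounds: tuple[int, int] | None = None,
) -> dict[str, dict[str, bool]]:
    """Colony-PCR style screen: an inner (semi-)nested product calls a clone
    positive only when it lies entirely within an outer product of the same
    template. Returns per-template {outer_product, inner_positive}."""
    out: dict[str, dict[str, bool]] = {}
    for tmpl in templates:
        outer_products = predict_amplicons(
            outer[0], outer[1], [tmpl], max_mismatches,
            forbid_3p_terminal_mismatch, length_bounds,
        )
        inner_products = predict_amplicons(
            inner[0], inner[1], [tmpl], max_mismatches,
            forbid_3p_terminal_mismatch, None,
        )
        inner_positive = any(
            op.forward_site.start <= ip.forward_site.start
            and ip.reverse_site.end <= op.reverse_site.end
            for op in outer_products
            for ip in inner_products
        )
        out[tmpl.id] = {
            "outer_product": bool(outer_products),
            "inner_positive": inner_positive,
        }
    return out


def _site_occurrences(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """0-based top-strand cut positions (cuts fall between seq[p-1] and seq[p])."""
    import numpy as np

    smask = encode_mask(seq)
    cuts: set[int] = set()
    site = enzyme.recognition_site
    patterns = [(site, enzyme.cut_offset)]
    if not enzyme.is_palindromic:
        # bottom-strand recognition seen on the top strand
        patterns.append(
            (reverse_complement(site), len(site) - enzyme.cut_offset)
        )
    for pat, offset in patterns:
        pmask = encode_mask(pat)
        if len(pat) > len(seq):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(smask, len(pat))
        hits = np.nonzero(((windows & pmask) == 0).sum(axis=1) == 0)[0]
        for h in hits:
            cuts.add(int(h) + offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(
    molecule: NucleotideSequence | str,
    enzyme: RestrictionEnzyme = MSPI,
    topology: str = "linear",
) -> RflpPattern:
    """Cut a molecule at every recognition-site occurrence (IUPAC-aware).

    Linear molecules give n+1 fragments for n cuts; circular give n (one
    full-length pseudo-fragment when uncut). Fragment lengths always sum to
    the molecule length.
    """
    if isinstance(molecule, str):
        molecule = NucleotideSequence("molecule", molecule)
    if topology not in ("linear", "circular"):
        raise ValidationError(f"topology must be linear|circular, got {topology!r}")
    seq = molecule.residues.replace("-", "")
    if not seq:
        raise ValidationError("empty molecule")
    cuts = _site_occurrences(seq, enzyme)
    n = len(seq)
    if topology == "linear":
        bounds = [0] + cuts + [n]
        frags = [b - a for a, b in zip(bounds, bounds[1:])]
    else:
        if not cuts:
            frags = [n]
        else:
            frags = [b - a for a, b in zip(cuts, cuts[1:])]
            frags.append(n - cuts[-1] + cuts[0])
    return RflpPattern(tuple(frags), molecule_id=molecule.id)


def rflp_group(
    amplicons: Sequence[AmpliconPrediction | NucleotideSequence],
    enzyme: RestrictionEnzyme = MSPI,
    size_tolerance_bp: int = 10,
) -> dict[str, list[str]]:
    """Group amplicons into RFLP types by fragment-size pattern.

    Two digests share a type iff they have the same fragment count and every
    rank-matched pair of (descending) lengths differs by at most
    ``size_tolerance_bp``. Grouping is greedy over a canonical ordering of
    the patterns, hence deterministic under input permutation. The number of
    keys is the number of RFLP types.
    """
    if size_tolerance_bp < 0:
        raise ValidationError("size_tolerance_bp must be >= 0")
    entries = []
    for item in amplicons:
        seq = item.as_sequence() if isinstance(item, AmpliconPrediction) else item
        pattern = digest(seq, enzyme)
        entries.append((pattern.fragment_lengths, seq.id))
    entries.sort()  # canonical order: by fragment tuple, then id
    groups: list[tuple[tuple[int, ...], list[str]]] = []
    for frags, sid in entries:
        placed = False
        for rep, members in groups:
            if len(rep) == len(frags) and all(
                abs(a - b) <= size_tolerance_bp for a, b in zip(rep, frags)
            ):
                members.append(sid)
                placed = True
                break
        if not placed:
            groups.append((frags, [sid]))
    return {
        "/".join(str(f) for f in rep): sorted(members) for rep, members in groups
    }


def load_enzymes(path: str | Path) -> list[RestrictionEnzyme]:
    """Enzyme definitions from a 3-column delimited file: name, site, offset."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0].lower() == "name":
                continue
            if len(fields) != 3:
                raise ValidationError(f"expected 3 columns, got: {line!r}")
            out.append(RestrictionEnzyme(fields[0], fields[1], int(fields[2])))
    return out


def write_amplicon_report(products: Sequence[AmpliconPrediction], path: str | Path) -> None:
    header = ("template_id", "fwd_start", "fwd_mismatches", "rev_end",
              "rev_mismatches", "product_length")
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in products:
            fh.write(
                f"{p.template_id}\t{p.forward_site.start}\t{p.forward_site.mismatch_count}\t"
                f"{p.reverse_site.end}\t{p.reverse_site.mismatch_count}\t{p.product_length}\n"
            )


def write_products_fasta(products: Sequence[AmpliconPrediction], path: str | Path) -> None:
    write_fasta([p.as_sequence() for p in products], path)
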