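"""Seeded synthetic-data generators with complete ground truth.

Every generator is a pure function of its spec and seed, and returns truth
records sufficient to score the downstream modules without re-deriving
anything: planted primer-site coordinates, group labels, chimera parents
and breakpoints, true standard-curve parameters.

The family generator emulates the kind of grouped SSU-rRNA alignment a
clade-specific assay is designed from: a shared ancestral sequence
diverged under a Kimura 2-parameter substitution process (separate
transition/transversion rates), with conserved primer-length sites planted
exactly in target members and deliberately corrupted (>= k mismatches) in
non-targets. Sequences are generated without indels, so the family doubles
as its own gapless alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .seqcore import (
    IUPAC_SETS,
    NucleotideSequence,
    reverse_complement,
)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}


@dataclass(frozen=True)
class PlantedSite:
    """One primer site to plant: exact in (some) targets, corrupted in
    non-targets.

    ``position`` is the 1-based plus-strand start of the site; reverse
    orientation plants the oligo's reverse complement there. ``n_target_exact``
    of the targets (the first ones, deterministically) receive a perfect
    concrete realisation of the oligo; remaining targets get a site with a
    mismatch count drawn from ``target_mismatch_range``; every non-target
    gets exactly ``nontarget_mismatches`` planted mismatches.
    """

    position: int
    oligo: str
    orientation: str = "forward"
    n_target_exact: int | None = None  # None -> all targets exact
    target_mismatch_range: tuple[int, int] = (2, 4)
    nontarget_mismatches: int = 3

    @property
    def length(self) -> int:
        return len(self.oligo)

    @property
    def end(self) -> int:
        return self.position + self.length - 1


@dataclass(frozen=True)
class FamilySpec:
    n_target: int = 49
    n_nontarget: int = 56
    sequence_length: int = 1800
    planted_sites: tuple[PlantedSite, ...] = ()
    substitution_rate: float = 0.05  # expected substitutions/site off-site
    ts_tv_ratio: float = 2.0  # kappa: transition/transversion rate ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 0.75):
            raise ValidationError("substitution_rate must lie in [0, 0.75]")
        if self.n_target < 1 or self.n_nontarget < 0:
            raise ValidationError("need >= 1 target")
        sites = sorted(self.planted_sites, key=lambda s: s.position)
        for a, b in zip(sites, sites[1:]):
            if b.position <= a.end:
                raise ValidationError(
                    f"planted sites overlap: [{a.position},{a.end}] and "
                    f"[{b.position},{b.end}]"
                )
        for s in sites:
            if s.position < 1 or s.end > self.sequence_length:
                raise ValidationError("planted site outside sequence bounds")


@dataclass(frozen=True)
class FamilyTruth:
    """Generator output: labelled sequences plus planted coordinates."""

    sequences: tuple[NucleotideSequence, ...]
    group_of: Mapping[str, str]  # id -> target|nontarget
    site_coords: Mapping[str, tuple[tuple[int, int], ...]]  # id -> site spans
    exact_ids: Mapping[int, tuple[str, ...]]  # site index -> ids planted exact
    spec: FamilySpec

    def targets(self) -> list[NucleotideSequence]:
        return [s for s in self.sequences if self.group_of[s.id] == "target"]

    def nontargets(self) -> list[NucleotideSequence]:
        return [s for s in self.sequences if self.group_of[s.id] == "nontarget"]


def _concretize(oligo: str, rng: np.random.Generator) -> str:
    """One concrete realisation of a degenerate oligo (uniform per position)."""
    return "".join(
        ch if ch in _BASES else sorted(IUPAC_SETS[ch])[rng.integers(len(IUPAC_SETS[ch]))]
        for ch in oligo
    )


def _mutate_k2p(seq: np.ndarray, rate: float, kappa: float, rng: np.random.Generator) -> None:
    """In-place K2P substitution sweep over an integer-coded sequence."""
    n = len(seq)
    hit = rng.random(n) < rate
    if not hit.any():
        return
    p_ts = kappa / (kappa + 2.0)
    for i in np.nonzero(hit)[0]:
        base = _BASES[seq[i]]
        if rng.random() < p_ts:
            seq[i] = _BASES.index(_TRANSITION[base])
        else:
            seq[i] = _BASES.index(_TRANSVERSIONS[base][rng.integers(2)])


def _plant_with_mismatches(
    oligo: str, n_mismatches: int, rng: np.random.Generator
) -> str:
    """A concrete site carrying exactly ``n_mismatches`` primer-incompatible
    bases; mismatch positions are drawn among positions that are not fully
    ambiguous in the oligo."""
    site = list(_concretize(oligo, rng))
    mutable = [i for i, ch in enumerate(oligo) if len(IUPAC_SETS[ch]) < 4]
    if n_mismatches > len(mutable):
        raise ValidationError(
            f"cannot plant {n_mismatches} mismatches in {oligo!r}"
        )
    pick = rng.choice(len(mutable), size=n_mismatches, replace=False)
    for idx in pick:
        i = mutable[idx]
        incompatible = sorted(set(_BASES) - IUPAC_SETS[oligo[i]])
        site[i] = incompatible[rng.integers(len(incompatible))]
    return "".join(site)


def generate_family(spec: FamilySpec) -> FamilyTruth:
    """Generate a target/non-target sequence family with planted primer sites."""
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.integers(0, 4, size=spec.sequence_length)
    names = [f"tgt{i+1:03d}" for i in range(spec.n_target)] + [
        f"ntg{i+1:03d}" for i in range(spec.n_nontarget)
    ]
    group_of = {
        name: ("target" if name.startswith("tgt") else "nontarget") for name in names
    }
    sequences = []
    site_coords: dict[str, tuple[tuple[int, int], ...]] = {}
    exact_ids: dict[int, list[str]] = {
        k: [] for k in range(len(spec.planted_sites))
    }
    for member_idx, name in enumerate(names):
        seq = ancestor.copy()
        _mutate_k2p(seq, spec.substitution_rate, spec.ts_tv_ratio, rng)
        chars = list("".join(_BASES[b] for b in seq))
        coords = []
        for site_idx, site in enumerate(spec.planted_sites):
            oligo = (
                site.oligo
                if site.orientation == "forward"
                else reverse_complement(site.oligo)
            )
            if group_of[name] == "target":
                n_exact = (
                    spec.n_target if site.n_target_exact is None else site.n_target_exact
                )
                if member_idx < n_exact:
                    planted = _concretize(oligo, rng)
                    exact_ids[site_idx].append(name)
                else:
                    lo, hi = site.target_mismatch_range
                    planted = _plant_with_mismatches(
                        oligo, int(rng.integers(lo, hi + 1)), rng
                    )
            else:
                planted = _plant_with_mismatches(
                    oligo, site.nontarget_mismatches, rng
                )
            chars[site.position - 1 : site.end] = list(planted)
            coords.append((site.position, site.end))
        sequences.append(NucleotideSequence(name, "".join(chars)))
        site_coords[name] = tuple(coords)
    return FamilyTruth(
        sequences=tuple(sequences),
        group_of=group_of,
        site_coords=site_coords,
        exact_ids={k: tuple(v) for k, v in exact_ids.items()},
        spec=spec,
    )


@dataclass(frozen=True)
class LibrarySpec:
    """Clone-library sampling: a template pool with mixing proportions and an
    optional chimera fraction (single uniform crossover between two distinct
    sampled parents)."""

    templates: tuple[NucleotideSequence, ...]
    proportions: tuple[float, ...]
    n_clones: int = 50
    chimera_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.proportions):
            raise ValidationError("templates and proportions differ in length")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError("proportions must sum to 1")
        if not (0.0 <= self.chimera_fraction < 1.0):
            raise ValidationError("chimera_fraction must lie in [0, 1)")
        if self.chimera_fraction > 0 and len(self.templates) < 2:
            raise ValidationError("chimeras need a pool of >= 2 templates")


@dataclass(frozen=True)
class CloneRecord:
    sequence: NucleotideSequence
    parents: tuple[str, ...]  # one template id, or two for a chimera
    is_chimera: bool
    breakpoint: int | None  # 1-based: clone = left[:bp] + right[bp:]


def generate_library(spec: LibrarySpec) -> list[CloneRecord]:
    """Sample clones from a template pool, optionally forming chimeras."""
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.proportions)
    clones = []
    for i in range(spec.n_clones):
        cid = f"clone{i+1:04d}"
        if spec.chimera_fraction > 0 and rng.random() < spec.chimera_fraction:
            a, b = rng.choice(len(spec.templates), size=2, replace=False, p=probs)
            left, right = spec.templates[int(a)], spec.templates[int(b)]
            bp = int(rng.integers(1, min(len(left), len(right))))
            residues = left.residues[:bp] + right.residues[bp:]
            clones.append(
                CloneRecord(
                    NucleotideSequence(cid, residues),
                    (left.id, right.id),
                    True,
                    bp,
                )
            )
        else:
            t = spec.templates[int(rng.choice(len(spec.templates), p=probs))]
            clones.append(
                CloneRecord(NucleotideSequence(cid, t.residues), (t.id,), False, None)
            )
    return clones


def generate_dilution_series(
    true_slope: float = -3.5187,
    true_intercept: float = 32.035,
    levels: int = 8,
    replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    top_copies_per_ul: float = 1e8,
):
    """Tenfold dilution series along a known standard-curve line.

    Returns :class:`~cladeamp.qpcr.DilutionPoint` objects with
    ct = slope * log10(copies) + intercept + N(0, sd).
    """
    from .qpcr import DilutionPoint

    if levels < 3:
        raise ValidationError("need >= 3 dilution levels")
    if ct_noise_sd < 0:
        raise ValidationError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for lvl in range(levels):
        copies = top_copies_per_ul / (10.0 ** lvl)
        for rep in range(replicates):
            ct = true_slope * np.log10(copies) + true_intercept
            if ct_noise_sd > 0:
                ct += rng.normal(0.0, ct_noise_sd)
            points.append(DilutionPoint(copies, float(ct), f"r{rep+1}"))
    return points


# --- synthetic stand-in reference template ---------------------------------

_REFERENCE_SITES = (
    # (plus-strand start, oligo planted on the plus strand)
    (4, "AACCTGGTTGATCCTGCCAGT"),  # universal forward (EukA) near the 5' end
    # Peri974F (which contains Peri979F as its 3' suffix) at its name position;
    # the R is concretised to G.
    (974, "GGAAACTCATCAGGGCAAGAAGATT"),
    # remainder of revcomp(Peri1004R) past the 974F footprint, so the reverse
    # primer's 5' image falls at position 1004 (Y concretised compatibly)
    (999, "GTAGGA"),
    # revcomp(Peri1403R) with its 5' image at 1414, making the
    # Peri974F/Peri1403R product span 974..1414 = 441 bp
    (1396, "CAAAATGTACACATCGCCC"),
)

REFERENCE_LENGTH = 1750


def synthetic_reference(seed: int = 20110815) -> NucleotideSequence:
    """A synthetic stand-in for the assay's reference 18S rDNA record.

    This is NOT the real GenBank record: it is a random K2P-free background
    with the assay's primer sites planted at the coordinates their names
    encode, spaced so that the specific forward/reverse pair (Peri974F /
    Peri1403R) predicts a single 441 bp product and the reverse primers'
    5' images fall at positions 1004 and 1414. Use it wherever a
    coordinate-faithful reference template is needed offline.
    """
    rng = np.random.default_rng(seed)
    chars = [_BASES[b] for b in rng.integers(0, 4, size=REFERENCE_LENGTH)]
    for start, oligo in _REFERENCE_SITES:
        chars[start - 1 : start - 1 + len(oligo)] = list(oligo)
    return NucleotideSequence(
        "synthetic_ref_18S", "".join(chars), "synthetic stand-in reference"
    )


def peritrich_like_family(seed: int = 0, n_target: int = 49, n_nontarget: int = 56,
                          n_target_exact: int = 46) -> FamilyTruth:
    """Convenience family mirroring the published design conditions: 49
    targets (46 with exact forward sites, 3 with 2-4 mismatches) and 56
    non-targets with >= 3 planted mismatches, on 1,800 nt backgrounds."""
    spec = FamilySpec(
        n_target=n_target,
        n_nontarget=n_nontarget,
        sequence_length=1800,
        planted_sites=(
            PlantedSite(
                position=974,
                oligo="GGAAACTCATCAGGRCAAGAAGATT",
                orientation="forward",
                n_target_exact=n_target_exact,
                target_mismatch_range=(2, 4),
                nontarget_mismatches=3,
            ),
            PlantedSite(
                position=1396,
                oligo="GGGCGRTGTGTACATTTTG",
                orientation="reverse",
                n_target_exact=None,
                nontarget_mismatches=3,
            ),
        ),
        substitution_rate=0.05,
        seed=seed,
    )
    return generate_family(spec)
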