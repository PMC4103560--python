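"""Kimura 2-parameter distances and furthest-neighbour OTU clustering.

The distance model corrects separately for transitions (proportion P) and
transversions (proportion Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with pairwise deletion of gapped/ambiguous sites. Saturated pairs (log
argument <= 0) get distance +inf and are never merged at a finite cutoff.

OTUs are called by agglomerative complete linkage ("furthest neighbour"):
clusters merge while the smallest maximum pairwise distance between any two
clusters is at or below the cutoff, which guarantees every OTU's internal
diameter stays within the cutoff. A 99% sequence-similarity cutoff is the
distance cutoff 0.01, the convention of clone-library OTU callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .seqcore import NucleotideSequence

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_CONCRETE = frozenset("ACGT")


def k2p_distance(a: str | NucleotideSequence, b: str | NucleotideSequence) -> float:
    """K2P distance (substitutions per site) between two aligned sequences.

    Sites where either sequence carries a gap or an ambiguity code are
    excluded (pairwise deletion). Returns ``inf`` for saturated pairs.
    """
    sa = a.residues if isinstance(a, NucleotideSequence) else a.upper().replace("U", "T")
    sb = b.residues if isinstance(b, NucleotideSequence) else b.upper().replace("U", "T")
    if len(sa) != len(sb):
        raise ValidationError(
            f"aligned lengths differ: {len(sa)} vs {len(sb)}"
        )
    valid = transitions = transversions = 0
    for x, y in zip(sa, sb):
        if x not in _CONCRETE or y not in _CONCRETE:
            continue
        valid += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if valid == 0:
        raise ValidationError("no valid (ungapped, unambiguous) site pairs")
    P = transitions / valid
    Q = transversions / valid
    arg = (1.0 - 2.0 * P - Q) * math.sqrt(max(1.0 - 2.0 * Q, 0.0))
    if arg <= 0.0:
        return math.inf
    return -0.5 * math.log(arg)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    ids: tuple[str, ...]
    values: np.ndarray  # shape (n, n), float, +inf allowed

    def __post_init__(self) -> None:
        n = len(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("diagonal must be zero")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T]
        ):
            raise ValidationError("matrix must be symmetric")
        if (v[finite] < 0).any():
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP-like text format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(
                    "inf" if not np.isfinite(x) else f"{x:.6f}" for x in self.values[i]
                )
                fh.write(f"{sid:<12s}{row}\n")


def k2p_matrix(seqs: Sequence[NucleotideSequence]) -> DistanceMatrix:
    """All-pairs K2P distances of equal-length aligned sequences."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(seqs[i], seqs[j])
    return DistanceMatrix(tuple(s.id for s in seqs), d)


@dataclass(frozen=True)
class OtuAssignment:
    """Cluster labels at a distance cutoff; complete-linkage semantics."""

    cutoff: float
    labels: Mapping[str, int]

    @property
    def n_otus(self) -> int:
        return len(set(self.labels.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, k in self.labels.items():
            out.setdefault(k, []).append(sid)
        return {k: sorted(v) for k, v in out.items()}


def cluster_furthest_neighbor(D: DistanceMatrix, cutoff: float) -> OtuAssignment:
    """Agglomerative complete-linkage clustering down to a distance cutoff.

    Merging continues while the smallest complete-linkage (maximum member
    pair) distance between clusters is <= cutoff. Ties are broken by the
    lexicographically smallest (member id, member id) pair so the partition
    is bit-reproducible under any input ordering. OTU indices are assigned
    in order of each cluster's smallest member id.
    """
    n = len(D.ids)
    if n == 0:
        return OtuAssignment(cutoff, {})
    # Work on index clusters; linkage matrix updated by the Lance-Williams
    # complete-linkage rule (pairwise max survives under max).
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    link = D.values.copy()
    np.fill_diagonal(link, np.inf)
    min_id = {i: D.ids[i] for i in range(n)}

    def tie_key(i: int, j: int) -> tuple[str, str]:
        a, b = min_id[i], min_id[j]
        return (a, b) if a <= b else (b, a)

    active = set(range(n))
    while len(active) > 1:
        best: tuple[float, tuple[str, str], int, int] | None = None
        act = sorted(active)
        for ai, i in enumerate(act):
            for j in act[ai + 1 :]:
                dij = link[i, j]
                if not np.isfinite(dij) or dij > cutoff:
                    continue
                cand = (dij, tie_key(i, j), i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            break
        _, _, i, j = best
        # merge j into i
        for k in active:
            if k in (i, j):
                continue
            link[i, k] = link[k, i] = max(link[i, k], link[j, k])
        clusters[i].extend(clusters[j])
        min_id[i] = min(min_id[i], min_id[j])
        del clusters[j]
        active.discard(j)
    ordered = sorted(clusters.values(), key=lambda idxs: min(D.ids[x] for x in idxs))
    labels: dict[str, int] = {}
    for otu_index, idxs in enumerate(ordered):
        for x in idxs:
            labels[D.ids[x]] = otu_index
    return OtuAssignment(cutoff, labels)


def cluster_per_sample(
    seqs_by_sample: Mapping[str, Sequence[NucleotideSequence]], cutoff: float
) -> dict[str, OtuAssignment]:
    """Independent per-library clusterings (the non-default alternative to one
    pooled clustering across samples)."""
    return {
        sample: cluster_furthest_neighbor(k2p_matrix(list(seqs)), cutoff)
        for sample, seqs in seqs_by_sample.items()
    }


@dataclass(frozen=True)
class OtuSharing:
    per_sample_counts: Mapping[str, int]
    n_unique_global: int
    sharing_table: Mapping[int, tuple[str, ...]]  # OTU -> samples (>= 2 only)


def shared_otus(
    assignments_by_sample: Mapping[str, Sequence[str]],
    global_assignment: OtuAssignment,
) -> OtuSharing:
    """Cross-sample OTU accounting against one pooled (global) clustering.

    ``assignments_by_sample`` maps each sample to the sequence ids it
    contributed; every sequence must appear in exactly one sample.
    """
    seen: dict[str, str] = {}
    for sample, ids in assignments_by_sample.items():
        for sid in ids:
            if sid in seen:
                raise ValidationError(
                    f"sequence {sid!r} appears in samples {seen[sid]!r} and {sample!r}"
                )
            if sid not in global_assignment.labels:
                raise ValidationError(f"sequence {sid!r} missing from global clustering")
            seen[sid] = sample
    per_sample = {
        sample: len({global_assignment.labels[sid] for sid in ids})
        for sample, ids in assignments_by_sample.items()
    }
    otu_samples: dict[int, set[str]] = {}
    for sid, sample in seen.items():
        otu_samples.setdefault(global_assignment.labels[sid], set()).add(sample)
    sharing = {
        otu: tuple(sorted(samples))
        for otu, samples in sorted(otu_samples.items())
        if len(samples) >= 2
    }
    n_unique = len({global_assignment.labels[sid] for sid in seen})
    return OtuSharing(per_sample, n_unique, sharing)


def write_otu_table(
    assignment: OtuAssignment,
    path: str | Path,
    sample_of: Mapping[str, str] | None = None,
) -> None:
    """Delimited OTU table: sequence id, sample, OTU index."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tsample\totu\n")
        for sid in sorted(assignment.labels):
            sample = sample_of.get(sid, "") if sample_of else ""
            fh.write(f"{sid}\t{sample}\t{assignment.labels[sid]}\n")
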