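# Methods

## Scope and model system

`cladeamp` models the computational side of a clade-specific SSU-rRNA
PCR/qPCR assay: evaluating degenerate primers against target and non-target
sequence groups, predicting amplicons and restriction patterns, clustering
amplicon sequences into OTUs, and converting qPCR cycle thresholds into
absolute rDNA copy numbers. The bundled primer panel (EukA plus the
peritrich-specific Peri974F/Peri979F/Peri1004R/Peri1403R) serves as the
worked example throughout; every operation is generic over any primer set
and sequence groups.

## Matching model

Primer–template matching is **ungapped and substitution-only**. Each IUPAC
symbol denotes a set of concrete bases; a primer base and a template base
match iff their sets intersect. Degenerate primers are matched as
compatible-set bitmasks in a single pass rather than by enumerating
expansions; the test suite verifies the two routes agree. Consequences to
be aware of:

- A template `N` matches any primer base, which can inflate perfect-match
  counts; `MatchResult` carries a count of ambiguous template positions
  inside the site for transparency.
- No indel tolerance: a bulged primer is reported as a run of mismatches.
  This mirrors BLAST/probe-database-style mismatch tabulation used when
  assessing primer specificity.

Coordinates are 1-based and inclusive on the template plus strand.
Minus-strand hits are reported by the plus-strand interval they occupy;
mismatch offsets are always counted from the primer's own 5′ and 3′ ends,
so "offset-1 from 3′" means the extension-blocking terminal position on
either strand. No numeric mismatch threshold separates "match" from
"non-match" anywhere in the library — thresholds are parameters of the
calling operation (defaults below).

## Primer design

`design_candidates` slides windows (default 18–26 nt, bracketing typical
specific-primer lengths) across a grouped alignment. For each window the
target rows are collapsed to the minimal degenerate consensus covering every
base at frequency ≥ `min_base_freq` (default 0.10); windows with a
gap-majority column, or consensus degeneracy above `max_degeneracy`
(default 8), are rejected.

Scoring is two-stage. A vectorised column-space screen first discards
windows that cannot meet the thresholds (the in-place mismatch count is an
upper bound on the scan minimum, so coverage passes found here are sound;
non-target separation is only bounded and must be confirmed). Surviving
windows are then re-scored by scanning the **ungapped** member sequences at
every offset — PCR acts on unaligned molecules, so alignment artifacts must
neither mask nor fabricate binding — and the reported
`target_coverage` (fraction of targets within `max_target_mismatches`,
default 1) and `min_nontarget_mismatches` (default threshold 3) are the
scan-based values. Ranking is (non-target separation desc, coverage desc,
degeneracy asc, start column asc, orientation), which is deterministic;
reverse-orientation candidates are reverse-complemented before scoring so
all numbers refer to the primer as synthesised. The threshold defaults are
engineering choices — the original manual design process they formalise had
no stated objective function.

## In-silico PCR and RFLP

A product requires a forward-primer site on the plus strand strictly
upstream of a reverse-primer site (bound on the minus strand). **Product
length is the inclusive span** from the forward primer's 5′ base to the
plus-strand image of the reverse primer's 5′ base — both footprints count,
as on a gel; this is the convention under which the specific pair yields
441 bp from reference coordinates 974–1414. Default screening parameters
are `max_mismatches=2` with 3′-terminal mismatches disallowed: single
5′-end mismatches are treated as tolerated (they barely affect priming)
while a 3′-terminal mismatch is treated as discriminating, which is how
such assays separate near-target from target sequences in practice.

Semi-nested screening calls a template positive only when an inner product
lies entirely within an outer product of the same template, so the
inner-positive set is a subset of the outer-positive set by construction.

Digests cut at every IUPAC-compatible occurrence of the recognition site
(both strands; for palindromic sites such as MspI's C^CGG one strand
suffices). Linear molecules give n+1 fragments from n cuts, circular give
n (one pseudo-fragment when uncut); lengths always sum to the molecule
length. RFLP types group digests whose sorted fragment lists match rank by
rank within `size_tolerance_bp` (default 10 bp, a stand-in for agarose gel
resolution — no physical value is claimed). Grouping is greedy over a
canonical ordering of patterns, hence deterministic under input
permutation.

## Distances and OTUs

K2P distances use pairwise deletion (sites with a gap or ambiguity in
either sequence are dropped), matching the behaviour of the classic
distance programs this workflow descends from. Saturated pairs (log
argument ≤ 0) get +∞ and never merge at a finite cutoff.

Clustering is agglomerative complete linkage: merge while the smallest
maximum-member-pair distance between clusters is ≤ the cutoff. The
implementation updates linkage by the Lance–Williams max rule; ties are
broken by the lexicographically smallest (member id, member id) pair and
OTU indices are ordered by smallest member id, making partitions
bit-reproducible under relabelling. The 99% similarity convention maps to
a 0.01 distance cutoff. Cross-sample accounting defaults to **one pooled
clustering** with per-sample OTU tallies and a sharing table;
`cluster_per_sample` exposes independent per-library clustering as the
alternative mode for users who reconcile libraries by hand.

## qPCR model

The standard curve is ordinary least squares of C_T on log₁₀(copies µL⁻¹),
with replicate wells averaged per dilution level by default (a flag pools
them). Efficiency is E = (10^(−1/k) − 1) × 100% with k < 0; note that the
published curve this package models prints its slope magnitude with a
positive sign, which is physically impossible and inconsistent with the
printed 92.4% efficiency — the slope is therefore taken as −3.5187
throughout, and `efficiency()` negates a positive input with a warning.

Standard mass converts to molecules as a/(L·660)·6.022×10²³ (a in g µL⁻¹,
L the fragment length in bp, default 1,775 for the bundled assay's linear
standard). Sample copy numbers invert the curve, then scale through the
volume chain copies µL⁻¹ × (extract µL / template µL) × (1000 / filtered
mL) to copies per litre of source water. The limit of detection is an
**input** (the copies of the faintest reliably detected standard, expressed
in cell equivalents by dividing by rDNA copies per cell); no statistical
LOD model is fitted. Samples beyond the LOD C_T are flagged
below-detection rather than suppressed.

## Synthetic data

The generators emulate the inputs such an assay consumes, with complete
truth records:

- **Families**: a random ancestral sequence diverged per member under a
  two-rate (transition/transversion, default κ = 2) substitution process at
  a per-site rate (default 0.05, typical of congeneric 18S divergence), so
  distances measured downstream match the K2P model by construction.
  Planted sites are exact in a configurable number of targets and carry
  exactly k primer-incompatible bases elsewhere (defaults: 2–4 mismatches
  in non-exact targets, ≥3 in non-targets, matching the separation a usable
  specific primer shows). No indels are simulated, so a family is its own
  gapless alignment. The default family mirrors the published design
  conditions: 49 targets (46 with exact forward sites) and 56 non-targets.
- **Clone libraries**: multinomial template sampling; chimeras (optional)
  are single uniform crossovers between two distinct parents and are
  *labelled*, never detected — chimera detection is out of scope.
- **Dilution series**: tenfold steps from 10⁸ copies µL⁻¹ with Gaussian
  C_T noise around a known line (default truth −3.5187/32.035).
- **Reference template**: `synthetic_reference()` is a synthetic stand-in
  for the assay's reference 18S record — random background with the panel's
  binding sites planted at the coordinates the primer names encode
  (974/979/1004/1414), spaced so the specific pair predicts a single
  441 bp product. It is coordinate-faithful, not sequence-faithful.

What passing tests on these data do **not** show: robustness to alignment
error, rRNA secondary-structure-driven rate heterogeneity, indels,
amplification bias, or real chimera structures — none of which the
generators emulate.

## Numerical and degenerate-input choices

- Expected GC% of a degenerate oligo is the mean over expansions (the only
  convention reproducing the published panel's GC column); not
  configurable.
- Tm is reported as (min, max) over expansions; both provided formulas
  depend on an expansion only through its G+C count, so large degeneracies
  use per-position extremes instead of enumeration. Positions like W
  (A/T) leave Tm unchanged, so a degenerate oligo can legitimately have
  min = max. Neither method claims to reproduce any published Tm column;
  the default is the salt-adjusted GC formula at [Na⁺] = 50 mM.
- Zero-valid-site K2P pairs, empty sequence groups, degenerate dilution
  designs, and out-of-bounds coordinates raise typed errors rather than
  returning sentinels.
- All simulation entry points take an explicit seed; identical seeds give
  bit-identical outputs.

## Problem sizes used by the test suite

Simulation-backed checks run at sizes chosen to exercise the statistics
while keeping the suite quick on one CPU: 1,000 random molecules for digest
conservation, 200 seeded matrices of ≤ 8 sequences against the naive
clustering oracle, 500 noisy dilution series (σ_CT = 0.15, 8 levels × 3
replicates) for slope recovery, 100 seeded families of 12 targets + 6
non-targets (260 nt) for planted-primer recovery, and a 50-clone library
with 11 planted target clones for the nested screen.

## Known limitations

- No thermodynamic binding model: mismatch counts, not ΔG, drive all
  specificity calls.
- No multiple-alignment computation; alignments are inputs.
- No chimera detection, tree building, rarefaction, or melt-curve
  analysis.
- The RFLP gel-resolution tolerance and all design thresholds are
  documented defaults, not measured quantities.
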