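# Methods

## The statistic

For a taxon group with n aligned homeobox fragments of L sites, the
within-group divergence is the arithmetic mean of the uncorrected
pairwise p-distances over all C(n, 2) pairs,

    p̄ = (2 / n(n−1)) Σ_{i<j} p_ij ,   p_ij = (differing resolved sites) /
                                              (sites resolved in both)

expressed in percent. The absolute divergence rate of a (gene, group)
cell is the quotient r = p̄(%) / t, with t the minimum age in million
years of the group's oldest assignable crown-group fossil. No multiple-
hit correction is applied and fossil ages carry no uncertainty, so r is
a deliberate *underestimate* of the true substitution rate: saturation,
among-site rate variation and incomplete fragments all bias p̄ downward,
and a minimum age can only inflate the denominator. The insect vs
non-insect contrast compares one rate value per (gene, group) cell —
8 insect values (one per Hox gene) against the 52 non-insect values —
which is the construction under which the summary statistics reproduce
the published 0.06 ± 0.003 (mean ± SE) and 0.04. The published
non-insect dispersion of 0.02 matches the sample SD of the 52 values,
not their SE; both are reported and neither interpretation is asserted.

## Distances

* Characters other than the plain bases (or the 20 amino acids) —
  gaps `-`, missing `?`, and all IUPAC ambiguity codes — count as
  *missing*, never as match or mismatch.
* `pairwise` deletion (default) drops unresolved sites per pair;
  `complete` masks any site unresolved in *any* sequence of the set for
  every pair. Which convention the original distance software used for
  these data is not recorded, so both are exposed; pairwise deletion is
  the default because the underlying fragments are often incomplete.
* A pair with zero comparable sites has an *undefined* distance (NaN in
  matrices, an exception in scalar calls) — explicitly not 0.
* Internal values keep full precision; p̄ is rounded to 1 decimal and
  rates to 3 decimals only at report time.

## Mann–Whitney U test

U is computed from mid-ranks (ties contribute half-wins). The exact path
evaluates the permutation null over random relabelings of the pooled
sample: for tie-free pools by the classical rank-sum counting recursion
(feasible at any practical n), with ties by explicit enumeration of the
C(n1+n2, n1) labelings, refused above a bound of 2×10⁵. The normal path
standardises U with mean n₁n₂/2 and the tie-corrected variance
n₁n₂/12 [(N+1) − Σ(t³−t)/(N(N−1))]. Two-sided p = 2·min(tails), capped
at 1. No continuity correction is applied by default — the convention is
explicit and switchable; note that the exact two-sided tail includes the
observed U's point mass, so the continuity-corrected normal tail is its
proper large-sample analog (the uncorrected one undershoots it by about
the point-mass probability, ~0.01 at n = 20 per side in mid-range).
`method="auto"` prefers the exact path whenever it is feasible.

On the published rate table (8 insect vs 52 non-insect values, with
ties) the auto path takes the tie-corrected normal approximation and
yields U = 358, z ≈ 3.26, two-sided p ≈ 1.1 × 10⁻³. The published
claim is "p < 0.001"; recomputation from the rounded printed
p-distances lands marginally above that bound, so this package asserts
the reproducible property (insects stochastically larger, p < 0.01) and
reports the exact value rather than guaranteeing the printed bound.

## Neighbor joining and classification

NJ follows the standard Q-criterion agglomeration with two explicit
conventions: ties in the Q minimisation break toward the
lexicographically lowest pair of clade labels (determinism), and
negative limb lengths are clamped to zero with the deficit moved to the
sister limb (path-length preserving; additive inputs never trigger it).
On additive matrices the generating topology and branch lengths are
recovered exactly; this is property-tested against randomly generated
trees and cross-checked against an independent NJ implementation.

Family assignment scores a query fragment (aligned to the homeodomain
frame, positions 1–60) against per-family reference panels by mean
p-distance over shared resolved positions. The margin to the runner-up
family drives the ambiguity flag: default margin 0 with an absolute-tie
rule, plus a `short_window` flag when fewer than 30 positions are
covered — short fragments are the classifier's known failure mode, the
Scr/Antp case being the canonical example (identical over positions
20–45; discriminable only at positions 1, 4, 6, 7 and 60).
`diagnostic_positions` reports frame positions where two panels'
observed residue sets are disjoint. Nucleotide queries are translated
with the standard code; the reading frame must be supplied.

## In-silico PCR

Degeneracy is the product of per-position IUPAC cardinalities. Site
search slides the primer over both strands counting mismatches
uniformly — no 3′-anchored weighting, the simplest defensible model for
validating primer definitions rather than predicting annealing
efficiency. Product lengths include both primer footprints; under this
convention templates constructed from the packaged pairs' own expansions
reproduce the published 160/128/145/164 bp fragments exactly. Melting
temperatures use the Wallace rule Tm = 2(A+T) + 4(G+C) evaluated over
GC-minimal and GC-maximal expansions, as advisory output only (the
packaged annealing temperatures are empirical optima, not predictions).

## Synthetic data

Groups are simulated as star phylogenies: one random ancestral fragment,
every lineage evolving independently, so each lineage carries half the
pair divergence (rate × age / 2) and expectations stay exact — matching
an analysis built on a group-mean p-distance, and mirroring the fact
that the fossil age bounds the *pairwise* split. Per site and lineage
the substitution count is Poisson; the per-lineage intensity h is found
by inverting the chosen saturation curve so that the expected pairwise
p-distance equals rate × age / 100 exactly:

* `linear` (default): events replace the site with a uniform draw from
  the full alphabet; the mismatch curve is p = 0.75 (1 − e^(−2h)), and
  targets at or above the 0.75 asymptote are capped just below it.
* `jukes-cantor`: events jump to one of the three other bases;
  p = 0.75 (1 − e^(−(4/3) d)) with d = 2h the pairwise load; targets
  ≥ 0.75 raise a "saturated" error.

Defaults are the study's conditions: nucleotide alphabet, L = 75 (the
modal site count), and the study-shaped design takes its 60 (gene,
group) cells, taxa counts (2–16) and fossil ages (195–528 My) from the
packaged reference table, with true rates 0.06 %/My for insect cells
and 0.04 %/My for the rest — the two summary means of the real data.
All randomness derives from the single spec seed (NumPy `SeedSequence`
spawning per group), so bundles are byte-reproducible.

What the simulator deliberately omits: within-group tree structure,
among-site rate variation, codon structure, indels and alignment error,
base-composition bias, and incomplete fragments. Passing recovery and
power tests therefore show that the *pipeline arithmetic and test* are
sound under the stated model, not that real homeobox data meet these
assumptions — on real data the same omissions are acknowledged sources
of rate underestimation.

## Problem sizes used in checks

The automated checks use 200 replicate groups (n = 30 taxa, 75 sites)
for parameter recovery at 0.066 %/My over 396 My, 30 study-shaped
replicates for the power check (declaring insects faster at two-sided
p < 0.05), 100 random additive matrices (n ≤ 12) for NJ recovery, and
2000 null replicates (20 per side) for the type-I error of the normal
path at α = 0.05. These sizes give Monte-Carlo errors comfortably below
the margins being tested while keeping the whole suite fast.

## Known limitations

* Fossil minimum ages make every rate a lower bound; between-group rate
  *contrasts* are only meaningful insofar as the calibration biases are
  comparable across groups.
* Uncorrected p-distances saturate; at the observed divergences
  (p̄ up to ~39%) multiple hits are certainly present.
* The pooled non-insect sample mixes genes and groups and treats the 52
  cells as exchangeable; gene identity is not modelled as a factor.
* The classifier is a nearest-panel method with no statistical support
  values; it flags ambiguity but does not quantify assignment
  uncertainty.
* Primer site search treats all mismatch positions equally; real PCR is
  far more sensitive to 3′-terminal mismatches.
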