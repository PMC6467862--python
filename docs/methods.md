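# Methods

## Model and rationale

Microsatellite alleles are tandem repeats whose lengths change mostly by
single-repeat insertions or deletions. The package's dissimilarity
measures therefore treat the repeat-count difference between two alleles,
Δ = |as_i − as_k| / ltr, as a parsimony estimate of the number of
unreversed mutation events separating them. Two modelling axes generate
the eight measures:

* **How loci are weighted.** Under a constant mutation rate (SMMc) every
  repeat step costs the same at every locus, so profile dissimilarity is
  the summed matching cost over loci, either normalised by the summed
  locus ranges (`SMMc`, in [0, 1]) or left as mutations per haploid
  genome copy (`MANMC`, unbounded). Under locus-specific rates (SMMv) a
  step at a slowly-mutating locus signals more divergence time, so each
  locus is first normalised by its own observed repeat-count range
  Δmax(j) (ρ = Δ/Δmax) and the normalised costs are averaged. The
  infinite alleles model (IAM) discards size information entirely
  (binary allele identity), and Bruvo's distance applies the saturating
  transform 1 − 2^(−Δ) per allele pair.
* **Absolute vs squared steps.** Each size-based measure has a squared
  variant (`*_sq`) replacing Δ by Δ² (and Δmax by Δmax² in the
  normalisers), the random-walk-motivated scaling where displacement
  grows as the square root of elapsed steps.

For ploidy q > 1 the per-locus cost is the minimum-cost perfect matching
between the two allele multisets — the assignment problem — solved with
`scipy.optimize.linear_sum_assignment` (exact, O(q³), deterministic). A
brute-force enumerator over all q! matchings is kept as an independent
test oracle (guarded to q ≤ 6). Among equal-cost matchings only the cost
is contractual; every downstream quantity depends on nothing else.

Key structural facts, all property-tested: the non-squared measures are
metrics (minimum-cost matching of a metric allele distance is a metric;
triangle inequality is *not* claimed for the squared variants); `SMMc`
equals `MANMC` × n / ΣΔmax on complete data, so the two are perfectly
Mantel-correlated; all measures are invariant to allele order within a
genotype and to locus order.

## Data handling

* Genotype tables are CSV/TSV with one row per individual and q columns
  per locus (`locus.1 … locus.q`); a locus table supplies repeat-unit
  lengths. Locus size bounds — and hence Δmax — are always recomputed
  from the data on load.
* Allele sizes may include primer/flank length; every formula uses size
  *differences*, so no flank correction is applied or needed.
* Off-ladder sizes: repeat differences are rounded to whole repeat
  units; a residual above 0.25 repeat units is an error, smaller
  residuals are rounded with a logged warning. Real capillary data drift
  by ±1 bp; this keeps such drift from fabricating fractional mutations.
* Missing data: a locus is missing as a whole (partial calls are an
  error). Pairwise sums — numerators *and* denominators of the ratio
  measures — run over the n_AB loci typed in both individuals. A pair
  sharing no usable locus raises an error rather than yielding NaN,
  which would silently corrupt clustering downstream.
* Monomorphic loci (Δmax = 0) would make ρ 0/0, so they are excluded
  from the range-normalised measures (`SMMv`, `SMMv_sq`) and from `IAM`
  (whose definition presumes polymorphism), with a warning; they are
  retained for `SMMc`/`MANMC`/`BRUVO`, contributing zero to both sides
  of the ratio.
* Homozygotes repeat the same size q times; a single value per locus is
  accepted only for haploids.

## Simulator

The generator emulates the evolution of haploid SSR lineages as a
random walk: an ancestral allele of 200 repeats evolves for G
generations; each generation a locus mutates with probability p and, if
it does, gains or loses one repeat with equal probability. p is drawn
from a Beta distribution truncated at 0.5 whose *realised* draws have
mean 0.25 and variance 0.02 — the shape parameters (a = 1.105,
b = 1.452) are calibrated against the closed-form truncated moments,
since naive moment-matching before rejection would shift the realised
mean to ≈0.23 and the variance to ≈0.014. `mut_var = 0` degenerates to a
point mass, useful for calibration tests.

Rate modes: `constant` redraws one p per generation shared by all loci
(loci differ only through the random placement of events); `variable`
draws one p per locus once and holds it fixed, making rate an intrinsic
locus property. The wording that motivated these modes admits either
reading per mode; this assignment is the one under which "variable rate
across loci" is literally true, and both behaviours remain available.

Sampling designs:

* **clonal** — one linked multi-locus trajectory; each individual is the
  trajectory state at an age drawn uniformly on [0, G]. Pairwise
  generation difference is |age_i − age_k| (mean ≈ G/3 for uniform
  ages), and the mutation difference is the exact count of events
  between the two sampling times, from trajectory bookkeeping. A "single
  pedigree" is thus one trajectory observed at many time points — the
  reading consistent with mean pairwise separation ≈ max/3.
* **sexual** — eight independent single-locus trajectories; each
  individual draws an independent age per locus, and the genotype's age
  is the mean. This decouples genetic distance from mean-age difference
  (tested: |r| < 0.15 at n = 100).
* **groups** — clonal sampling structured into blocks: group g's members
  are sampled at ages g·age_step + U{0..spread} (defaults: 100 groups of
  20, step 15, spread ≤ 9), so between-group age gaps are multiples of
  the step. The trajectory is evolved exactly long enough to cover the
  oldest group.

A repeat count reaching 0 aborts the run: with a 200-repeat ancestor and
the timescales used here it indicates a misconfiguration, and silent
reflection would bias the walk. Fixed seeds give bit-identical
populations.

What the generator does *not* emulate: diploid/polyploid inheritance,
recombination, selection, multi-repeat (two-phase) jumps, genotyping
noise, or allele-size constraints. Passing tests therefore show that the
measures recover known separation under an idealised one-step SMM, not
that they are robust to real-data artefacts.

## Analysis toolkit

* **Through-origin fits** report slope, RMSE, CV(RMSE) = RMSE/mean(y),
  MAE, and *two* coefficients of determination: the centred R²
  (1 − SSres/Σ(y−ȳ)², strict, can go negative for a misspecified
  zero-intercept model) and the uncentred R² (1 − SSres/Σy², the
  convention statistical software prints for models forced through the
  origin; algebraically cos²(x, y), hence inflated for positive data).
  Both are exposed because the two answer different questions; summary
  comparisons in this package quote the uncentred value, the convention
  under which zero-intercept fit quality is conventionally reported.
  In regressions of dissimilarity against known separation the
  dissimilarity is the response, so RMSE is on the dissimilarity scale
  and comparable across measures.
* **Mantel test**: Pearson r over off-diagonal upper triangles; p by
  joint row/column permutation (default 9999, two-sided, +1-corrected),
  own implementation for seeded determinism, cross-checked in tests
  against scikit-bio's.
* **UPGMA** via scipy average-linkage; the tree keeps the linkage matrix
  so cophenetic distances (2 × MRCA height) are exact rather than
  re-derived from rounded Newick branch lengths. Newick export carries
  branch lengths; ties break deterministically inside scipy's linkage.
* **Robinson–Foulds**: symmetric difference of unrooted bipartition sets
  (via dendropy) normalised by 2(n − 3), the maximum for binary trees —
  UPGMA output is binary by construction. Reported as the proportion of
  partitions not shared.
* **DAD** (distance of average differences between groups) is the plain
  mean dissimilarity over cross pairs, diagonal 0. The DAD literature
  also contains within-group-corrected variants; the plain between-group
  mean is used here and this choice is deliberate and documented — with
  near-coeval groups the correction is negligible.

## The age-group experiment

`group_age_regression` wires the pieces together: simulate age groups,
compute a pairwise matrix, aggregate to DAD, regress DAD through the
origin on the known between-group age gaps. At the default scale (100
groups × 20 genotypes, ≈1,500 generations, ≈370 mutation events per
locus) the walk is deep in its diffusive regime: expected displacement
grows as the square root of the age gap, so the plain constant-rate
measure fits a straight line through the origin imperfectly (uncentred
R² ≈ 0.88 averaged over seeds), and — because the expected *squared*
displacement is exactly linear in elapsed generations — the squared
variant fits comparably rather than worse. The acceptance suite records
the expectation that the squared variant degrades markedly; under this
simulator that degradation does not materialise, and the corresponding
test documents the discrepancy rather than hiding it.

## Numerical choices and limitations

* Matrix printing uses 6 decimals; round-trips are exact at that
  precision. Square PHYLIP output uses relaxed (whitespace-delimited)
  labels.
* The truncated-Beta calibration solves a 2-D root-finding problem once
  per (mean, variance, cap) and caches it; the closed form
  ∫₀^c x f_{a,b} = (a/(a+b)) F_{a+1,b}(c) keeps it exact.
* Haploid pairwise matrices take a vectorised all-pairs path (no
  matching needed at q = 1), verified in tests against the general
  per-pair path; the general path scales as O(N² n q³).
* Individual-level R_ST is not implemented: variance-component
  definitions are ambiguous for single-individual "populations".
  Unequal-ploidy comparisons (Bruvo's virtual-allele scheme) and
  two-phase mutation models are out of scope.
* Problem sizes in tests and the acceptance script (6–10 simulation
  replicates, populations ≤ 2,000) were chosen as the package's standard
  desk-scale defaults; all reported statistics stabilise well below
  these sizes.
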