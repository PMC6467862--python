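# ssrdissim

Mutation-model-aware dissimilarity between multilocus microsatellite
(SSR) genotypes of haploid, diploid, or polyploid individuals — plus a
stepwise-mutation simulator with exact ground truth and a toolkit for
comparing the resulting dissimilarity structures (through-origin fits,
Mantel tests, UPGMA/cophenetic distances, Robinson–Foulds, group-level
DAD distances).

## Who this is for

Population geneticists working with codominant SSR markers who need
*between-individual* genetic distances — for clustering, ordination, or
exploratory structure analysis — and who want the distance to reflect an
explicit model of how microsatellite alleles evolve, rather than treating
every pair of distinct alleles as equally different.

## The measures

An allele at locus *j* is recorded as a fragment size in bp; with repeat
unit length ltr_j, two alleles differ by Δ_j = |as_i − as_k| / ltr_j
repeat units. Under a one-step stepwise mutation model (SMM), Δ is the
parsimony count of unreversed single-repeat insertions/deletions
separating the alleles. Normalising by the locus's maximum observed
repeat difference Δmax(j) gives ρ_j = Δ_j / Δmax(j) ∈ [0, 1], a relative
divergence time that discounts loci with wide ranges (a proxy for fast,
locus-specific mutation).

For two q-ploid genotypes the q alleles of one individual are matched
one-to-one to the q alleles of the other so the summed allele distance is
minimal — the assignment problem, solved exactly by the Hungarian
algorithm (q! candidate matchings; 24 for a tetraploid). With minimal
matching costs ρ_min, Δ_min, δ_min per locus, the profile measures over n
loci are:

| measure   | definition                                        | model |
|-----------|---------------------------------------------------|-------|
| `smmv`    | (1/nq) Σ_j ρ_min(A,B;j)                           | SMM, variable rates |
| `smmv-sq` | same with squared normalised differences          | |
| `smmc`    | (1/q) Σ_j Δ_min(A,B;j) / Σ_j Δmax(j)              | SMM, constant rate |
| `smmc-sq` | squared steps over squared ranges                 | |
| `manmc`   | (1/nq) Σ_j Δ_min(A,B;j) — mutations per genome copy | SMM, constant rate |
| `manmc-sq`| squared-step analogue                             | |
| `iam`     | (1/nq) Σ_j δ_min(A,B;j), binary allele identity   | infinite alleles |
| `bruvo`   | (1/nq) Σ_j min-matched Σ (1 − 2^(−Δ))             | generalised SMM |

All except `manmc`/`manmc-sq` live in [0, 1]. Missing data are handled
per pair: every sum (numerator and denominator) runs over the n_AB loci
typed in both individuals. Bruvo's allele distance 1 − 2^(−Δ) saturates
within a few repeat units — alleles ≥ 4 repeats apart are ≥ 0.9375
distant — which is why it tracks true mutational separation poorly once
repeat differences grow; the package includes it for comparison.

Two *population-level* statistics, Goldstein's ASD (D₁) and the squared
mean-size difference (δμ)², are provided under a `legacy` command purely
to demonstrate why they must not be used between individuals: D₁ > 0 for
two identical heterozygotes, and (δμ)² = 0 for clearly different
genotypes with equal allele-size means.

## Worked example

Four diploid individuals at one dinucleotide locus, with identical mean
allele sizes (sizes in bp; i1 = 41/53 is 11/17 in repeat units):

```csv
individual_id,L1.1,L1.2
i1,41,53
i2,43,51
i3,45,49
i4,43,51
```

```sh
ssrdissim dissim genotypes.csv loci.csv --measure manmc --out manmc.csv
```

```
id,i1,i2,i3,i4
i1,0.000000,1.000000,2.000000,1.000000
i2,1.000000,0.000000,1.000000,0.000000
i3,2.000000,1.000000,0.000000,1.000000
i4,1.000000,0.000000,1.000000,0.000000
```

Read: i2 and i4 carry the same genotype, so their distance is 0; turning
i1 = (11,17) into i2 = (12,16) needs one repeat step per allele copy
under the best matching (11↔12, 17↔16), i.e. 1.0 mutations per haploid
genome copy; i1 and i3 are two steps apart per copy. The same matrix
under `--measure smmc` is rescaled into [0, 1] by the locus range
(Δmax = 6): 1/6, 1/3, ... — the two measures are always perfectly
(Mantel r = 1) correlated on complete data. By contrast the legacy
(δμ)² statistic calls *all six pairs identical* (every genotype has mean
14), and ASD D₁ assigns the identical pair i2, i4 a distance of 8.

The simulator generates haploid populations by a random walk of
single-repeat steps (ancestor 200 repeats; per-generation mutation
probability drawn with mean 0.25, variance 0.02, capped at 0.5) and
records the exact number of generations and mutation events separating
every sampled pair:

```sh
ssrdissim simulate --mode groups --seed 1 --out sim/
ssrdissim dissim sim/genotypes.csv sim/loci.csv --measure smmc --out sim/d.csv
ssrdissim tree sim/d.csv --out sim/upgma.nwk --cophenetic sim/coph.csv
```

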