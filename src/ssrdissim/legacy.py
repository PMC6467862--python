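"""Population-level allele-size statistics applied at the individual level.

Goldstein's average squared distance (ASD, D1) and the squared difference
of mean allele sizes ((delta-mu)^2, SMD) were designed to compare
*populations* of microsatellite allele frequencies.  Treating a single
genotype as a one-entity population breaks both: D1 can be positive for
two *identical* heterozygous genotypes (it averages over all ordered
allele cross-pairs, including within-genotype spread), while (delta-mu)^2
is blind to any within-genotype spread and reports 0 for clearly distinct
genotypes with equal allele-size means.  They are provided here for
demonstration, not for analysis.

Inputs are single-locus calls expressed in repeat counts (not bp).
"""

from __future__ import annotations

from .io import DataValidationError


def _check(calls_a, calls_b) -> None:
    if calls_a is None or calls_b is None:
        raise DataValidationError("legacy measures require non-missing calls")
    if len(calls_a) != len(calls_b):
        raise DataValidationError(
            f"ploidy mismatch: {len(calls_a)} vs {len(calls_b)}"
        )


def mean_allele_size(calls) -> float:
    """Arithmetic mean repeat count of one genotype's alleles."""
    if calls is None or len(calls) == 0:
        raise DataValidationError("empty or missing call")
    return sum(calls) / len(calls)


def asd_d1(calls_a, calls_b) -> float:
    """Average squared distance D1 over all q^2 ordered allele cross-pairs,
    each weighted 1/q * 1/q.

    Note the pathology: ``asd_d1(A, A) > 0`` for any heterozygous A.
    """
    _check(calls_a, calls_b)
    q = len(calls_a)
    return sum((a - b) ** 2 for a in calls_a for b in calls_b) / q ** 2


def smd_delta_mu_sq(calls_a, calls_b) -> float:
    """Squared difference of mean allele sizes, (delta-mu)^2.

    Note the pathology: any two genotypes with equal mean repeat counts are
    reported as identical, however different their alleles.
    """
    _check(calls_a, calls_b)
    return (mean_allele_size(calls_a) - mean_allele_size(calls_b)) ** 2
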