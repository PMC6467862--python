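"""Distances between two SSR alleles at one locus.

Each metric encodes a different assumption about how microsatellite alleles
evolve:

* ``DELTA`` — absolute repeat-count difference; under a one-step stepwise
  mutation model (SMM) this is the parsimony count of unreversed
  insertions/deletions separating the alleles.
* ``DELTA_SQ`` — squared repeat difference, the random-walk analogue in
  which displacement grows with the square root of the number of steps.
* ``RHO`` / ``RHO_SQ`` — the same differences normalised by the locus's
  maximum observed repeat difference, so that loci with wide size ranges
  (a proxy for fast mutation) weigh each repeat step less.
* ``IAM_BINARY`` — infinite alleles model: any two distinct alleles are
  equally distant (0/1).
* ``BRUVO`` — 1 - 2^(-delta), a saturating transform of the repeat
  difference derived from a generalised SMM; it approaches 1 so quickly
  that alleles four or more repeats apart are nearly maximally distant.
"""

from __future__ import annotations

import enum

from .io import LocusDef, MonomorphicLocusError, round_repeat_units


class AlleleMetricKind(enum.Enum):
    """Allele-level distance kinds understood by the assignment engine."""

    DELTA = "delta"
    DELTA_SQ = "delta_sq"
    RHO = "rho"
    RHO_SQ = "rho_sq"
    IAM_BINARY = "iam_binary"
    BRUVO = "bruvo"


def repeat_difference(size_i: float, size_k: float, locus: LocusDef) -> int:
    """Repeat-count difference |size_i - size_k| / ltr, rounded to the
    nearest whole repeat unit."""
    return round_repeat_units(
        abs(size_i - size_k) / locus.ltr,
        context=f"locus {locus.locus_id}",
    )


def rho(size_i: float, size_k: float, locus: LocusDef) -> float:
    """Range-normalised repeat difference delta / delta_max, in [0, 1].

    Dividing by the locus's maximum observed repeat difference converts the
    raw step count into a relative divergence time, comparable across loci
    with different (locus-specific) mutation rates.
    """
    if locus.is_monomorphic:
        raise MonomorphicLocusError(
            f"locus {locus.locus_id} is monomorphic; range-normalised "
            "distance is undefined"
        )
    return repeat_difference(size_i, size_k, locus) / locus.delta_max


def rho_sq(size_i: float, size_k: float, locus: LocusDef) -> float:
    """Squared range-normalised repeat difference, in [0, 1]."""
    return rho(size_i, size_k, locus) ** 2


def delta_sq(size_i: float, size_k: float, locus: LocusDef) -> int:
    """Squared repeat-count difference (unnormalised)."""
    return repeat_difference(size_i, size_k, locus) ** 2


def iam_binary(size_i: float, size_k: float,
               locus: LocusDef | None = None) -> int:
    """Infinite-alleles distance: 0 for identical alleles, else 1.

    Sizes are compared after snapping to the repeat ladder when a locus is
    given, so sub-repeat-unit drift does not split alleles.
    """
    if locus is not None:
        return int(repeat_difference(size_i, size_k, locus) != 0)
    return int(size_i != size_k)


def bruvo_allele(size_i: float, size_k: float, locus: LocusDef) -> float:
    """Bruvo's allele distance 1 - 2^(-delta), in [0, 1).

    Saturates fast: delta = 4 already gives 0.9375, so alleles more than a
    few repeats apart are all nearly maximally distant.
    """
    return 1.0 - 2.0 ** (-repeat_difference(size_i, size_k, locus))


_DISPATCH = {
    AlleleMetricKind.DELTA: repeat_difference,
    AlleleMetricKind.DELTA_SQ: delta_sq,
    AlleleMetricKind.RHO: rho,
    AlleleMetricKind.RHO_SQ: rho_sq,
    AlleleMetricKind.IAM_BINARY: iam_binary,
    AlleleMetricKind.BRUVO: bruvo_allele,
}


def allele_distance(kind: AlleleMetricKind, size_i: float, size_k: float,
                    locus: LocusDef) -> float:
    """Evaluate the allele distance of the given kind."""
    return float(_DISPATCH[kind](size_i, size_k, locus))
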