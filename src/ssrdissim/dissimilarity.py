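"""Profile-level dissimilarity between multilocus SSR genotypes.

At every locus the q alleles of one individual are matched one-to-one to
the q alleles of the other so that the summed allele distance is minimal —
the classical assignment problem, solved exactly with the Hungarian
algorithm (``scipy.optimize.linear_sum_assignment``).  The minimal matching
cost is the parsimony estimate of the mutational separation at that locus;
the profile measures aggregate it across loci under different
mutation-model assumptions:

======== ============================================ ==========
measure  allele metric / aggregation                  range
======== ============================================ ==========
SMMv     rho (range-normalised), mean over loci       [0, 1]
SMMv_sq  rho^2, mean over loci                        [0, 1]
SMMc     raw repeat steps / summed locus ranges       [0, 1]
SMMc_sq  squared steps / summed squared ranges        [0, 1]
IAM      binary allele identity, mean mismatch        [0, 1]
MANMC    mean repeat steps per locus per genome copy  [0, inf)
MANMC_sq squared-step analogue of MANMC               [0, inf)
BRUVO    1 - 2^(-delta) per allele pair, mean         [0, 1]
======== ============================================ ==========

Missing data are handled per pair: sums (numerator *and* denominator) run
over the loci typed in both individuals.  Monomorphic loci are excluded
from the range-normalised measures (SMMv, SMMv_sq) and from IAM, where the
normalisation or the polymorphism premise would otherwise break; they are
retained for SMMc/MANMC/BRUVO, to which they contribute zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import (
    Dataset,
    DissimilarityMatrix,
    LocusDef,
    MEASURES,
    NoSharedLociError,
    ROUNDING_TOLERANCE,
    SSRError,
    SSRProfile,
)
from .metrics import AlleleMetricKind, allele_distance

logger = logging.getLogger("ssrdissim")

_BRUTE_FORCE_MAX_PLOIDY = 6

#: allele metric driving the assignment problem for each profile measure
_MEASURE_METRIC: dict[str, AlleleMetricKind] = {
    "SMMv": AlleleMetricKind.RHO,
    "SMMv_sq": AlleleMetricKind.RHO_SQ,
    "SMMc": AlleleMetricKind.DELTA,
    "SMMc_sq": AlleleMetricKind.DELTA_SQ,
    "IAM": AlleleMetricKind.IAM_BINARY,
    "MANMC": AlleleMetricKind.DELTA,
    "MANMC_sq": AlleleMetricKind.DELTA_SQ,
    "BRUVO": AlleleMetricKind.BRUVO,
}

#: measures that only use polymorphic loci
_POLYMORPHIC_ONLY = frozenset({"SMMv", "SMMv_sq", "IAM"})


def normalize_measure(name: str) -> str:
    """Map user-facing spellings (``smmc-sq``, ``bruvo`` ...) to canonical
    measure names."""
    key = name.strip().lower().replace("-", "_")
    for canon in MEASURES:
        if key == canon.lower():
            return canon
    raise ValueError(
        f"unknown measure {name!r}; expected one of {', '.join(MEASURES)}"
    )


@dataclass(frozen=True)
class MatchResult:
    """Solution of the per-locus assignment problem.

    ``pairing`` lists (index into A's alleles, index into B's alleles);
    ``cost`` is the minimal summed allele distance.  Among equal-cost
    matchings the solver's first optimum is reported — every downstream
    quantity depends only on the cost.
    """

    locus_id: str
    pairing: tuple[tuple[int, int], ...]
    cost: float


def best_match(calls_a, calls_b, locus: LocusDef,
               metric: AlleleMetricKind) -> MatchResult:
    """Minimum-cost perfect matching of two equal-ploidy allele sets.

    Exact O(q^3) Hungarian solution of the q x q allele-distance matrix.
    """
    if calls_a is None or calls_b is None:
        raise SSRError(f"missing call at locus {locus.locus_id}")
    q = len(calls_a)
    if len(calls_b) != q:
        raise SSRError(
            f"locus {locus.locus_id}: ploidy mismatch {q} vs {len(calls_b)}"
        )
    cost = np.empty((q, q))
    for i, a in enumerate(calls_a):
        for k, b in enumerate(calls_b):
            cost[i, k] = allele_distance(metric, a, b, locus)
    rows, cols = linear_sum_assignment(cost)
    return MatchResult(
        locus_id=locus.locus_id,
        pairing=tuple(zip(rows.tolist(), cols.tolist())),
        cost=float(cost[rows, cols].sum()),
    )


def enumerate_matchings(q: int):
    """All q! perfect matchings of q alleles against q alleles, as
    permutations of B-indices."""
    return itertools.permutations(range(q))


def brute_force_match(calls_a, calls_b, locus: LocusDef,
                      metric: AlleleMetricKind) -> MatchResult:
    """Exhaustive minimum over all q! matchings; the independent oracle for
    :func:`best_match` (guarded to q <= 6)."""
    q = len(calls_a)
    if q > _BRUTE_FORCE_MAX_PLOIDY:
        raise SSRError(
            f"brute-force matching limited to q <= {_BRUTE_FORCE_MAX_PLOIDY}"
        )
    dist = [[allele_distance(metric, a, b, locus) for b in calls_b]
            for a in calls_a]
    best_cost = math.inf
    best_perm = None
    for perm in enumerate_matchings(q):
        c = sum(dist[i][perm[i]] for i in range(q))
        if c < best_cost:
            best_cost = c
            best_perm = perm
    return MatchResult(
        locus_id=locus.locus_id,
        pairing=tuple((i, k) for i, k in enumerate(best_perm)),
        cost=float(best_cost),
    )


def locus_dissimilarity(calls_a, calls_b, locus: LocusDef,
                        metric: AlleleMetricKind) -> float:
    """Per-locus dissimilarity: minimal matching cost divided by ploidy.

    With ``RHO``/``RHO_SQ`` this is the per-genome-copy relative mutation
    count at the locus, in [0, 1].
    """
    q = len(calls_a)
    return best_match(calls_a, calls_b, locus, metric).cost / q


# ---------------------------------------------------------------------------
# Profile-level measures (general, any ploidy)

def _pair_value(A: SSRProfile, B: SSRProfile, loci, measure: str) -> tuple[float, int]:
    """(dissimilarity, number of loci used) for one pair of profiles."""
    q = A.ploidy
    metric = _MEASURE_METRIC[measure]
    poly_only = measure in _POLYMORPHIC_ONLY

    shared = [j for j in range(len(loci))
              if A.calls[j] is not None and B.calls[j] is not None]
    if not shared:
        raise NoSharedLociError(
            f"individuals {A.individual_id!r} and {B.individual_id!r} share "
            "no typed locus"
        )
    used = [j for j in shared if not loci[j].is_monomorphic] if poly_only else shared
    if not used:
        raise NoSharedLociError(
            f"individuals {A.individual_id!r} and {B.individual_id!r}: no "
            f"shared polymorphic locus for measure {measure}"
        )

    costs = [best_match(A.calls[j], B.calls[j], loci[j], metric).cost
             for j in used]
    total = float(sum(costs))
    n_ab = len(used)

    if measure in ("SMMv", "SMMv_sq", "IAM", "MANMC", "MANMC_sq", "BRUVO"):
        value = total / (n_ab * q)
    elif measure == "SMMc":
        denom = sum(loci[j].delta_max for j in used)
        value = total / (q * denom) if denom else 0.0
    elif measure == "SMMc_sq":
        denom = sum(loci[j].delta_max ** 2 for j in used)
        value = total / (q * denom) if denom else 0.0
    else:  # pragma: no cover
        raise ValueError(measure)
    return value, n_ab


def _measure_fn(measure: str):
    def fn(A: SSRProfile, B: SSRProfile, dataset: Dataset) -> float:
        return _pair_value(A, B, dataset.loci, measure)[0]
    return fn


#: Mean range-normalised matching cost per locus (variable mutation rates).
dissimilarity_smmv = _measure_fn("SMMv")
#: Squared-difference analogue of :func:`dissimilarity_smmv`.
dissimilarity_smmv_sq = _measure_fn("SMMv_sq")
#: Summed repeat steps over summed locus ranges (constant mutation rate).
dissimilarity_smmc = _measure_fn("SMMc")
#: Squared-difference analogue of :func:`dissimilarity_smmc`.
dissimilarity_smmc_sq = _measure_fn("SMMc_sq")
#: Mean minimal allele-mismatch proportion (infinite alleles model).
dissimilarity_iam = _measure_fn("IAM")
#: Minimum average number of mutations per haploid genome copy.
dissimilarity_manmc = _measure_fn("MANMC")
#: Squared-difference analogue of :func:`dissimilarity_manmc`.
dissimilarity_manmc_sq = _measure_fn("MANMC_sq")
#: Mean Bruvo matching cost per locus per genome copy.
dissimilarity_bruvo = _measure_fn("BRUVO")


# ---------------------------------------------------------------------------
# Pairwise matrices

def pairwise_matrix(dataset: Dataset, measure: str) -> DissimilarityMatrix:
    """Pairwise dissimilarity matrix over all individuals of a dataset.

    Haploid datasets take a vectorised path (no matching needed at q = 1);
    the general path solves the assignment problem pair by pair.  Any pair
    with no shared typed locus raises :class:`NoSharedLociError`.
    """
    measure = normalize_measure(measure)
    if len(dataset.individuals) < 2:
        raise SSRError("pairwise matrix needs at least 2 individuals")
    if dataset.ploidy == 1:
        values, n_shared = _pairwise_haploid(dataset, measure)
    else:
        n = len(dataset.individuals)
        values = np.zeros((n, n))
        n_shared = np.zeros((n, n), dtype=int)
        for i in range(n):
            for k in range(i + 1, n):
                v, nab = _pair_value(
                    dataset.individuals[i], dataset.individuals[k],
                    dataset.loci, measure,
                )
                values[i, k] = values[k, i] = v
                n_shared[i, k] = n_shared[k, i] = nab
    return DissimilarityMatrix(
        ids=dataset.ids, values=values, measure=measure, n_shared=n_shared,
    )


def _pairwise_haploid(dataset: Dataset, measure: str):
    """Vectorised all-pairs computation for q = 1 (no matching required:
    the locus cost is the allele distance itself)."""
    loci = dataset.loci
    poly_only = measure in _POLYMORPHIC_ONLY
    N = len(dataset.individuals)

    sizes = np.full((N, len(loci)), np.nan)
    for i, ind in enumerate(dataset.individuals):
        for j, call in enumerate(ind.calls):
            if call is not None:
                sizes[i, j] = call[0]
    present = ~np.isnan(sizes)

    num = np.zeros((N, N))
    count = np.zeros((N, N), dtype=int)
    denom = np.zeros((N, N))

    for j, loc in enumerate(loci):
        if poly_only and loc.is_monomorphic:
            continue
        s = sizes[:, j]
        valid = np.outer(present[:, j], present[:, j])
        raw = np.abs(s[:, None] - s[None, :]) / loc.ltr
        delta = np.rint(raw)
        resid = np.abs(raw - delta)
        bad = valid & (resid > ROUNDING_TOLERANCE)
        if bad.any():
            raise SSRError(
                f"locus {loc.locus_id}: pairwise repeat residual exceeds "
                f"{ROUNDING_TOLERANCE} repeat units"
            )
        if (valid & (resid > 1e-9)).any():
            logger.warning("locus %s: off-ladder differences rounded",
                           loc.locus_id)
        delta = np.where(valid, delta, 0.0)

        if measure in ("SMMv", "SMMv_sq"):
            c = delta / loc.delta_max
            if measure == "SMMv_sq":
                c = c ** 2
        elif measure == "IAM":
            c = (delta != 0).astype(float)
        elif measure in ("SMMc", "MANMC"):
            c = delta
        elif measure in ("SMMc_sq", "MANMC_sq"):
            c = delta ** 2
        elif measure == "BRUVO":
            c = np.where(valid, 1.0 - 2.0 ** (-delta), 0.0)
        else:  # pragma: no cover
            raise ValueError(measure)
        num += np.where(valid, c, 0.0)
        count += valid
        if measure == "SMMc":
            denom += valid * loc.delta_max
        elif measure == "SMMc_sq":
            denom += valid * loc.delta_max ** 2

    off = ~np.eye(N, dtype=bool)
    if (count[off] == 0).any():
        i, k = np.argwhere((count == 0) & off)[0]
        raise NoSharedLociError(
            f"individuals {dataset.ids[i]!r} and {dataset.ids[k]!r} share "
            f"no usable locus for measure {measure}"
        )
    if measure in ("SMMc", "SMMc_sq"):
        values = np.divide(num, denom, out=np.zeros_like(num),
                           where=denom > 0)
    else:
        values = num / np.maximum(count, 1)
    np.fill_diagonal(values, 0.0)
    return values, count
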