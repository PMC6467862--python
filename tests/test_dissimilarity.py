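import numpy as np
import pytest

import ssrdissim as sd
from ssrdissim.dissimilarity import _pair_value, normalize_measure
from conftest import random_dataset

MEASURE_FNS = {
    "SMMv": sd.dissimilarity_smmv,
    "SMMv_sq": sd.dissimilarity_smmv_sq,
    "SMMc": sd.dissimilarity_smmc,
    "SMMc_sq": sd.dissimilarity_smmc_sq,
    "IAM": sd.dissimilarity_iam,
    "MANMC": sd.dissimilarity_manmc,
    "MANMC_sq": sd.dissimilarity_manmc_sq,
    "BRUVO": sd.dissimilarity_bruvo,
}


def haploid(locus_reps, ids_reps, ltr=2):
    """Build a haploid dataset from repeat counts.

    ``ids_reps``: {individual: [repeats per locus]}.
    """
    n_loci = len(next(iter(ids_reps.values())))
    calls = [[None if r is None else (float(100 + ltr * r),) for r in reps]
             for reps in ids_reps.values()]
    return sd.build_dataset([f"L{j}" for j in range(n_loci)],
                            [ltr] * n_loci, list(ids_reps), calls, ploidy=1)


class TestWorkedFixture:
    def test_smmc(self, four_diploids):
        i1, i2 = four_diploids.individuals[:2]
        assert sd.dissimilarity_smmc(i1, i2, four_diploids) == \
            pytest.approx(1 / 6)

    def test_smmc_sq(self, four_diploids):
        i1, i2 = four_diploids.individuals[:2]
        # minimal squared matching (1^2 + 1^2) over q * delta_max^2
        assert sd.dissimilarity_smmc_sq(i1, i2, four_diploids) == \
            pytest.approx(1 / 36 * 2 / 2)

    def test_manmc(self, four_diploids):
        inds = four_diploids.individuals
        assert sd.dissimilarity_manmc(inds[0], inds[1], four_diploids) == 1.0
        assert sd.dissimilarity_manmc(inds[1], inds[3], four_diploids) == 0.0

    def test_pairwise_manmc_matrix(self, four_diploids):
        m = sd.pairwise_matrix(four_diploids, "manmc")
        assert m[("i2", "i4")] == 0.0
        assert m[("i1", "i2")] == 1.0
        assert m[("i1", "i3")] == 2.0

    def test_smmv_equals_smmc_for_single_locus(self, four_diploids):
        # one locus: both normalise by the same delta_max
        i1, i2 = four_diploids.individuals[:2]
        assert sd.dissimilarity_smmv(i1, i2, four_diploids) == \
            pytest.approx(sd.dissimilarity_smmc(i1, i2, four_diploids))


class TestHaploidExamples:
    def test_smmv_single_full_range_locus(self):
        reps = {
            "A": [10] * 8, "B": [10] * 7 + [20],
            "C": [15] * 7 + [12],  # makes the first 7 loci polymorphic
        }
        ds = haploid(None, reps)
        A, B = ds.individuals[0], ds.individuals[1]
        assert sd.dissimilarity_smmv(A, B, ds) == pytest.approx(1 / 8)
        assert sd.dissimilarity_smmv_sq(A, B, ds) == pytest.approx(1 / 8)

    def test_manmc_one_locus_two_steps(self):
        reps = {"A": [10] * 8, "B": [10] * 7 + [12]}
        ds = haploid(None, reps)
        A, B = ds.individuals
        assert sd.dissimilarity_manmc(A, B, ds) == pytest.approx(2 / 8)

    def test_manmc_sq_single_locus(self):
        ds = haploid(None, {"A": [10], "B": [13]})
        A, B = ds.individuals
        assert sd.dissimilarity_manmc_sq(A, B, ds) == pytest.approx(9.0)

    def test_single_locus_haploid_extreme_pair(self):
        ds = haploid(None, {"A": [10], "B": [20]})
        A, B = ds.individuals
        assert sd.dissimilarity_smmc_sq(A, B, ds) == pytest.approx(1.0)
        assert sd.dissimilarity_smmc(A, B, ds) == pytest.approx(1.0)

    @pytest.mark.parametrize("delta,expected", [(1, 0.5), (10, 1 - 2 ** -10)])
    def test_bruvo_saturation(self, delta, expected):
        ds = haploid(None, {"A": [10], "B": [10 + delta]})
        A, B = ds.individuals
        assert sd.dissimilarity_bruvo(A, B, ds) == pytest.approx(expected)

    def test_iam_haploid_is_mismatch_proportion(self):
        reps = {"A": [1, 2, 3, 4], "B": [1, 9, 3, 7], "C": [5, 6, 7, 8]}
        ds = haploid(None, reps)
        A, B = ds.individuals[0], ds.individuals[1]
        assert sd.dissimilarity_iam(A, B, ds) == pytest.approx(2 / 4)


class TestDiploidIam:
    def test_half_mismatch(self):
        ds = sd.build_dataset(
            ["L"], [2], ["A", "B"], [[(100, 100)], [(100, 104)]], ploidy=2,
        )
        A, B = ds.individuals
        assert sd.dissimilarity_iam(A, B, ds) == pytest.approx(0.5)

    def test_assignment_matches_allele_count_intersection_q2(self):
        # for diploids the assignment-based mismatch equals
        # q - |multiset intersection|
        rng = np.random.default_rng(11)
        for _ in range(200):
            ra = rng.integers(0, 6, size=2)
            rb = rng.integers(0, 6, size=2)
            ds = sd.build_dataset(
                ["L"], [2], ["A", "B", "C"],
                [[tuple(100.0 + 2 * r for r in ra)],
                 [tuple(100.0 + 2 * r for r in rb)],
                 [(100.0, 112.0)]], ploidy=2,
            )
            A, B = ds.individuals[0], ds.individuals[1]
            inter = 0
            remaining = list(rb)
            for x in ra:
                if x in remaining:
                    remaining.remove(x)
                    inter += 1
            expected = (2 - inter) / 2
            assert sd.dissimilarity_iam(A, B, ds) == pytest.approx(expected)


class TestMissingData:
    def test_average_over_shared_loci_only(self):
        reps = {"A": [10, 14, None], "B": [12, 14, 20], "C": [20, 20, 10]}
        ds = haploid(None, reps)
        A, B = ds.individuals[0], ds.individuals[1]
        # locus 3 missing in A: MANMC averages the 2-step difference at the
        # first locus over the 2 shared loci only
        assert sd.dissimilarity_manmc(A, B, ds) == pytest.approx(2 / 2)
        _, nab = _pair_value(A, B, ds.loci, "MANMC")
        assert nab == 2

    def test_no_shared_loci_fails_loudly(self):
        reps = {"A": [10, None], "B": [None, 20], "C": [12, 22]}
        ds = haploid(None, reps)
        with pytest.raises(sd.NoSharedLociError):
            sd.pairwise_matrix(ds, "MANMC")

    def test_smmc_ratio_restricted_to_shared_loci(self):
        reps = {"A": [10, 14, None], "B": [12, 14, 20], "C": [20, 24, 10]}
        ds = haploid(None, reps)
        A, B = ds.individuals[0], ds.individuals[1]
        dmax1 = ds.loci[0].delta_max
        dmax2 = ds.loci[1].delta_max
        assert sd.dissimilarity_smmc(A, B, ds) == \
            pytest.approx(2 / (dmax1 + dmax2))


class TestIdentities:
    def test_smmc_is_manmc_rescaled_on_complete_data(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, n_ind=8, n_loci=5, ploidy=2)
        mc = sd.pairwise_matrix(ds, "SMMc")
        mm = sd.pairwise_matrix(ds, "MANMC")
        total_range = sum(l.delta_max for l in ds.loci)
        np.testing.assert_allclose(
            mc.values, mm.values * ds.n_loci / total_range, atol=1e-12,
        )

    def test_duplicated_individual_gives_zero_matrix_rows(self):
        ds = haploid(None, {"A": [10, 20], "B": [10, 20], "C": [12, 24]})
        for meas in MEASURE_FNS:
            m = sd.pairwise_matrix(ds, meas)
            assert m[("A", "B")] == 0.0


class TestInvariances:
    @pytest.mark.parametrize("measure", sorted(MEASURE_FNS))
    def test_allele_and_locus_order_invariance(self, measure):
        rng = np.random.default_rng(42)
        ds = random_dataset(rng, n_ind=5, n_loci=4, ploidy=3)
        base = sd.pairwise_matrix(ds, measure).values

        # permute allele order within every genotype
        perm_calls = [
            [tuple(rng.permutation(c)) if c is not None else None
             for c in ind.calls]
            for ind in ds.individuals
        ]
        ds_a = sd.build_dataset([l.locus_id for l in ds.loci],
                                [l.ltr for l in ds.loci], ds.ids,
                                perm_calls, ploidy=3)
        np.testing.assert_allclose(sd.pairwise_matrix(ds_a, measure).values,
                                   base, atol=1e-12)

        # permute locus order
        order = rng.permutation(ds.n_loci)
        ds_l = sd.build_dataset([ds.loci[j].locus_id for j in order],
                                [ds.loci[j].ltr for j in order], ds.ids,
                                [[ind.calls[j] for j in order]
                                 for ind in ds.individuals], ploidy=3)
        np.testing.assert_allclose(sd.pairwise_matrix(ds_l, measure).values,
                                   base, atol=1e-12)

    @pytest.mark.parametrize("measure", sorted(MEASURE_FNS))
    def test_haploid_fast_path_matches_general_path(self, measure):
        rng = np.random.default_rng(17)
        ds = random_dataset(rng, n_ind=10, n_loci=5, ploidy=1,
                            missing_rate=0.15)
        fast = sd.pairwise_matrix(ds, measure)
        n = len(ds.individuals)
        for i in range(n):
            for k in range(i + 1, n):
                v, nab = _pair_value(ds.individuals[i], ds.individuals[k],
                                     ds.loci, measure)
                assert fast.values[i, k] == pytest.approx(v, abs=1e-12)
                assert fast.n_shared[i, k] == nab


class TestMetricStructure:
    @pytest.mark.parametrize("measure",
                             ["SMMv", "SMMc", "IAM", "MANMC", "BRUVO"])
    def test_triangle_inequality_on_random_triples(self, measure):
        rng = np.random.default_rng(23)
        ds = random_dataset(rng, n_ind=12, n_loci=4, ploidy=2)
        m = sd.pairwise_matrix(ds, measure).values
        n = m.shape[0]
        for _ in range(500):
            i, j, k = rng.choice(n, size=3, replace=False)
            assert m[i, k] <= m[i, j] + m[j, k] + 1e-9

    @pytest.mark.parametrize("measure", sorted(MEASURE_FNS))
    def test_range_symmetry_zero_diagonal(self, measure):
        rng = np.random.default_rng(31)
        ds = random_dataset(rng, n_ind=8, n_loci=4, ploidy=2)
        m = sd.pairwise_matrix(ds, measure)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert np.all(m.values >= 0)
        if measure not in ("MANMC", "MANMC_sq"):
            assert np.all(m.values <= 1 + 1e-12)

    def test_zero_iff_identical_on_shared_loci(self):
        ds = haploid(None, {"A": [10, 20], "B": [10, 21], "C": [12, 24]})
        for meas in MEASURE_FNS:
            m = sd.pairwise_matrix(ds, meas)
            assert m[("A", "B")] > 0


class TestMeasureNames:
    @pytest.mark.parametrize("alias,canon", [
        ("smmc-sq", "SMMc_sq"), ("bruvo", "BRUVO"), ("iam", "IAM"),
        ("MANMC_SQ", "MANMC_sq"),
    ])
    def test_aliases(self, alias, canon):
        assert normalize_measure(alias) == canon

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            normalize_measure("nei")
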