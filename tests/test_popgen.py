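"""Reproduction-selection model: recursion, likelihood and endpoint tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cagefit import popgen
from cagefit.popgen import (
    DegenerateSelectionError,
    FitnessParams,
    GenotypeDist,
    allele_freq_from_counts,
    apply_selection,
    cage_log_likelihood,
    endpoint_binomial_test,
    equilibrium_frequency,
    gamete_allele_freqs,
    hwe_genotype_freqs,
    simulate_trajectory,
)

from conftest import make_cage_table

# (h, s) giving exactly the study's fitted fitnesses (1, 1.23, 0.62)
FIT_PAPER = FitnessParams(h=-0.23 / 0.38, s=-0.38)

hs_pairs = st.tuples(
    st.floats(-1, 1, allow_nan=False), st.floats(-0.99, 1, allow_nan=False)
)


class TestHweGenotypeFreqs:
    @pytest.mark.parametrize(
        "p1, expected",
        [
            (0.5, (0.25, 0.50, 0.25)),
            (1.0, (1.0, 0.0, 0.0)),
            (0.6, (0.36, 0.48, 0.16)),
        ],
    )
    def test_binomial_expansion(self, p1, expected):
        assert hwe_genotype_freqs(p1) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("p1", [-0.1, 1.1])
    def test_rejects_out_of_range(self, p1):
        with pytest.raises(ValueError):
            hwe_genotype_freqs(p1)


class TestApplySelection:
    def test_neutral_is_identity(self):
        f = GenotypeDist(0.25, 0.5, 0.25)
        assert apply_selection(f, FitnessParams(0.3, 0.0)) == pytest.approx(f)

    def test_paper_fitnesses(self):
        # w = (1, 1.23, 0.62), sum of weighted freqs = 1.02
        out = apply_selection(GenotypeDist(0.25, 0.5, 0.25), FIT_PAPER)
        assert out == pytest.approx((0.24510, 0.60294, 0.15196), abs=5e-6)

    def test_monomorphic_fixed_point(self):
        f = GenotypeDist(1.0, 0.0, 0.0)
        assert apply_selection(f, FitnessParams(0.9, -0.9)) == pytest.approx(f)

    def test_degenerate_raises(self):
        # only R2R2 present but its fitness is zero
        with pytest.raises(DegenerateSelectionError):
            apply_selection(GenotypeDist(0.0, 0.0, 1.0), FitnessParams(0.0, -1.0))


class TestFitnessParams:
    @pytest.mark.parametrize("h, s", [(-1.5, 0.0), (0.0, 1.5), (2.0, -2.0)])
    def test_bounds_enforced(self, h, s):
        with pytest.raises(ValueError):
            FitnessParams(h, s)

    def test_fitness_vector(self):
        assert FIT_PAPER.fitnesses == pytest.approx([1.0, 1.23, 0.62])


def test_gamete_allele_freqs():
    assert gamete_allele_freqs(GenotypeDist(0.25, 0.5, 0.25)) == 0.5
    assert gamete_allele_freqs(GenotypeDist(1.0, 0.0, 0.0)) == 1.0
    assert gamete_allele_freqs(GenotypeDist(0.24510, 0.60294, 0.15196)) == pytest.approx(
        0.54657, abs=1e-6
    )


class TestTrajectory:
    def test_neutral_constant(self):
        traj = simulate_trajectory(FitnessParams(0.4, 0.0), 11)
        p1 = traj.larval[:, 0] + 0.5 * traj.larval[:, 1]
        assert p1 == pytest.approx(np.full(11, 0.5), abs=0)

    def test_overdominant_monotone_toward_equilibrium(self):
        traj = simulate_trajectory(FIT_PAPER, 50)
        p1 = traj.larval[:, 0] + 0.5 * traj.larval[:, 1]
        assert np.all(np.diff(p1) > 0)
        assert np.all(p1 < 0.61 / 0.84 + 1e-12)

    def test_dominant_advantage_drives_r1_out(self):
        # w = (1, 2, 2): selection against R1R1 only, so p1 declines
        # monotonically toward 0 (hyperbolically once R1 is rare)
        traj = simulate_trajectory(FitnessParams(1.0, 1.0), 500)
        p1 = traj.larval[:, 0] + 0.5 * traj.larval[:, 1]
        assert np.all(np.diff(p1) < 0)
        assert p1[-1] < 0.01

    def test_generation_indexing_one_based(self):
        traj = simulate_trajectory(FIT_PAPER, 3)
        assert traj.larval_at(1) == pytest.approx((0.25, 0.5, 0.25))
        with pytest.raises(IndexError):
            traj.larval_at(0)

    @settings(max_examples=50, deadline=None)
    @given(hs=hs_pairs)
    def test_frequency_conservation(self, hs):
        traj = simulate_trajectory(FitnessParams(*hs), 20)
        for stage in (traj.larval, traj.post_selection):
            assert np.allclose(stage.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(stage >= -1e-15) and np.all(stage <= 1 + 1e-15)
        assert np.all((traj.gamete_p1 >= 0) & (traj.gamete_p1 <= 1))


class TestEquilibrium:
    def test_paper_overdominance(self):
        assert equilibrium_frequency(FIT_PAPER) == pytest.approx(0.61 / 0.84, abs=1e-12)

    def test_additive_has_none(self):
        assert equilibrium_frequency(FitnessParams(0.5, 0.4)) is None

    def test_overdominance_closed_form(self):
        # w = (1, 1.2, 0.8): p1* = (1.2 - 0.8) / (2*1.2 - 1 - 0.8) = 2/3.
        # (A perfectly symmetric w = (1, 1.2, 1) is unreachable in the
        # (h, s) parametrization, where w22 = 1 forces w12 = 1.)
        fp = FitnessParams(h=-1.0, s=-0.2)
        assert equilibrium_frequency(fp) == pytest.approx(0.4 / 0.6)

    @settings(max_examples=25, deadline=None)
    @given(
        h=st.floats(-1.0, -0.25, allow_nan=False),
        s=st.floats(-0.9, -0.25, allow_nan=False),
    )
    def test_trajectory_converges_to_closed_form(self, h, s):
        # h < 0, s < 0 is exactly the overdominant sector of the (h, s) box;
        # the chosen ranges keep the heterozygote advantage > 0.05 so that
        # 10,000 generations suffice for 1e-10 convergence
        fp = FitnessParams(h, s)
        eq = equilibrium_frequency(fp)
        w11, w12, w22 = fp.fitnesses
        assert w12 > w11 and w12 > w22 and eq is not None
        traj = simulate_trajectory(fp, 10_000)
        assert abs(traj.gamete_p1[-1] - eq) < 1e-10


def naive_log_likelihood(data: pd.DataFrame, h: float, s: float) -> float:
    """Independent oracle: pure-Python generation-by-generation recursion."""
    w12, w22 = 1.0 + h * s, 1.0 + s
    freqs = {}
    p = 0.5
    for gen in range(1, int(data["generation"].max()) + 1):
        q = 1.0 - p
        larv = (p * p, 2 * p * q, q * q)
        freqs[gen] = larv
        tot = larv[0] * 1.0 + larv[1] * w12 + larv[2] * w22
        post = (larv[0] / tot, larv[1] * w12 / tot, larv[2] * w22 / tot)
        p = post[0] + post[1] / 2.0
    logL = 0.0
    for row in data.itertuples():
        f = freqs[int(row.generation)]
        for n, fg in zip((row.n_R1R1, row.n_R1R2, row.n_R2R2), f):
            if n > 0:
                if fg == 0.0:
                    return float("-inf")
                logL += n * math.log(fg)
    return logL


class TestCageLogLikelihood:
    def test_single_hwe_record_closed_form(self, single_record_cages):
        L = cage_log_likelihood(single_record_cages, FitnessParams(0.0, 0.0))
        assert L == pytest.approx(150 * math.log(0.5), abs=1e-9)
        assert L == pytest.approx(-103.972, abs=5e-4)

    def test_all_het_record(self):
        data = make_cage_table([("c1", 1, 0, 40, 0)])
        L = cage_log_likelihood(data, FitnessParams(0.2, 0.0))
        assert L == pytest.approx(40 * math.log(0.5), abs=1e-12)

    def test_impossible_data_is_neg_inf(self):
        # h=1, s=-1 kills all carriers of R2 after generation 1: any later
        # heterozygote observation is impossible under the model
        data = make_cage_table([("c1", 2, 50, 10, 0)])
        assert cage_log_likelihood(data, FitnessParams(1.0, -1.0)) == float("-inf")

    def test_matches_naive_recursion(self, cage_data):
        rng = np.random.default_rng(42)
        for _ in range(20):
            h = rng.uniform(-1, 1)
            s = rng.uniform(-0.95, 1)
            expected = naive_log_likelihood(cage_data, h, s)
            got = cage_log_likelihood(cage_data, FitnessParams(h, s))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_maximum_at_generating_parameters(self):
        # expected counts at large N: likelihood peaks at the truth
        traj = simulate_trajectory(FIT_PAPER, 11)
        records = [
            ("c1", g, *np.round(traj.larval[g - 1] * 100_000).astype(int))
            for g in range(1, 12)
        ]
        data = make_cage_table(records)
        L_true = cage_log_likelihood(data, FIT_PAPER)
        for dh in (-0.05, 0.05):
            for ds in (-0.05, 0.05):
                L_pert = cage_log_likelihood(
                    data, FitnessParams(FIT_PAPER.h + dh, FIT_PAPER.s + ds)
                )
                assert L_true >= L_pert

    def test_validation_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            cage_log_likelihood(
                make_cage_table([("c1", 0, 1, 1, 1)]), FitnessParams(0, 0)
            )
        with pytest.raises(ValueError):
            cage_log_likelihood(
                make_cage_table([("c1", 1, 0, 0, 0)]), FitnessParams(0, 0)
            )
        with pytest.raises(ValueError):
            cage_log_likelihood(
                make_cage_table([("c1", 2, 1, 1, 1), ("c1", 2, 1, 1, 1)]),
                FitnessParams(0, 0),
            )


class TestAlleleFreqFromCounts:
    @pytest.mark.parametrize(
        "counts, expected",
        [((25, 50, 25), 0.5), ((100, 0, 0), 1.0), ((40, 46, 14), 0.63)],
    )
    def test_examples(self, counts, expected):
        assert allele_freq_from_counts(*counts) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            allele_freq_from_counts(0, 0, 0)


class TestEndpointBinomialTest:
    def test_null_exact(self):
        # 100 R1 alleles out of 200 (50 hom + 0 het ... use 50/0/50)
        stat, p = endpoint_binomial_test(50, 0, 50)
        assert stat == 0.0 and p == 1.0

    def test_fixation_extreme(self):
        stat, p = endpoint_binomial_test(100, 0, 0)
        assert p < 1e-10

    def test_matches_exact_binomial(self):
        # 126 R1 alleles of 200: (n11, n12, n22) = (53, 20, 27)
        stat, p = endpoint_binomial_test(53, 20, 27, continuity=True)
        k, n = 2 * 53 + 20, 200
        exact = 2 * sum(stats.binom.pmf(i, n, 0.5) for i in range(k, n + 1))
        assert p == pytest.approx(exact, rel=0.10)

    def test_continuity_shrinks_statistic(self):
        s0, _ = endpoint_binomial_test(53, 20, 27, continuity=False)
        s1, _ = endpoint_binomial_test(53, 20, 27, continuity=True)
        assert s1 < s0
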