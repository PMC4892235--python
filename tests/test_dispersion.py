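"""MPD/MNTD, randomization nulls, NRI/NTI and randomization p-values."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphaudit import (dispersion_test, mntd, mpd, null_distribution,
                        p_value, patristic_matrix, ses_index, simulate_yule,
                        tip_labels)
from morphaudit.dispersion import NullDistribution

from conftest import exhaustive_null, metric_brute


@pytest.fixture
def dm4(t4):
    return patristic_matrix(t4)


class TestMetrics:
    def test_mpd_examples(self, dm4):
        assert mpd(dm4, {"A", "B", "C"}) == pytest.approx(10 / 3)
        assert mpd(dm4, {"A", "B"}) == 2.0
        assert mpd(dm4, {"A", "B", "C", "D"}) == pytest.approx(10 / 3)

    def test_mntd_examples(self, dm4):
        # C's nearest focal tip is A or B at distance 4 (D is not focal)
        assert mntd(dm4, {"A", "B", "C"}) == pytest.approx(8 / 3)
        assert mntd(dm4, {"A", "B"}) == 2.0

    def test_pair_focal_set_forces_equality(self, dm4):
        for pair in [{"A", "B"}, {"A", "C"}, {"B", "D"}]:
            assert mntd(dm4, pair) == mpd(dm4, pair)

    def test_too_small_focal_set_raises(self, dm4):
        for focal in [set(), {"A"}]:
            with pytest.raises(ValueError):
                mpd(dm4, focal)
            with pytest.raises(ValueError):
                mntd(dm4, focal)

    def test_unknown_label_raises(self, dm4):
        with pytest.raises(KeyError):
            mpd(dm4, {"A", "Z"})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000), data=st.data())
    def test_mntd_bounded_by_mpd_and_both_match_brute_force(self, seed, data):
        tree = simulate_yule(9, 1.0, seed)
        dm = patristic_matrix(tree)
        focal = data.draw(st.sets(st.sampled_from(dm.labels), min_size=2, max_size=9))
        m1, m2 = mpd(dm, focal), mntd(dm, focal)
        assert m2 <= m1 + 1e-12
        assert m1 == pytest.approx(metric_brute(dm, focal, "MPD"))
        assert m2 == pytest.approx(metric_brute(dm, focal, "MNTD"))


class TestNullDistribution:
    def test_t4_pair_null_matches_exhaustive_enumeration(self, dm4):
        exact = exhaustive_null(dm4, 2, "MPD")
        assert sorted(exact) == [2, 2, 4, 4, 4, 4]
        null = null_distribution(dm4, 2, "MPD", reps=1000, rng=0)
        se = exact.std(ddof=1) / np.sqrt(null.reps)
        assert abs(null.mean - exact.mean()) < 3 * se

    def test_full_pool_draw_is_degenerate(self, dm4):
        null = null_distribution(dm4, 4, "MPD", reps=50, rng=0)
        assert null.sd == 0
        assert np.all(null.values == null.values[0])

    def test_seed_reproducibility(self, dm4):
        a = null_distribution(dm4, 3, "MNTD", reps=200, rng=42)
        b = null_distribution(dm4, 3, "MNTD", reps=200, rng=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_n_raises(self, dm4):
        for n in (1, 5):
            with pytest.raises(ValueError):
                null_distribution(dm4, n, "MPD")

    def test_null_values_are_achievable_metric_values(self, dm4):
        """Every replicate value must occur in the exhaustive enumeration."""
        exact = set(np.round(exhaustive_null(dm4, 3, "MNTD"), 12))
        null = null_distribution(dm4, 3, "MNTD", reps=300, rng=7)
        assert set(np.round(null.values, 12)) <= exact


class TestSesIndex:
    def test_centered_observation_gives_zero(self):
        null = NullDistribution("MPD", np.array([1.0, 2.0, 3.0]), 2)
        assert ses_index(2.0, null) == 0.0

    def test_t4_exhaustive_example(self, dm4):
        null = NullDistribution("MPD", exhaustive_null(dm4, 2, "MPD"), 2)
        assert null.mean == pytest.approx(10 / 3)
        assert null.sd == pytest.approx(1.0328, abs=1e-4)
        assert ses_index(2.0, null) == pytest.approx(1.291, abs=1e-3)

    def test_sign_convention(self):
        null = NullDistribution("MNTD", np.array([1.0, 2.0, 3.0]), 2)
        assert ses_index(3.0, null) < 0  # above null mean: overdispersed
        assert ses_index(1.0, null) > 0  # below null mean: clustered

    def test_zero_sd_gives_nan_not_inf(self):
        null = NullDistribution("MPD", np.full(10, 2.0), 2)
        assert math.isnan(ses_index(1.0, null))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 100), min_size=3, max_size=50), st.floats(0, 100))
    def test_antisymmetric_under_reflection_about_null_mean(self, vals, obs):
        null = NullDistribution("MPD", np.array(vals), 2)
        if null.sd < 1e-6 * max(1.0, abs(null.mean)):
            return  # (near-)degenerate nulls are NA territory, tested elsewhere
        reflected = NullDistribution("MPD", 2 * null.mean - null.values, 2)
        assert ses_index(2 * null.mean - obs, reflected) == pytest.approx(
            -ses_index(obs, null), rel=1e-6, abs=1e-9)


class TestPValue:
    def test_extreme_low_rank(self):
        null = NullDistribution("MPD", np.arange(1.0, 1001.0), 2)
        assert p_value(0.5, null) == pytest.approx(2 / 1001)

    def test_central_rank_is_near_one(self):
        null = NullDistribution("MPD", np.arange(1.0, 1002.0), 2)
        assert p_value(501.0, null) > 0.99

    def test_t4_exhaustive_example(self, dm4):
        null = NullDistribution("MPD", exhaustive_null(dm4, 2, "MPD"), 2)
        assert p_value(2.0, null) == pytest.approx(6 / 7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=100), st.floats(-1, 11))
    def test_p_in_half_open_unit_interval(self, vals, obs):
        p = p_value(obs, NullDistribution("MPD", np.array(vals), 2))
        assert 0 < p <= 1


class TestDispersionTest:
    def test_focal_spanning_all_tips_gives_na(self, t4):
        res = dispersion_test(t4, {"A", "B", "C", "D"}, reps=100, seed=0)
        assert math.isnan(res.nri) and math.isnan(res.nti)
        assert res.reason == "focal set spans all tips"
        assert res.obs_mpd == pytest.approx(10 / 3)

    def test_tiny_focal_set_gives_na_with_reason(self, t4):
        res = dispersion_test(t4, {"A"}, reps=100, seed=0)
        assert res.n == 1 and not res.is_tested
        assert "fewer than 2" in res.reason

    def test_same_seed_bit_identical(self, t4):
        a = dispersion_test(t4, {"A", "B"}, reps=500, seed=9, clade="X", level="species")
        b = dispersion_test(t4, {"A", "B"}, reps=500, seed=9, clade="X", level="species")
        assert a == b

    def test_substreams_independent_of_other_clades(self):
        """A clade's result depends only on (seed, clade, level, metric)."""
        tree = simulate_yule(10, 1.0, 21)
        focal = sorted(tip_labels(tree))[:4]
        a = dispersion_test(tree, focal, reps=200, seed=9, clade="X", level="genus")
        b = dispersion_test(tree, focal, reps=200, seed=9, clade="Y", level="genus")
        c = dispersion_test(tree, focal, reps=200, seed=9, clade="X", level="genus")
        assert a == c
        assert a.nri != b.nri

    def test_clustered_sisters_score_positive_indices(self):
        tree = simulate_yule(48, 1.0, 11)
        dm = patristic_matrix(tree)
        from morphaudit import sample_clustered
        focal = sample_clustered(dm, 12, seed=3)
        res = dispersion_test(dm, focal, reps=1000, seed=5)
        assert res.nti > 0 and res.nri > 0


class TestPicanteCrossCheck:
    def test_observed_metrics_match_picante(self, tmp_path):
        """Independent oracle: R picante's mpd/mntd on the same tree and
        focal set must equal ours."""
        tree = simulate_yule(10, 1.0, 123)
        tree_path = tmp_path / "tree.nwk"
        tree.write(path=str(tree_path), schema="newick",
                   suppress_rooting=True, unquoted_underscores=True)
        dm = patristic_matrix(tree)
        focal = sorted(tip_labels(tree))[::2]
        rscript = f"""
        suppressMessages(library(picante))
        tr <- ape::read.tree("{tree_path}")
        focal <- c({", ".join(repr(f) for f in focal)})
        d <- cophenetic(tr)
        comm <- matrix(0, nrow=1, ncol=length(tr$tip.label),
                       dimnames=list("s", tr$tip.label))
        comm[1, focal] <- 1
        cat(sprintf("%.12f %.12f", mpd(comm, d), mntd(comm, d)))
        """
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        r_mpd, r_mntd = map(float, out.stdout.split())
        assert mpd(dm, focal) == pytest.approx(r_mpd, rel=1e-9)
        assert mntd(dm, focal) == pytest.approx(r_mntd, rel=1e-9)
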