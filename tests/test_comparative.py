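"""Discordance, density arcs, trend smoothing and correlation."""

import numpy as np
import pytest

from ued.comparative import (
    correlate_series,
    density_arc,
    discordance_series,
    eligible_pairs,
    fit_trend,
    locate_extremum,
    permutation_slope_test,
)
from ued.lexicons import CategoricalLexicon
from ued.trajectory import TrajectoryPoint
from ued.transcripts import CharacterNarrative


def traj_const(v, a, n=50, total=100, offset=0):
    return [
        TrajectoryPoint(index=i, position=offset + i, t=(offset + i + 0.5) / total, v=v, a=a)
        for i in range(n)
    ]


def narrative(tokens, positions=None, total=None):
    positions = positions if positions is not None else list(range(len(tokens)))
    total = total if total is not None else (positions[-1] + 1 if positions else 0)
    return CharacterNarrative("m1", "A", tokens, positions, n_turns=1, movie_total_tokens=total)


class TestEligiblePairs:
    def _nar(self, speaker, first, last, total=1000):
        return CharacterNarrative(
            "m1", speaker, ["w"] * 2, [first, last], n_turns=1, movie_total_tokens=total
        )

    def test_speaker_absent_from_first_edge_is_excluded(self):
        nars = [self._nar("A", 0, 999), self._nar("B", 500, 999)]
        assert eligible_pairs(nars) == []

    def test_three_qualifying_speakers_give_three_pairs(self):
        nars = [self._nar(s, 10, 990) for s in "ABC"]
        assert eligible_pairs(nars) == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_single_qualifying_speaker_gives_no_pairs(self):
        nars = [self._nar("A", 10, 990), self._nar("B", 200, 800)]
        assert eligible_pairs(nars) == []


class TestDiscordance:
    def test_identical_trajectories_have_zero_distance(self):
        a = traj_const(0.4, 0.6, n=90, total=100)
        s = discordance_series(a, a, n_bins=20)
        assert np.nanmax(s.distance) == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset_is_the_euclidean_norm(self):
        a = traj_const(0.2, 0.2, n=100, total=100)
        b = traj_const(0.5, 0.6, n=100, total=100)
        s = discordance_series(a, b, n_bins=10)
        assert np.allclose(s.distance, 0.5)  # 3-4-5 triangle

    def test_symmetry_in_the_pair(self, rng):
        def rand_traj(seed):
            r = np.random.default_rng(seed)
            return [
                TrajectoryPoint(i, i, (i + 0.5) / 80, r.uniform(0, 1), r.uniform(0, 1))
                for i in range(80)
            ]

        a, b = rand_traj(1), rand_traj(2)
        s_ab = discordance_series(a, b, n_bins=25, speakers=("A", "B"))
        s_ba = discordance_series(b, a, n_bins=25, speakers=("B", "A"))
        assert s_ab.speakers == s_ba.speakers == ("A", "B")
        np.testing.assert_allclose(s_ab.distance, s_ba.distance, atol=1e-15)

    def test_triangle_inequality_per_bin(self):
        a = traj_const(0.2, 0.2, n=100, total=100)
        b = traj_const(0.5, 0.6, n=100, total=100)
        c = traj_const(0.9, 0.1, n=100, total=100)
        ab = discordance_series(a, b, n_bins=10).distance
        bc = discordance_series(b, c, n_bins=10).distance
        ac = discordance_series(a, c, n_bins=10).distance
        assert np.all(ac <= ab + bc + 1e-12)

    def test_edges_outside_a_speakers_presence_are_missing(self):
        a = traj_const(0.5, 0.5, n=100, total=100)
        b = traj_const(0.5, 0.5, n=40, total=100, offset=30)  # middle only
        s = discordance_series(a, b, n_bins=10)
        assert np.isnan(s.distance[0]) and np.isnan(s.distance[-1])
        assert np.isfinite(s.distance[5])

    def test_interior_gaps_are_interpolated(self):
        # speaker B occupies bins 0-1 and 8-9 only; interior bins interpolate
        b = traj_const(0.2, 0.2, n=20, total=100) + traj_const(0.8, 0.8, n=20, total=100, offset=80)
        a = traj_const(0.5, 0.5, n=100, total=100)
        s = discordance_series(a, b, n_bins=10)
        assert np.all(np.isfinite(s.distance))

    def test_empty_trajectory_is_an_error(self):
        a = traj_const(0.5, 0.5)
        with pytest.raises(ValueError):
            discordance_series(a, [], n_bins=10)


class TestDensityArc:
    def test_first_window_density(self):
        lex = CategoricalLexicon(entries={"bad": frozenset({"negative"})})
        tokens = ["bad"] * 3 + ["x"] * 27 + ["bad"] * 5
        arc = density_arc(narrative(tokens), lex, "negative", window=30)
        assert arc.density[0] == pytest.approx(10.0)

    def test_absent_category_gives_all_zero_arc(self):
        lex = CategoricalLexicon(entries={"bad": frozenset({"negative"})})
        arc = density_arc(narrative(["bad"] * 40), lex, "joy", window=30)
        assert np.all(arc.density == 0.0)

    def test_matches_brute_force_windowed_count(self, rng):
        lex = CategoricalLexicon(entries={"bad": frozenset({"negative"})})
        tokens = [("bad" if rng.uniform() < 0.3 else "ok") for _ in range(200)]
        arc = density_arc(narrative(tokens), lex, "negative", window=30)
        for k in range(len(arc.density)):
            brute = 100.0 * tokens[k : k + 30].count("bad") / 30
            assert arc.density[k] == pytest.approx(brute, abs=1e-10)

    def test_short_narrative_warns_and_is_empty(self):
        lex = CategoricalLexicon()
        with pytest.warns(UserWarning, match="shorter"):
            arc = density_arc(narrative(["a"] * 5), lex, "joy", window=30)
        assert arc.t.size == 0


class TestTrend:
    def test_noiseless_parabola_extremum_recovered(self):
        x = np.linspace(0, 1, 200)
        curve = fit_trend(x, -((x - 0.9) ** 2))
        ext = locate_extremum(curve, "max")
        assert ext.t == pytest.approx(0.9, abs=0.02)
        assert ext.distinct and not ext.boundary

    def test_constant_input_yields_flat_curve(self):
        x = np.linspace(0, 1, 50)
        curve = fit_trend(x, np.full(50, 3.25))
        assert np.allclose(curve(np.linspace(0, 1, 11)), 3.25, atol=1e-6)
        assert not locate_extremum(curve, "max").distinct

    def test_monotone_input_has_boundary_extremum(self):
        x = np.linspace(0, 1, 100)
        curve = fit_trend(x, 2 * x + 1)
        ext = locate_extremum(curve, "max")
        assert ext.boundary and ext.t == pytest.approx(1.0, abs=0.01)
        ext_min = locate_extremum(curve, "min")
        assert ext_min.boundary and ext_min.t == pytest.approx(0.0, abs=0.01)

    def test_parameter_recovery_under_noise(self, rng):
        x = np.linspace(0, 1, 400)
        truth = np.sin(2 * np.pi * x) * 0.5
        y = truth + rng.normal(0, 0.1, x.size)
        curve = fit_trend(x, y)
        err = np.abs(curve(x) - truth)
        assert np.mean(err) < 0.05  # well under the noise SD

    def test_degenerate_x_is_an_error(self):
        with pytest.raises(ValueError, match="span|degenerate"):
            fit_trend(np.full(30, 0.5), np.arange(30.0))

    def test_duplicate_x_values_are_averaged(self):
        x = np.repeat(np.linspace(0, 1, 30), 2)
        y = np.tile([1.0, 3.0], 30)  # pairs average to 2
        curve = fit_trend(x, y)
        assert np.allclose(curve(np.linspace(0.1, 0.9, 9)), 2.0, atol=1e-6)


class TestCorrelation:
    def test_perfect_linear_relations(self):
        x = np.linspace(0, 1, 30)
        assert correlate_series(x, 2 * x + 1) == pytest.approx(1.0)
        assert correlate_series(x, -x) == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self, rng):
        x = rng.uniform(size=100)
        y = rng.uniform(size=100)
        r = correlate_series(x, y)
        brute = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(brute, abs=1e-10)

    def test_missing_bins_are_dropped_pairwise(self):
        x = np.array([0.1, 0.2, np.nan, 0.4, 0.5])
        y = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        assert correlate_series(x, y) == pytest.approx(1.0)

    def test_constant_input_is_unavailable(self):
        assert correlate_series(np.ones(10), np.arange(10.0)) is None


class TestPermutationCheck:
    def test_strong_trend_has_small_p_value(self):
        x = np.linspace(0, 1, 60)
        slope, p = permutation_slope_test(x, 3 * x + 0.1, n_permutations=199, seed=0)
        assert slope == pytest.approx(3.0, abs=1e-8)
        assert p <= 0.01

    def test_pure_noise_has_large_p_value(self, rng):
        x = np.linspace(0, 1, 60)
        _, p = permutation_slope_test(x, rng.normal(size=60), n_permutations=199, seed=1)
        assert p > 0.05
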