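"""Density, variability, displacement detection and the metric profile."""

import numpy as np
import pytest
from scipy import stats

from ued.dynamics import (
    detect_displacements,
    dimensional_density,
    emotion_word_density,
    summarize_profile,
    variability,
    variability_2d,
)
from ued.homebase import HomeBaseEllipse
from ued.lexicons import CategoricalLexicon
from ued.synthetic import default_spec, make_narrative
from ued.trajectory import ScoredWord, TrajectoryPoint
from ued.transcripts import build_narratives, select_main_characters
from dataclasses import replace


def circle_home(center=(0.5, 0.5), radius=0.1):
    psi = float(stats.chi2.ppf(0.68, 2))
    lam = radius**2 / psi
    return HomeBaseEllipse(
        center=np.asarray(center, float),
        lambda1=lam,
        lambda2=lam,
        eigenvectors=np.eye(2),
        psi=psi,
        confidence=0.68,
        n=10,
    )


def traj_at_distances(distances, center=(0.5, 0.5), radius=0.1):
    """Trajectory along +v whose perimeter distances are exactly `distances`
    (0 means at the center, i.e. inside)."""
    pts = []
    for i, d in enumerate(distances):
        v = center[0] if d == 0 else center[0] + radius + d
        pts.append(TrajectoryPoint(index=i, position=i, t=None, v=v, a=center[1]))
    return pts


class TestDensity:
    def test_flagged_fraction_in_percent(self):
        lex = CategoricalLexicon(entries={"glad": frozenset({"joy"}), "meh": frozenset()})
        tokens = ["glad", "glad"] + ["x"] * 8
        assert emotion_word_density(tokens, lex, "joy") == pytest.approx(20.0)

    def test_denominator_includes_non_lexicon_tokens(self):
        lex = CategoricalLexicon(entries={"glad": frozenset({"joy"})})
        assert emotion_word_density(["glad", "zzz", "zzz", "zzz"], lex, "joy") == pytest.approx(25.0)

    def test_no_covered_tokens_is_zero(self):
        assert emotion_word_density(["a", "b"], CategoricalLexicon(), "joy") == 0.0

    def test_empty_token_list_is_unavailable(self):
        assert emotion_word_density([], CategoricalLexicon(), "joy") is None

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            emotion_word_density(["a"], CategoricalLexicon(), "happiness")

    def test_dimensional_density_is_plain_mean(self):
        scored = [
            ScoredWord("a", 0, 0, 0.2, 0.6),
            ScoredWord("b", 1, 1, 0.8, 0.4),
        ]
        assert dimensional_density(scored) == pytest.approx((0.5, 0.5))
        assert dimensional_density([]) is None
        assert dimensional_density(scored[:1]) == (0.2, 0.6)


class TestVariability:
    def test_population_denominator(self):
        assert variability([0.4, 0.6]) == pytest.approx(0.1)

    def test_constant_series_is_zero(self):
        assert variability([0.7] * 5) == 0.0

    def test_two_dimensional_is_mean_of_component_sds(self, rng):
        v = rng.normal(0.5, 0.2, 400)
        a = rng.normal(0.5, 0.1, 400)
        va = np.column_stack([v, a])
        expected = (v.std() + a.std()) / 2
        assert variability_2d(va) == pytest.approx(expected, abs=1e-12)


class TestDetectDisplacements:
    def test_single_excursion_indices_lengths_and_rates(self):
        distances = [0.0] * 10 + [0.1, 0.2, 0.3, 0.2, 0.1] + [0.0] * 10
        traj = traj_at_distances(distances)
        (d,) = detect_displacements(traj, circle_home())
        assert (d.exit_index, d.first_out_index, d.peak_index, d.return_index) == (9, 10, 12, 15)
        assert d.length == 5 and not d.truncated
        assert d.peak_distance == pytest.approx(0.3)
        assert (d.rise_words, d.recovery_words) == (3, 3)
        assert d.rise_rate == pytest.approx(0.1)
        assert d.recovery_rate == pytest.approx(0.1)

    def test_trajectory_entirely_inside_yields_nothing(self):
        traj = traj_at_distances([0.0] * 20)
        assert detect_displacements(traj, circle_home()) == []

    def test_run_touching_the_end_is_truncated(self):
        traj = traj_at_distances([0.0] * 5 + [0.1, 0.2])
        (d,) = detect_displacements(traj, circle_home())
        assert d.truncated and d.return_index is None
        assert d.rise_words == 2 and d.recovery_words is None

    def test_run_touching_the_start_is_truncated(self):
        traj = traj_at_distances([0.2, 0.1] + [0.0] * 5)
        (d,) = detect_displacements(traj, circle_home())
        assert d.truncated and d.exit_index is None and d.rise_words is None

    def test_peak_ties_break_to_earliest_index(self):
        distances = [0.0, 0.2, 0.3, 0.3, 0.2, 0.0]
        traj = traj_at_distances(distances)
        (d,) = detect_displacements(traj, circle_home())
        assert d.peak_index == 2

    def test_rates_swap_under_time_reversal_of_asymmetric_excursion(self):
        distances = [0.0] * 3 + [0.1, 0.3, 0.2, 0.1] + [0.0] * 3
        fwd = detect_displacements(traj_at_distances(distances), circle_home())[0]
        rev = detect_displacements(traj_at_distances(distances[::-1]), circle_home())[0]
        assert fwd.rise_words == rev.recovery_words
        assert fwd.recovery_words == rev.rise_words
        assert fwd.rise_rate == pytest.approx(rev.recovery_rate)

    def test_shrinking_the_home_base_never_decreases_count(self):
        distances = [0.0] * 5 + [0.05] * 3 + [0.0] * 5 + [0.3] * 3 + [0.0] * 5
        traj = traj_at_distances(distances, radius=0.1)
        big = circle_home(radius=0.2)
        small = circle_home(radius=0.05)
        # the same physical points classified against nested home bases
        n_big = len([d for d in detect_displacements(traj, big) if not d.truncated])
        n_small = len([d for d in detect_displacements(traj, small) if not d.truncated])
        assert n_small >= n_big

    def test_count_length_consistency(self):
        distances = [0.0] * 4 + [0.1] * 2 + [0.0] * 4 + [0.2] * 3 + [0.0] * 4
        traj = traj_at_distances(distances)
        disps = detect_displacements(traj, circle_home())
        assert sum(d.length for d in disps) <= len(traj)
        assert len([d for d in disps if not d.truncated]) == 2


class TestProfile:
    def test_synthetic_speaker_with_three_events_counts_three(self, lexicons):
        vad, emo = lexicons
        turns, truth = make_narrative(default_spec(seed=11), vad)
        nars = build_narratives(turns, select_main_characters(turns, 20))
        nar = [n for n in nars if n.speaker == "S1"][0]
        prof = summarize_profile(nar, vad, emo, min_displacements=3)
        assert prof.displacement_count == len(truth.events) == 3
        assert prof.n_vad_words == 600
        assert prof.mean_peak_distance is not None

    def test_zero_variance_speaker_has_no_variability_or_displacements(self, lexicons):
        vad, emo = lexicons
        spec = replace(default_spec(seed=1), sigma=0.0, events=[])
        turns, _ = make_narrative(spec, vad)
        nars = build_narratives(turns, select_main_characters(turns, 20))
        nar = [n for n in nars if n.speaker == "S1"][0]
        prof = summarize_profile(nar, vad, emo)
        assert prof.variability_2d == pytest.approx(0.0, abs=1e-12)
        assert prof.displacement_count == 0
        assert prof.home_ellipse is None  # degenerate cloud: no 2-D home base

    def test_averages_withheld_below_min_displacements(self, lexicons):
        vad, emo = lexicons
        turns, _ = make_narrative(default_spec(seed=11), vad)
        nars = build_narratives(turns, select_main_characters(turns, 20))
        nar = [n for n in nars if n.speaker == "S1"][0]
        prof = summarize_profile(nar, vad, emo, min_displacements=5)
        assert prof.displacement_count == 3
        assert prof.mean_peak_distance is None
        assert prof.mean_rise_rate is None

    def test_profile_row_is_flat_and_complete(self, lexicons):
        vad, emo = lexicons
        turns, _ = make_narrative(default_spec(seed=2), vad)
        nars = build_narratives(turns, select_main_characters(turns, 20))
        row = summarize_profile(nars[0], vad, emo, min_displacements=3).to_row()
        for key in ("density_negative", "mean_valence", "home_semi_major", "displacement_count"):
            assert key in row
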