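"""Ethogram statistics: phases, fractions, transitions, rates, inference."""

import numpy as np
import pytest
from scipy import stats

from wormscreen.core import Ethogram, StimulusProtocol
from wormscreen.ethostats import (
    _bc_interval,
    behavior_fractions,
    bootstrap_ci,
    compare_groups,
    extract_transitions,
    harmonic_mean_rate,
    jackknife_sd,
    mann_whitney,
    normal_ci,
    p_stars,
    phase_windows,
    reversal_duration_after,
    transition_rate,
    transition_table,
    two_sample_ztest,
    worm_fractions,
)


class TestPhaseWindows:
    def test_default_protocol_eleven_windows(self):
        w = phase_windows(StimulusProtocol())
        assert len(w) == 11
        assert w.labels == ["P", "H1", "L1", "H2", "L2", "H3", "L3", "H4", "L4", "H5", "L5"]
        assert w.windows[-1][2] == 300.0

    def test_single_repeat(self):
        w = phase_windows(StimulusProtocol(repeats=1))
        assert w.labels == ["P", "H1", "L1"]

    def test_zero_pre_omits_p(self):
        w = phase_windows(StimulusProtocol(pre_duration=0, repeats=1))
        assert w.labels == ["H1", "L1"]
        assert w.windows[0][1] == 0.0


class TestFractions:
    def test_counting_example(self):
        """20 frames: 10 F, 5 R, 5 T -> fractions 0.50, 0.25, 0.25, 0."""
        e = Ethogram("w", ["forward"] * 10 + ["reversal"] * 5 + ["turn"] * 5, fps=1.0)
        w = phase_windows(StimulusProtocol(pre_duration=20, repeats=0))
        wf = worm_fractions(e, w).set_index("behavior")
        assert wf.loc["forward", "fraction"] == 0.50
        assert wf.loc["reversal", "fraction"] == 0.25
        assert wf.loc["turn", "fraction"] == 0.25
        assert wf.loc["pause", "fraction"] == 0.0

    def test_all_forward_zero_width_ci(self):
        ethos = [Ethogram(f"w{i}", ["forward"] * 10, fps=1.0) for i in range(5)]
        w = phase_windows(StimulusProtocol(pre_duration=10, repeats=0))
        fr = behavior_fractions(ethos, w, seed=0).set_index("behavior")
        assert fr.loc["forward", "fraction"] == 1.0
        assert fr.loc["forward", "ci_lo"] == fr.loc["forward", "ci_hi"] == 1.0

    def test_fractions_sum_to_one_excluding_unknown(self):
        e = Ethogram(
            "w",
            ["forward", "unknown", "reversal", "turn", "pause", "unknown"] * 4,
            fps=2.0,
        )
        w = phase_windows(StimulusProtocol(pre_duration=12, repeats=0))
        wf = worm_fractions(e, w)
        assert wf["fraction"].sum() == pytest.approx(1.0)

    def test_ctmc_fractions_match_occupancy(self):
        """Symmetric 2-state chain: fraction near the stationary 1/2."""
        from wormscreen.synthetic import CTMCModel, simulate_ethograms

        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.5
        model = CTMCModel(rate_matrices={"pre": m})
        proto = StimulusProtocol(pre_duration=200, repeats=0)
        ethos, _ = simulate_ethograms(model, proto, n_worms=50, fps=10, seed=11)
        fr = behavior_fractions(ethos, phase_windows(proto), seed=0).set_index("behavior")
        per_worm = [np.mean(np.asarray(e.labels) == "forward") for e in ethos]
        se = np.std(per_worm, ddof=1) / np.sqrt(len(per_worm))
        assert abs(fr.loc["forward", "fraction"] - 0.5) <= 3 * se


class TestTransitions:
    def test_constant_no_events(self):
        e = Ethogram("w", ["forward"] * 10, fps=1.0)
        assert extract_transitions(e, min_bout=1) == []

    def test_worked_sequence(self):
        """FFFF RR FFF at 1 fps: (t=4, F->R, pre=4 s), (t=6, R->F, pre=2 s)."""
        e = Ethogram("w", ["forward"] * 4 + ["reversal"] * 2 + ["forward"] * 3, fps=1.0)
        evs = extract_transitions(e, min_bout=1)
        assert len(evs) == 2
        assert (evs[0].time_s, evs[0].from_behavior, evs[0].to_behavior, evs[0].pre_duration) == (4.0, "forward", "reversal", 4.0)
        assert (evs[1].time_s, evs[1].from_behavior, evs[1].to_behavior, evs[1].pre_duration) == (6.0, "reversal", "forward", 2.0)

    def test_debounce_absorbs_short_bout(self):
        e = Ethogram("w", ["forward"] * 4 + ["reversal"] + ["forward"] * 3, fps=1.0)
        assert extract_transitions(e, min_bout=3) == []

    def test_unknown_terminates_without_event(self):
        e = Ethogram(
            "w", ["forward"] * 3 + ["unknown"] * 2 + ["reversal"] * 3, fps=1.0
        )
        assert extract_transitions(e, min_bout=1) == []

    def test_event_phase_assignment(self):
        proto = StimulusProtocol(pre_duration=5, stim_duration=5, isi=5, repeats=1)
        w = phase_windows(proto)
        e = Ethogram("w", ["forward"] * 7 + ["reversal"] * 5, fps=1.0)
        evs = extract_transitions(e, min_bout=1, windows=w)
        assert evs[0].phase == "H1"  # transition at t=7 s falls in H1 = [5, 10)
        assert evs[0].pre_duration == 7.0  # full bout, not truncated at phase edge


class TestTransitionRate:
    def test_closed_form(self):
        rate, _ = transition_rate([1.0, 2.0, 4.0])
        assert rate == pytest.approx(3.0 / 7.0)

    def test_equal_durations_zero_jackknife_sd(self):
        rate, sd = transition_rate([2.0, 2.0, 2.0])
        assert rate == pytest.approx(0.5)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_jackknife_worked_case(self):
        """Durations {1, 2}: rate 2/3; LOO estimates {1, 1/2}; SD = 0.25."""
        rate, sd = transition_rate([1.0, 2.0])
        assert rate == pytest.approx(2.0 / 3.0)
        assert sd == pytest.approx(0.25)

    def test_empty_set_missing_not_zero(self):
        rate, sd = transition_rate([])
        assert np.isnan(rate) and np.isnan(sd)

    def test_single_event_sd_undefined(self):
        rate, sd = transition_rate([2.0])
        assert rate == pytest.approx(0.5)
        assert np.isnan(sd)

    def test_harmonic_identity_random_sets(self, rng):
        for _ in range(200):
            d = rng.exponential(3.0, rng.integers(1, 40))
            assert abs(harmonic_mean_rate(d) - len(d) / d.sum()) < 1e-12


class TestBootstrap:
    def test_constant_data_degenerate(self):
        lo, hi = bootstrap_ci(np.full(10, 4.2), np.mean, seed=0)
        assert lo == hi
        assert lo == pytest.approx(4.2)

    def test_symmetric_distribution_reduces_to_percentile(self):
        """With theta_hat at the bootstrap median, z0 = 0 and the BC interval
        is the plain percentile interval."""
        boot = np.linspace(-1, 1, 1000)  # symmetric, no mass exactly at 0
        level = 0.834
        lo, hi = _bc_interval(boot, theta_hat=0.0, level=level)
        za = stats.norm.ppf((1 + level) / 2)
        plo, phi = np.quantile(boot, [stats.norm.cdf(-za), stats.norm.cdf(za)])
        assert lo == pytest.approx(plo, abs=1e-6)
        assert hi == pytest.approx(phi, abs=1e-6)

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal(30)
        assert bootstrap_ci(x, np.mean, seed=42) == bootstrap_ci(x, np.mean, seed=42)

    def test_large_sample_approaches_normal_theory(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(2000)
        lo, hi = bootstrap_ci(x, np.mean, level=0.834, B=4000, seed=1)
        nlo, nhi = normal_ci(x.mean(), x.std(ddof=1) / np.sqrt(len(x)), level=0.834)
        width = nhi - nlo
        assert lo == pytest.approx(nlo, abs=0.15 * width)
        assert hi == pytest.approx(nhi, abs=0.15 * width)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0]), np.mean, seed=0)


class TestMannWhitney:
    def test_exact_small_sample(self):
        """x={1,2}, y={3,4}: U = 0 and p = 2/6 by enumerating all C(4,2)=6
        equally likely rank assignments."""
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_samples_with_ties(self):
        _, p = mann_whitney([1.0, 1.0, 2.0], [1.0, 1.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_large_sample_matches_normal_approximation(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(55) + 0.3
        u, p = mann_whitney(x, y)
        # independent hand-coded tie-corrected normal approximation
        n, m = len(x), len(y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        u_stat = ranks[:n].sum() - n * (n + 1) / 2
        mu = n * m / 2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = (counts**3 - counts).sum() / ((n + m) * (n + m - 1))
        sd = np.sqrt(n * m / 12 * ((n + m + 1) - tie_term))
        z = (u_stat - mu - 0.5 * np.sign(u_stat - mu)) / sd
        p_ref = 2 * stats.norm.sf(abs(z))
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestReversalDuration:
    def test_no_reversal_in_window(self):
        e = Ethogram("w", ["forward"] * 10, fps=1.0)
        assert reversal_duration_after(e, stim_time=5.0) == 0.0

    def test_worked_example(self):
        """Stim at t=5; F until t=6 then RRRR then F: duration 4 s."""
        e = Ethogram("w", ["forward"] * 6 + ["reversal"] * 4 + ["forward"], fps=1.0)
        assert reversal_duration_after(e, stim_time=5.0) == 4.0

    def test_ongoing_reversal_not_counted(self):
        labels = ["reversal"] * 6 + ["forward"] * 2 + ["reversal"] * 3 + ["forward"]
        e = Ethogram("w", labels, fps=1.0)
        # reversal ongoing at t=5 started at t=0: skip; next starts at t=8
        assert reversal_duration_after(e, stim_time=5.0) == 3.0

    def test_bout_measured_beyond_window(self):
        e = Ethogram("w", ["forward"] * 3 + ["reversal"] * 8, fps=1.0)
        assert reversal_duration_after(e, stim_time=2.0, response_window=3.0) == 8.0


class TestCompareGroups:
    def test_control_vs_itself(self):
        rng = np.random.default_rng(0)
        g = {"N2": rng.normal(1, 0.1, 20)}
        rep = compare_groups(g, control="N2", seed=0).set_index("group")
        assert rep.loc["N2", "p"] == 1.0
        assert rep.loc["N2", "stars"] == ""

    def test_three_groups_two_comparisons(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(1, 0.1, 15) for k in ("N2", "mutA", "mutB")}
        rep = compare_groups(groups, control="N2", seed=0)
        assert len(rep) == 3
        assert rep[rep["group"] != "N2"]["U"].notna().all()

    def test_fourfold_rate_difference_nonoverlapping_cis(self):
        """Two strains with 4-fold different F->R rates, 50 worms each: the
        harmonic-mean rate CIs at level 0.834 must separate."""
        from wormscreen.synthetic import CTMCModel, simulate_ethograms

        proto = StimulusProtocol(pre_duration=100, repeats=0)
        w = phase_windows(proto)
        rates = {}
        for name, lam in (("N2", 0.4), ("mut", 0.1)):
            m = np.zeros((4, 4))
            m[0, 1] = lam
            m[1, 0] = 0.5
            model = CTMCModel(rate_matrices={"pre": m})
            ethos, _ = simulate_ethograms(model, proto, n_worms=50, fps=10, seed=5)
            durs = [
                ev.pre_duration
                for e in ethos
                for ev in extract_transitions(e, min_bout=1, windows=w)
                if ev.from_behavior == "forward" and ev.to_behavior == "reversal"
            ]
            rates[name] = np.asarray(durs)
        ci_n2 = bootstrap_ci(rates["N2"], harmonic_mean_rate, level=0.834, seed=1)
        ci_mut = bootstrap_ci(rates["mut"], harmonic_mean_rate, level=0.834, seed=2)
        assert ci_mut[1] < ci_n2[0]

    def test_star_coding(self):
        assert p_stars(0.2) == ""
        assert p_stars(0.04) == "*"
        assert p_stars(0.009) == "**"
        assert p_stars(0.0005) == "***"


def test_transition_table_columns_and_rates(rng):
    proto = StimulusProtocol(pre_duration=30, stim_duration=10, isi=10, repeats=1)
    w = phase_windows(proto)
    labels = (["forward"] * 8 + ["reversal"] * 4) * 4 + ["forward"] * 2
    e = Ethogram("w", labels, fps=1.0)
    table = transition_table([e], w, min_bout=1, seed=0)
    fr = table[(table["from"] == "forward") & (table["to"] == "reversal")]
    assert set(table["phase"]) == set(w.labels)
    assert (fr["n"].sum()) == 4
    # the harmonic-mean identity holds row-wise where defined
    defined = table[table["rate"].notna()]
    assert (defined["n"] >= 1).all()
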