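"""Generator correctness: schemes, Gillespie paths, trace rendering,
dose series and slow-conversion scenarios."""

import numpy as np
import pytest
from scipy import stats

from fretkin import (
    KineticScheme,
    PhotophysicsModel,
    PRESETS,
    build_scheme,
    render_trace,
    simulate_dose_series,
    simulate_slow_process,
    simulate_state_path,
    simulate_traces,
)
from fretkin.synthetic import hill_occupancy


class TestBuildScheme:
    def test_preset_rates(self):
        scheme = build_scheme("control")
        assert scheme.rates[scheme.index("GA"), scheme.index("AC")] == 0.74
        assert scheme.rates[scheme.index("GA"), scheme.index("CR")] == 0.99

    def test_row_sum_matches_reported_decay_rate(self):
        # didemnin GA row: 0.64 + 0.07 = 0.71
        scheme = build_scheme("didemnin")
        assert scheme.exit_rates[scheme.index("GA")] == pytest.approx(0.71)

    def test_unknown_condition_raises(self):
        with pytest.raises(KeyError, match="foo"):
            build_scheme("foo")

    def test_dark_arrival_prepends_state(self):
        scheme = build_scheme("control", include_dark_arrival=True, arrival_rate=0.5)
        assert scheme.state_labels == ("dark", "CR", "GA", "AC")
        assert scheme.state_fret_means[0] == 0.0
        assert scheme.rates[0, 1] == 0.5
        assert scheme.rates[0, 2:].sum() == 0.0  # dark exits only to CR

    def test_absorb_high(self):
        scheme = build_scheme("control", absorb_high=True)
        assert scheme.absorbing_flags[scheme.index("AC")]

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(("CR", "GA"), [0.45, 0.2], np.zeros((2, 2)))  # wrong order
        with pytest.raises(ValueError):
            KineticScheme(("a", "b"), [0.1, 0.2], [[0.0, -1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            KineticScheme(("a", "b"), [0.1, 0.2], [[0.5, 1.0], [1.0, 0.0]])  # diagonal


class TestSimulateStatePath:
    def test_absorbing_start_is_single_event(self):
        scheme = build_scheme("control", absorb_high=True)
        path = simulate_state_path(scheme, 5.0, start_state=scheme.index("AC"), seed=0)
        assert len(path.states) == 1
        assert path.t_entry[0] == 0.0 and path.t_exit[0] == 5.0

    def test_dwell_mean_matches_exponential(self):
        # total exit rate 2.0 /s: mean of 10,000 dwells ~ 0.5 s within 3 SE
        scheme = KineticScheme(("a", "b"), [0.2, 0.7], [[0.0, 2.0], [0.0, 0.0]])
        rng = np.random.default_rng(1)
        dwells = []
        while len(dwells) < 10_000:
            p = simulate_state_path(scheme, 1e9, seed=rng)
            dwells.append(p.durations[0])
        dwells = np.array(dwells)
        se = dwells.std() / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 0.5) < 3 * se

    def test_symmetric_scheme_occupancy(self):
        scheme = KineticScheme(("a", "b"), [0.2, 0.7], [[0.0, 1.0], [1.0, 0.0]])
        path = simulate_state_path(scheme, 20_000.0, seed=3)
        occ0 = path.occupancy(0) / path.t_end
        assert occ0 == pytest.approx(0.5, abs=0.02)

    def test_dwell_distribution_ks(self):
        # Gillespie dwells in a state with k_i = 1.73 are Exponential(k_i)
        scheme = build_scheme("control")
        rng = np.random.default_rng(7)
        dwells = []
        while len(dwells) < 10_000:
            p = simulate_state_path(scheme, 50.0, start_state=1, seed=rng)
            full = p.durations[:-1][p.states[:-1] == 1]  # last event may be cut
            dwells.extend(full)
        dwells = np.array(dwells[:10_000])
        ks = stats.kstest(dwells, "expon", args=(0, 1 / 1.73))
        assert ks.pvalue > 0.01

    def test_path_tiles_window(self):
        path = simulate_state_path(build_scheme("control"), 10.0, seed=11)
        assert path.t_entry[0] == 0.0
        np.testing.assert_allclose(path.t_entry[1:], path.t_exit[:-1])
        assert path.t_exit[-1] == pytest.approx(10.0)
        assert np.all(path.durations > 0)

    def test_seed_reproducibility(self):
        a = simulate_state_path(build_scheme("control"), 10.0, seed=5)
        b = simulate_state_path(build_scheme("control"), 10.0, seed=5)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.t_exit, b.t_exit)


class TestRenderTrace:
    def test_zero_noise_constant_state(self):
        scheme = build_scheme("control", absorb_high=True)
        # start and stay in GA-like absorbing toy: make GA absorbing instead
        scheme = build_scheme("control").with_absorbing("GA")
        path = simulate_state_path(scheme, 1.0, start_state=1, seed=0)
        model = PhotophysicsModel(
            fret_noise_sigma=0.0, donor_bleach_rate=0.0, acceptor_bleach_rate=0.0
        )
        tr = render_trace(path, model, seed=0)
        np.testing.assert_allclose(tr.fret, 0.45, atol=1e-12)

    def test_zero_noise_occupancy_weighted_mean(self):
        # multi-transition path: frame FRET equals occupancy-weighted truth
        scheme = build_scheme("control", include_dark_arrival=True)
        model = PhotophysicsModel(
            fret_noise_sigma=0.0, donor_bleach_rate=0.0, acceptor_bleach_rate=0.0
        )
        path = simulate_state_path(scheme, 10.0, seed=21)
        tr = render_trace(path, model, seed=21)
        dt = model.frame_period
        for f in range(0, tr.n_frames, 37):
            lo_f, hi_f = f * dt, (f + 1) * dt
            w = 0.0
            for s, a, b in zip(path.states, path.t_entry, path.t_exit):
                ov = max(0.0, min(b, hi_f) - max(a, lo_f))
                w += ov * path.state_fret_means[s]
            assert abs(tr.fret[f] - w / dt) < 1e-12

    def test_bleach_truncates_at_exponential_time(self):
        scheme = build_scheme("control").with_absorbing("GA")
        model = PhotophysicsModel(
            fret_noise_sigma=0.0, donor_bleach_rate=0.2, acceptor_bleach_rate=0.0,
            frame_period=0.015,
        )
        rng = np.random.default_rng(4)
        durations = []
        for _ in range(5000):
            path = simulate_state_path(scheme, 1e6, start_state=1, seed=rng)
            tr = render_trace(path, model, seed=rng)
            durations.append(tr.n_frames * model.frame_period)
        durations = np.array(durations)
        se = durations.std() / np.sqrt(len(durations))
        assert abs(durations.mean() - 5.0) < 3 * se

    def test_noise_sd_recovered(self):
        scheme = build_scheme("control").with_absorbing("GA")
        path = simulate_state_path(scheme, 150.0, start_state=1, seed=0)
        model = PhotophysicsModel(
            fret_noise_sigma=0.06, donor_bleach_rate=0.0, acceptor_bleach_rate=0.0
        )
        tr = render_trace(path, model, seed=1)
        assert tr.n_frames == 10_000
        sd = tr.fret.std(ddof=1)
        se = 0.06 / np.sqrt(2 * (tr.n_frames - 1))
        assert abs(sd - 0.06) < 3 * se

    def test_empty_path_raises(self):
        path = simulate_state_path(build_scheme("control"), 1.0, seed=0)
        empty = type(path)(
            states=np.empty(0, dtype=np.intp), t_entry=np.empty(0), t_exit=np.empty(0),
            t_end=1.0, state_labels=path.state_labels,
            state_fret_means=path.state_fret_means,
        )
        with pytest.raises(ValueError):
            render_trace(empty, PhotophysicsModel(), seed=0)

    def test_fret_is_ratiometric(self):
        traces = simulate_traces(
            build_scheme("control"), PhotophysicsModel(background=50.0), 3, 5.0, seed=9
        )
        for tr in traces:
            total = tr.donor + tr.acceptor
            ok = total > 0
            np.testing.assert_allclose(
                tr.fret[ok], tr.acceptor[ok] / total[ok], atol=1e-12
            )

    def test_trace_set_reproducibility(self):
        kw = dict(n_traces=5, t_max=5.0, seed=17)
        a = simulate_traces(build_scheme("control"), PhotophysicsModel(), **kw)
        b = simulate_traces(build_scheme("control"), PhotophysicsModel(), **kw)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.fret, y.fret)
            np.testing.assert_array_equal(x.donor, y.donor)


class TestDoseSeries:
    def test_zero_concentration_all_free(self):
        free = build_scheme("control", include_dark_arrival=True, absorb_high=True)
        bound = build_scheme("didemnin", include_dark_arrival=True, absorb_high=True)
        series = simulate_dose_series(
            free, bound, ic50=4.5, hill=1.0, concentrations=[0.0],
            n_traces=50, model=PhotophysicsModel(), t_max=1.0, seed=0,
        )
        assert all(not t.metadata["bound"] for t in series[0.0])

    def test_midpoint_bound_fraction(self):
        free = build_scheme("control", absorb_high=True)
        bound = build_scheme("didemnin", absorb_high=True)
        series = simulate_dose_series(
            free, bound, ic50=4.5, hill=1.0, concentrations=[4.5],
            n_traces=2000, model=PhotophysicsModel(), t_max=0.2, seed=1,
        )
        frac = np.mean([t.metadata["bound"] for t in series[4.5]])
        se = np.sqrt(0.25 / 2000)
        assert abs(frac - 0.5) < 3 * se

    def test_saturation_occupancy(self):
        assert hill_occupancy(1e4 * 4.5, 4.5, 1.0) >= 0.999

    def test_negative_concentration_rejected(self):
        free = build_scheme("control")
        with pytest.raises(ValueError):
            simulate_dose_series(
                free, free, 4.5, 1.0, [-1.0], 10, PhotophysicsModel(), seed=0
            )


class TestSlowProcess:
    def test_zero_rate_limit(self):
        traces = simulate_slow_process(1e-12, 50, 3600.0, seed=0)
        for tr in traces:
            assert np.all(tr.truth_states == 0)  # never leaves GA

    def test_conversion_fraction_near_total(self):
        traces = simulate_slow_process(5e-3, 1000, 2000.0, seed=1)
        frac = np.mean([tr.truth_path.states[-1] == 1 for tr in traces])
        assert frac > 0.999 - 3 * np.sqrt(1e-3 / 1000) - 0.005

    def test_conversion_fraction_exponential_cdf(self):
        # k = 6e-4, T = 1000 s: converted fraction ~ 1 - exp(-0.6) = 0.451
        traces = simulate_slow_process(6e-4, 1000, 1000.0, seed=2)
        frac = np.mean([tr.truth_path.states[-1] == 1 for tr in traces])
        p = 1 - np.exp(-0.6)
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(frac - p) < 3 * se

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_slow_process(0.0, 10, 100.0, seed=0)
        with pytest.raises(ValueError):
            simulate_slow_process(1e-3, 10, -5.0, seed=0)


def test_preset_row_sums_consistent_at_printed_precision():
    """Row sums of every preset match the reported decay rates k_i."""
    for name, preset in PRESETS.items():
        rates = np.array(preset["rates"])
        for i, reported in enumerate(preset["reported_totals"]):
            decimals = len(str(reported).split(".")[1])
            assert round(rates[i].sum(), decimals) == pytest.approx(reported), (
                name, i,
            )
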