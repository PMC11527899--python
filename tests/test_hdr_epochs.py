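"""Epoching, baseline normalisation, median HDR and aggregation."""

import numpy as np
import pandas as pd
import pytest

from swallowfnirs import hdr_epochs, synthgen
from swallowfnirs.hdr_epochs import (EpochSet, aggregate,
                                     baseline_consistency_check,
                                     baseline_normalize, extract_epochs,
                                     grand_average, median_hdr)
from swallowfnirs.synthgen import (Channel, ConcentrationSeries,
                                   ConfigurationError)

FS = 50.0


def _conc(values, n_channels=2):
    """Constant-per-channel concentration series of the given length."""
    n = len(values)
    hbo = np.tile(np.asarray(values, dtype=float), (n_channels, 1))
    chans = tuple(Channel(i + 1, i + 1, "L" if i % 2 == 0 else "R",
                          "precentral") for i in range(n_channels))
    return ConcentrationSeries(time=np.arange(n) / FS, hbo=hbo,
                               hbr=-hbo / 3, channels=chans)


def _events(onsets, positions=None, ordinals=None):
    n = len(onsets)
    return pd.DataFrame({
        "onset": onsets,
        "block": [1] * n,
        "position": positions or ["neutral"] * n,
        "ordinal": ordinals or list(range(1, n + 1)),
        "verified": [True] * n,
    })


class TestExtractEpochs:
    def test_out_of_bounds_event_dropped_with_warning(self):
        conc = _conc(np.zeros(int(60 * FS)))
        ev = _events([5.0, 30.0])
        with pytest.warns(UserWarning, match="dropped 1"):
            epochs = extract_epochs(conc, ev)
        assert len(epochs) == 1
        assert epochs.events["onset"].iloc[0] == 30.0

    def test_epoch_length_and_constant_values(self):
        conc = _conc(np.full(int(60 * FS), 3.5))
        epochs = extract_epochs(conc, _events([30.0]))
        assert epochs.data.shape == (1, 2, int(30 * FS) + 1)
        assert np.allclose(epochs.data, 3.5)

    def test_noise_free_epoch_matches_kernel(self, optics):
        proto = synthgen.ProtocolSpec(n_blocks=1,
                                      swallows_per_position_per_block=2,
                                      inter_block_rest=0.0)
        sched = synthgen.make_schedule(proto, seed=0)
        chans = synthgen.default_channels()
        hrf = synthgen.HRFParams()
        conc, truth = synthgen.simulate_concentrations(
            sched, chans, hrf, synthgen.NoiseParams.silent(), seed=0)
        epochs = extract_epochs(conc, truth)
        _, kernel = synthgen.hrf_kernel(hrf, FS)
        first = epochs.events.iloc[0]
        amp = hrf.amplitude_by_position[first["position"]]
        trace = epochs.data[0, 0]
        post = trace[epochs.tau >= 0][:len(kernel)]
        assert np.allclose(post[:int(20 * FS)],
                           amp * kernel[:int(20 * FS)], atol=1e-9)

    def test_empty_event_list(self):
        conc = _conc(np.zeros(int(60 * FS)))
        epochs = extract_epochs(conc, _events([]))
        assert len(epochs) == 0


class TestBaselineNormalize:
    def test_constant_epoch_maps_to_zero(self):
        conc = _conc(np.full(int(60 * FS), 7.0))
        epochs = baseline_normalize(extract_epochs(conc, _events([30.0])))
        assert np.allclose(epochs.data, 0.0)

    def test_baseline_mean_exactly_zero(self, rng):
        conc = _conc(rng.standard_normal(int(120 * FS)))
        epochs = baseline_normalize(
            extract_epochs(conc, _events([20.0, 60.0, 90.0])))
        base = epochs.data[:, :, epochs.tau < 0].mean(axis=2)
        assert np.abs(base).max() < 1e-12

    def test_ramp_keeps_slope(self):
        n = int(60 * FS)
        conc = _conc(0.2 * np.arange(n) / FS)
        epochs = baseline_normalize(extract_epochs(conc, _events([30.0])))
        slope = np.gradient(epochs.data[0, 0], 1 / FS)
        assert np.allclose(slope, 0.2, atol=1e-9)
        # closed form: ramp value at centre of baseline window is removed,
        # so the sample at tau = -5.005 s (baseline midpoint) is ~0
        mid = np.argmin(np.abs(epochs.tau + 5.01))
        assert abs(epochs.data[0, 0, mid]) < 0.01

    def test_double_application_rejected(self):
        conc = _conc(np.zeros(int(60 * FS)))
        epochs = baseline_normalize(extract_epochs(conc, _events([30.0])))
        with pytest.raises(ValueError):
            baseline_normalize(epochs)


class TestMedianHDR:
    def _epochs(self, trace):
        conc = _conc(trace)
        return baseline_normalize(extract_epochs(conc, _events([30.0])))

    def test_constant_window_returns_constant(self):
        n = int(60 * FS)
        trace = np.zeros(n)
        i0 = int(30 * FS)
        trace[i0 + int(5 * FS): i0 + int(20 * FS) + 1] = 2.0
        vals = median_hdr(self._epochs(trace))
        assert vals[0, 0] == pytest.approx(2.0)

    def test_robust_to_minority_spikes(self, rng):
        # perturbing fewer than half the window samples by huge amounts
        # cannot move the median beyond the clean sample range
        n = int(60 * FS)
        epochs = self._epochs(np.zeros(n))
        window = (epochs.tau >= 5) & (epochs.tau <= 20)
        n_win = window.sum()
        data = epochs.data.copy()
        idx = rng.choice(np.flatnonzero(window), size=n_win // 2 - 1,
                         replace=False)
        data[0, 0, idx] += rng.choice([-1e6, 1e6], size=len(idx))
        spiked = EpochSet(data=data, tau=epochs.tau, events=epochs.events,
                          channels=epochs.channels, sample_rate=FS,
                          baseline_applied=True)
        clean = median_hdr(epochs)[0, 0]
        assert abs(median_hdr(spiked)[0, 0] - clean) < 1e-9

    def test_unnormalized_epochs_rejected(self):
        conc = _conc(np.zeros(int(60 * FS)))
        epochs = extract_epochs(conc, _events([30.0]))
        with pytest.raises(ValueError):
            median_hdr(epochs)

    def test_window_outside_epoch_rejected(self):
        conc = _conc(np.zeros(int(60 * FS)))
        epochs = baseline_normalize(extract_epochs(conc, _events([30.0])))
        with pytest.raises(ConfigurationError):
            median_hdr(epochs, window=(5.0, 25.0))


class TestAggregate:
    def _setup(self, rng, n_events=8):
        onsets = 30.0 + 38.0 * np.arange(n_events)
        events = _events(list(onsets), ordinals=list(range(1, n_events + 1)))
        scalars = rng.standard_normal((n_events, 2))
        chans = (Channel(1, 1, "L", "precentral"),
                 Channel(2, 2, "R", "precentral"))
        return scalars, events, chans

    def test_constant_scalars_constant_cells(self, rng):
        scalars, events, chans = self._setup(rng)
        out = aggregate(np.full_like(scalars, 4.0), events, chans, "P01")
        assert np.allclose(out["oxyhb"], 4.0)

    def test_hemisphere_separation(self, rng):
        scalars, events, chans = self._setup(rng)
        scalars = np.tile([1.0, 2.0], (len(events), 1))
        out = aggregate(scalars, events, chans, "P01")
        assert (out.loc[out["hemisphere"] == "L", "oxyhb"] == 1.0).all()
        assert (out.loc[out["hemisphere"] == "R", "oxyhb"] == 2.0).all()

    def test_all_cell_is_plain_mean_of_components(self, rng):
        # brute-force recomputation: no double weighting
        scalars, events, chans = self._setup(rng)
        out = aggregate(scalars, events, chans, "P01")
        cell = out[(out["hemisphere"] == "L") & (out["timing"] == "all")]
        assert cell["oxyhb"].iloc[0] == pytest.approx(scalars[:, 0].mean())
        first = out[(out["hemisphere"] == "L") & (out["timing"] == "first")]
        assert first["oxyhb"].iloc[0] == pytest.approx(
            scalars[:2, 0].mean())
        last = out[(out["hemisphere"] == "L") & (out["timing"] == "last")]
        assert last["oxyhb"].iloc[0] == pytest.approx(
            scalars[6:8, 0].mean())

    def test_scaling_equivariance(self, rng):
        scalars, events, chans = self._setup(rng)
        out1 = aggregate(scalars, events, chans, "P01")
        out2 = aggregate(2.5 * scalars, events, chans, "P01")
        assert np.allclose(out2["oxyhb"], 2.5 * out1["oxyhb"])

    def test_position_ordering_in_synthetic_cohort(self, small_session):
        # generator amplitudes order down < neutral < up; the summary
        # must reproduce that in both hemispheres
        from swallowfnirs import pipeline
        out = pipeline.analyze_session(small_session)
        cells = out.summary[out.summary["timing"] == "all"].pivot_table(
            index="hemisphere", columns="position", values="oxyhb")
        for hemi in ("L", "R"):
            assert cells.loc[hemi, "up"] > cells.loc[hemi, "down"]


class TestGrandAverage:
    def test_single_epoch_identity(self):
        conc = _conc(np.sin(np.arange(int(60 * FS)) / 100))
        epochs = extract_epochs(conc, _events([30.0]))
        ga = grand_average(epochs)
        trace = ga[ga["position"] == "neutral"]["mean"].to_numpy()
        assert np.allclose(trace, epochs.data[0].mean(axis=0))

    def test_opposite_epochs_cancel(self):
        n = int(200 * FS)
        trace = np.zeros(n)
        i0, i1 = int(30 * FS), int(130 * FS)
        trace[i0 - 500:i0 + 1001] = 1.0
        trace[i1 - 500:i1 + 1001] = -1.0
        epochs = extract_epochs(_conc(trace), _events([30.0, 130.0]))
        ga = grand_average(epochs)
        assert np.abs(ga["mean"]).max() < 1e-12


class TestBaselineConsistency:
    def _table(self, rng, n=26, drift=0.0, noise=0.3):
        rows = []
        for i in range(n):
            for pos in ("down", "neutral", "up"):
                base = rng.normal(0, noise)
                rows.append({"participant": i, "position": pos,
                             "timing": "first",
                             "baseline": base + rng.normal(0, noise)})
                rows.append({"participant": i, "position": pos,
                             "timing": "last",
                             "baseline": base + drift + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_identical_baselines_pass(self):
        df = self._table(np.random.default_rng(0), drift=0.0, noise=0.0)
        out = baseline_consistency_check(df)
        assert (out["p_value"] == 1.0).all()
        assert out["consistent"].all()

    def test_injected_drift_detected(self, rng):
        # 5 µM drift in the last swallows at n=26 is detected essentially
        # always by the paired test
        out = baseline_consistency_check(self._table(rng, drift=5.0))
        assert (out["p_value"] < 0.05).all()
        assert not out["consistent"].any()

    def test_driftless_tables_pass_at_nominal_rate(self):
        # type-I simulation: per-position rejection should track alpha
        rejections = 0
        n_tests = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            out = baseline_consistency_check(self._table(rng, drift=0.0))
            rejections += (~out["consistent"]).sum()
            n_tests += len(out)
        assert rejections / n_tests <= 0.10

    def test_single_participant_rejected(self):
        df = pd.DataFrame({"participant": [1, 1], "position": ["up", "up"],
                           "timing": ["first", "last"],
                           "baseline": [0.0, 0.1]})
        with pytest.raises(ValueError):
            baseline_consistency_check(df)
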