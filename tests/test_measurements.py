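"""Measurement extraction, normalization and lognormal noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nfkbid as nk
from nfkbid.measurements import (
    RHO,
    MeasurementSet,
    TimeSeries,
    normalize,
    normalize_series,
    read_csv,
    write_csv,
)


def _series(values, times=None, **kw):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values), dtype=float) if times is None else times
    kw.setdefault("protocol", "p")
    kw.setdefault("genotype", "WT")
    kw.setdefault("observable", "NFkBn")
    return TimeSeries(times=times, values=values, **kw)


class TestExtraction:
    def test_on_off_counts_and_dim(self, raw_on_off):
        assert raw_on_off.N == 50
        assert raw_on_off.n_series == 9
        assert raw_on_off.dim == 41

    def test_total_ikba_is_one_at_rest(self, raw_on_off):
        for s in raw_on_off.series:
            if s.observable == "IkBa_total":
                assert s.values[0] == pytest.approx(1.0, abs=1e-9)

    def test_all_extracted_values_non_negative(self, raw_on_off):
        assert raw_on_off.values_vector().min() >= 0.0

    def test_time_outside_trajectory_rejected(self, on_off):
        traj = nk.simulate(nk.FITTED, [(0.0, 100.0, 1)], grid_step_min=5.0)
        with pytest.raises(ValueError, match="span"):
            nk.extract_observables(traj, on_off.schedule, "WT")


class TestNormalization:
    def test_constant_series_maps_to_ones(self):
        out = normalize_series(_series([3.0, 3.0, 3.0]))
        assert np.allclose(out.values, 1.0)

    def test_shift_then_scale_hand_example(self):
        out = normalize_series(_series([0.0, 1.0, 1.0]), rho=0.03)
        xp = np.array([0.03, 1.03, 1.03])
        expected = xp / np.prod(xp) ** (1 / 3)
        assert np.allclose(out.values, expected, rtol=1e-12)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_series(_series([0.0, 0.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1e3), min_size=2, max_size=12),
           st.floats(1e-3, 1e3))
    def test_unit_geometric_mean_and_scale_invariance(self, values, c):
        values = np.asarray(values)
        if values.max() <= 0:
            return
        out = normalize_series(_series(values))
        assert np.prod(out.values) == pytest.approx(1.0, rel=1e-9)
        scaled = normalize_series(_series(c * values))
        assert np.allclose(scaled.values, out.values, rtol=1e-9)

    def test_normalized_set_flagged_and_double_normalize_rejected(
            self, raw_on_off):
        norm = normalize(raw_on_off)
        assert norm.normalized and norm.N == raw_on_off.N
        with pytest.raises(ValueError, match="already"):
            normalize(norm)


class TestNoise:
    def test_sigma_one_is_identity(self, raw_on_off):
        out = nk.add_lognormal_noise(raw_on_off, nk.NoiseModel(1.0, seed=3))
        assert np.array_equal(out.values_vector(),
                              raw_on_off.values_vector())

    def test_same_seed_reproduces(self, raw_on_off):
        a = nk.add_lognormal_noise(raw_on_off, nk.NoiseModel(1.2, seed=7))
        b = nk.add_lognormal_noise(raw_on_off, nk.NoiseModel(1.2, seed=7))
        c = nk.add_lognormal_noise(raw_on_off, nk.NoiseModel(1.2, seed=8))
        assert np.array_equal(a.values_vector(), b.values_vector())
        assert not np.array_equal(a.values_vector(), c.values_vector())

    def test_median_of_draws_is_unperturbed_value(self):
        base = _series(np.full(10_000, 2.5))
        mset = MeasurementSet((base,),)
        out = nk.add_lognormal_noise(mset, nk.NoiseModel(1.3, seed=0))
        assert np.median(out.values_vector()) == pytest.approx(2.5, rel=0.01)

    def test_geometric_sd_below_one_rejected(self):
        with pytest.raises(ValueError, match="geometric"):
            nk.NoiseModel(0.9)

    def test_noise_then_normalize_commutes_with_rescaling(self, raw_on_off):
        noise = nk.NoiseModel(1.2, seed=11)
        a = normalize(nk.add_lognormal_noise(raw_on_off, noise))
        scaled = MeasurementSet(tuple(
            TimeSeries(s.protocol, s.genotype, s.observable, s.times,
                       7.3 * s.values)
            for s in raw_on_off.series))
        b = normalize(nk.add_lognormal_noise(scaled, noise))
        assert np.allclose(a.values_vector(), b.values_vector(), rtol=1e-9)


class TestCSV:
    def test_round_trip(self, raw_on_off, tmp_path):
        path = tmp_path / "m.csv"
        write_csv(raw_on_off, path)
        back = read_csv(path)
        assert back.N == raw_on_off.N
        assert not back.normalized
        assert np.allclose(back.values_vector(),
                           raw_on_off.values_vector())
        npath = tmp_path / "n.csv"
        write_csv(normalize(raw_on_off), npath)
        assert read_csv(npath).normalized
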