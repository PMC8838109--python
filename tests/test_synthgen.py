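"""Generators: ground-truth recovery, limits and determinism."""

import math

import numpy as np
import pytest

import spindyn as sd
from spindyn.exceptions import CoverageError, InvalidParameterError


class TestGenDecay:
    def test_noiseless_values(self):
        c = sd.gen_decay(1.0, [0.0, 1.0])
        assert c.intensities[0] == pytest.approx(1.0)
        assert c.intensities[1] == pytest.approx(math.exp(-1.0))

    def test_fit_recovers_generating_t1_under_noise(self):
        c = sd.gen_decay(0.4, np.geomspace(0.01, 5.0, 12), noise_sd=0.02, seed=7)
        t1, _ = sd.fit_decay(c)
        assert t1 == pytest.approx(0.4, abs=0.02)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(InvalidParameterError):
            sd.gen_decay(-1.0, [0.1, 0.2])

    def test_stretched_option(self):
        c = sd.gen_decay(1.0, [2.0], stretch_beta=0.5)
        assert c.intensities[0] == pytest.approx(math.exp(-math.sqrt(2.0)))


class TestGenRateSeries:
    def test_slow_branch_matches_printed_arrhenius_form(self):
        s = sd.gen_rate_series(sd.GroundTruth(30.0, 1.0), [250.0], "slow")
        assert np.log(s.rates[0]) == pytest.approx(30000 / (8.314462618 * 250), rel=1e-9)
        assert np.log(s.rates[0]) == pytest.approx(14.434, abs=2e-3)

    def test_zero_activation_energy_is_flat(self):
        s = sd.gen_rate_series(sd.GroundTruth(0.0, 2.5), [200.0, 250.0, 300.0], "fast")
        assert np.allclose(s.rates, 2.5)

    def test_loglinear_at_zero_noise(self):
        s = sd.gen_rate_series(sd.GroundTruth(12.0, 3.0), np.linspace(230, 320, 7), "fast")
        resid = np.polyfit(1 / s.temperatures, np.log(s.rates), 1, full=True)[1]
        assert float(resid[0]) < 1e-20

    def test_recovery_with_noise(self):
        truth = sd.GroundTruth(4.1, 1.0, noise_sd=0.01, seed=1)
        s = sd.gen_rate_series(truth, np.linspace(280, 330, 8), "fast")
        res = sd.arrhenius_fit(s)
        assert res.e_star == pytest.approx(4.1, abs=0.2)
        assert res.branch == "fast"

    def test_empty_temperatures_rejected(self):
        with pytest.raises(InvalidParameterError):
            sd.gen_rate_series(sd.GroundTruth(10.0), [], "fast")


class TestGenPake:
    def test_splitting_convention_scale_one(self):
        p = sd.gen_pake(13.5, scale=1.0, lb=0.02)
        d_eff, unc = sd.extract_splitting(p)
        assert d_eff == pytest.approx(13.5, abs=unc)

    def test_lee_goldburg_scaled_splitting(self):
        # 23.5 kHz x 1/sqrt(3) = 13.57 kHz horn-to-horn in the scaled data
        p = sd.gen_pake(23.5, scale=sd.lg_scale(), lb=0.02)
        raw = sd.extract_splitting(sd.DipolarPattern(p.freqs, p.intensities))[0]
        assert raw == pytest.approx(13.57, abs=0.1)

    def test_prescaled_coupling_is_linear(self):
        p = sd.gen_pake(13.5 / 3.0, scale=1.0, lb=0.02)
        d_eff, unc = sd.extract_splitting(p)
        assert d_eff == pytest.approx(4.5, abs=unc)

    def test_grid_coverage_enforced(self):
        with pytest.raises(CoverageError):
            sd.gen_pake(20.0, scale=1.0, grid=np.arange(-5.0, 5.0, 0.1))


class TestGenExchange:
    def test_slow_limit_two_peaks_at_site_frequencies(self):
        grid = np.linspace(-200, 200, 4001)
        sp = sd.gen_exchange_spectrum(sd.ExchangePair(-50.0, 50.0, 0.0, 0.05), grid)
        y = sp.intensities
        peaks = grid[np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1]
        assert sorted(np.round(peaks, 1)) == [-50.0, 50.0]

    def test_fast_limit_single_peak_at_mean(self):
        grid = np.linspace(-200, 200, 4001)
        sp = sd.gen_exchange_spectrum(sd.ExchangePair(-50.0, 50.0, 1e6, 0.05), grid)
        assert abs(grid[np.argmax(sp.intensities)]) < 0.5
        n_max = np.sum((sp.intensities[1:-1] > sp.intensities[:-2])
                       & (sp.intensities[1:-1] > sp.intensities[2:]))
        assert n_max == 1

    def test_coalescence_at_classical_condition(self):
        # two maxima merge at k = pi * dnu / sqrt(2) ~ 222 1/s for dnu = 100 Hz
        grid = np.linspace(-200, 200, 4001)

        def n_maxima(k):
            y = sd.gen_exchange_spectrum(sd.ExchangePair(-50.0, 50.0, k, 1.0), grid).intensities
            return np.sum((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))

        k_c = next(k for k in np.arange(180.0, 280.0, 1.0) if n_maxima(k) == 1)
        assert k_c == pytest.approx(np.pi * 100.0 / np.sqrt(2.0), rel=0.03)


class TestGenDSC:
    def test_flat_trace_without_transitions(self):
        tr = sd.gen_dsc(0.9)
        assert np.allclose(tr.signal, 0.9)

    def test_peak_integral_recovers_generating_enthalpy(self):
        tr = sd.gen_dsc(1.0, [(272.0, 1.13, 1.0)])
        assert sd.integrate_peak(tr, (262, 282)) == pytest.approx(1.13, abs=0.01)

    def test_baseline_step_recovered(self):
        tr = sd.gen_dsc([(0.0, 1.0), (272.0, 1.0 - 0.102)])
        assert abs(sd.cp_step(tr, 272.0)) == pytest.approx(0.102, abs=0.005)

    def test_close_transitions_warn(self):
        with pytest.warns(UserWarning, match="3 widths"):
            sd.gen_dsc(1.0, [(270.0, 1.0, 2.0), (272.0, 0.5, 2.0)])

    def test_heatflow_mode_consistent_with_cp(self):
        hf = sd.gen_dsc(1.0, [(260.0, 0.8, 1.0)], mode="heatflow", scan_rate=10.0)
        assert sd.integrate_peak(hf, (250, 270)) == pytest.approx(0.8, abs=0.01)


class TestGenToyCell:
    def test_cubic_volume(self):
        cell = sd.gen_toy_cell((10, 10, 10, 90, 90, 90), [])
        assert sd.cell_volume(cell) == pytest.approx(1000.0)

    def test_single_site_cell(self):
        cell = sd.gen_toy_cell((10, 10, 10, 90, 90, 90), [("C", (0, 0, 0))])
        assert len(cell.sites) == 1 and cell.sites[0].element == "C"

    def test_constructed_contact_distance(self, cubic_cell):
        cl = sd.contacts(cubic_cell, "O", "O", 3.2)
        assert len(cl) == 1
        assert cl[0].distance == pytest.approx(2.80, abs=1e-9)

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError):
            sd.gen_toy_cell((5, 5, 5, 90, 90, 90), [("Xx", (0, 0, 0))])


class TestDeterminismAndNoise:
    def test_fixed_seed_bit_identical(self):
        a = sd.gen_decay(1.0, np.linspace(0.1, 5, 10), 0.05, seed=3).intensities
        b = sd.gen_decay(1.0, np.linspace(0.1, 5, 10), 0.05, seed=3).intensities
        assert np.array_equal(a, b)
        ra = sd.gen_rate_series(sd.GroundTruth(10, 1, 0.02, seed=9),
                                np.linspace(240, 300, 6), "fast").rates
        rb = sd.gen_rate_series(sd.GroundTruth(10, 1, 0.02, seed=9),
                                np.linspace(240, 300, 6), "fast").rates
        assert np.array_equal(ra, rb)

    @pytest.mark.parametrize("generator", ["decay", "rates"])
    def test_estimator_spread_grows_with_noise(self, generator):
        spreads = []
        for noise in (0.01, 0.05, 0.15):
            est = []
            for seed in range(40):
                if generator == "decay":
                    c = sd.gen_decay(1.0, np.geomspace(0.05, 5, 12), noise, seed=seed)
                    est.append(sd.fit_decay(c)[0])
                else:
                    s = sd.gen_rate_series(sd.GroundTruth(15.0, 1.0, noise, seed=seed),
                                           np.linspace(240, 300, 8), "fast")
                    est.append(sd.arrhenius_fit(s).e_star)
            spreads.append(np.std(est))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_zero_noise_roundtrips_tight(self, cubic_cell):
        # decay -> T1, rates -> E*, pake -> D, DSC -> dH, cell -> volume
        t1, _ = sd.fit_decay(sd.gen_decay(6.1, np.geomspace(0.05, 30, 10)))
        assert t1 == pytest.approx(6.1, rel=1e-3)
        e = sd.arrhenius_fit(sd.gen_rate_series(sd.GroundTruth(22.0, 2.0),
                                                np.linspace(230, 300, 8), "slow")).e_star
        assert e == pytest.approx(22.0, rel=1e-3)
        dh = sd.integrate_peak(sd.gen_dsc(1.0, [(260.0, 0.46, 1.0)]), (250, 270))
        assert dh == pytest.approx(0.46, rel=1e-2)
        assert sd.cell_volume(cubic_cell) == pytest.approx(1000.0, rel=1e-6)


class TestWriters:
    def test_csv_and_sidecar_roundtrip(self, tmp_path):
        import json
        import pandas as pd
        from spindyn.synthgen import write_curve_csv, write_ground_truth

        c = sd.gen_decay(1.0, np.linspace(0.1, 2, 5), 0.01, seed=1)
        write_curve_csv(c, tmp_path / "c.csv")
        df = pd.read_csv(tmp_path / "c.csv")
        assert np.allclose(df["intensity"], c.intensities)
        write_ground_truth(c.meta, tmp_path / "c.json")
        assert json.loads((tmp_path / "c.json").read_text())["t1_true"] == 1.0

    def test_cif_writer_roundtrip(self, tmp_path, cubic_cell):
        from spindyn.synthgen import write_cif

        write_cif(cubic_cell, tmp_path / "toy.cif")
        back = sd.read_structure(tmp_path / "toy.cif")
        assert back.a == pytest.approx(10.0)
        assert len(back.sites) == 2
        assert sd.cell_volume(back) == pytest.approx(1000.0)
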