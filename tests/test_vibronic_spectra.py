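"""DHO cumulant lineshapes, ensemble spectra, and Stokes-shift accounting."""

import math

import numpy as np
import pandas as pd
import pytest

import lovspec as lv
from lovspec.constants import EV_TO_CM
from lovspec.errors import ConfigurationError, CoverageError, NormalizationError, UsageError
from lovspec.vibronic_spectra import huang_rhys_from_gradient


def single_mode(freq=1400.0, s=0.7):
    return lv.SpectralDensity([lv.VibronicMode(freq, s)])


def record(exc, cluster="C", emi=None, mu=(1.0, 0.0, 0.0), snap=0):
    return lv.ElectronicRecord(snapshot=snap, cluster=cluster, exc_ev=exc,
                               emi_ev=emi, dipole=np.asarray(mu))


class TestHuangRhys:
    def test_zero_gradient_gives_zero_coupling(self):
        modes = huang_rhys_from_gradient([1000.0, 1500.0], [0.0, 0.0])
        assert all(m.huang_rhys == 0.0 for m in modes)

    def test_quadratic_in_gradient(self):
        (m1,) = huang_rhys_from_gradient([1200.0], [0.3])
        (m2,) = huang_rhys_from_gradient([1200.0], [0.6])
        assert m2.huang_rhys == pytest.approx(4.0 * m1.huang_rhys)

    def test_two_route_displacement_identity(self):
        # route 1: S = g^2 / (2 hbar w^3); route 2: Delta = g/w^2, S = w Delta^2 / (2 hbar)
        w, g = 0.007, 3.1e-5  # arbitrary consistent (atomic-style) units
        (mode,) = huang_rhys_from_gradient([w], [g])
        delta = g / w**2
        assert mode.huang_rhys == pytest.approx(w * delta**2 / 2.0, rel=1e-12)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ConfigurationError):
            huang_rhys_from_gradient([0.0], [0.1])


class TestCumulantLineshape:
    def test_no_coupling_gives_single_lorentzian_at_origin(self):
        sd = single_mode(s=0.0)
        ls = lv.cumulant_lineshape(sd, temperature_k=0.0, broadening_cm1=50.0)
        peak = ls.grid_cm1[np.argmax(ls.intensity)]
        assert abs(peak) <= 2.0
        # symmetric about the origin
        half = np.interp([-50.0, 50.0], ls.grid_cm1, ls.intensity)
        assert half[0] == pytest.approx(half[1], rel=1e-3)
        assert half[0] == pytest.approx(0.5 * ls.intensity.max(), rel=0.02)

    def test_area_normalized(self):
        for t in (0.0, 300.0):
            ls = lv.cumulant_lineshape(single_mode(), temperature_k=t)
            assert ls.area() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("s", [0.3, 0.7, 1.2])
    def test_zero_temperature_poisson_progression(self, s):
        """At T->0 a single mode must reproduce the Franck-Condon progression:
        stick weights e^{-S} S^n / n! convolved with the Lorentzian damping."""
        freq, hwhm = 1400.0, 3.0
        ls = lv.cumulant_lineshape(single_mode(freq, s), temperature_k=0.0,
                                   broadening_cm1=hwhm)
        for n in range(5):
            a, b = n * freq - freq / 2, n * freq + freq / 2
            m = (ls.grid_cm1 > a) & (ls.grid_cm1 <= b)
            got = np.trapezoid(ls.intensity[m], ls.grid_cm1[m])
            want = sum(
                math.exp(-s) * s**k / math.factorial(k)
                * (np.arctan((b - k * freq) / hwhm) - np.arctan((a - k * freq) / hwhm))
                / np.pi
                for k in range(20)
            )
            assert got == pytest.approx(want, rel=0.01)

    def test_first_moment_equals_reorganization_energy(self):
        sd = single_mode(1400.0, 0.7)  # lambda = 980 cm^-1
        ls = lv.cumulant_lineshape(sd, temperature_k=0.0, broadening_cm1=3.0)
        moment = np.trapezoid(ls.grid_cm1 * ls.intensity, ls.grid_cm1)
        assert moment == pytest.approx(sd.reorganization_energy_cm1, abs=10.0)

    def test_narrow_grid_rejected(self):
        with pytest.raises(CoverageError):
            lv.cumulant_lineshape(single_mode(), grid_cm1=np.arange(-100.0, 100.0, 2.0))


class TestEnsembleSpectrum:
    def setup_method(self):
        self.line = lv.cumulant_lineshape(single_mode(), broadening_cm1=200.0)

    def test_single_record_centered_at_its_energy(self):
        spec = lv.ensemble_spectrum([record(3.0)], self.line)
        peak_rel = self.line.grid_cm1[np.argmax(self.line.intensity)]
        peak_abs = spec.grid_cm1[np.argmax(spec.intensity)]
        assert peak_abs == pytest.approx(3.0 * EV_TO_CM + peak_rel, abs=5.0)

    def test_linear_in_identical_records(self):
        one = lv.ensemble_spectrum([record(3.0)], self.line)
        two = lv.ensemble_spectrum([record(3.0), record(3.0, snap=1)], self.line,
                                   grid_cm1=one.grid_cm1)
        assert np.allclose(two.intensity, 2.0 * one.intensity)

    def test_matches_direct_summation_oracle(self):
        recs = [record(3.00), record(3.00 + 300.0 / EV_TO_CM, snap=1)]
        spec = lv.ensemble_spectrum(recs, self.line)
        direct = np.zeros_like(spec.grid_cm1)
        for r in recs:
            direct += r.dipole_sq * np.interp(
                spec.grid_cm1 - r.exc_ev * EV_TO_CM,
                self.line.grid_cm1, self.line.intensity, left=0.0, right=0.0,
            )
        assert np.allclose(spec.intensity, direct)
        # peak maximum lies between the two centers
        peak = spec.grid_cm1[np.argmax(spec.intensity)]
        lo, hi = recs[0].exc_ev * EV_TO_CM, recs[1].exc_ev * EV_TO_CM
        assert lo < peak < hi

    def test_record_order_irrelevant(self):
        recs = [record(3.0 + 0.01 * i, snap=i) for i in range(5)]
        a = lv.ensemble_spectrum(recs, self.line)
        b = lv.ensemble_spectrum(recs[::-1], self.line, grid_cm1=a.grid_cm1)
        assert np.allclose(a.intensity, b.intensity)


class TestWeightedAverage:
    def _spec(self, center, grid):
        return lv.LineShape(grid, np.exp(-((grid - center) ** 2) / (2 * 100.0**2)))

    def test_single_cluster_unchanged(self):
        grid = np.arange(0.0, 5000.0, 5.0)
        s = self._spec(2000.0, grid)
        avg = lv.weighted_average_spectra({"a": s}, {"a": 1.0})
        assert np.allclose(avg.intensity, s.intensity)

    def test_dominant_cluster_dominates(self):
        grid = np.arange(0.0, 5000.0, 5.0)
        spectra = {"c7": self._spec(2000.0, grid), "c2": self._spec(3500.0, grid)}
        avg = lv.weighted_average_spectra(spectra, {"c7": 0.78, "c2": 0.05})
        dev = np.abs(avg.intensity - spectra["c7"].intensity).max()
        assert dev < 0.07  # within the minority weight of the dominant spectrum

    def test_equal_weights_of_disjoint_peaks(self):
        grid = np.arange(0.0, 8000.0, 5.0)
        spectra = {"a": self._spec(1000.0, grid), "b": self._spec(7000.0, grid)}
        avg = lv.weighted_average_spectra(spectra, {"a": 0.5, "b": 0.5})
        assert avg.intensity.max() == pytest.approx(0.5, abs=1e-6)
        assert np.interp(1000.0, avg.grid_cm1, avg.intensity) == pytest.approx(0.5, abs=1e-6)

    def test_grid_mismatch_rejected(self):
        g1 = np.arange(0.0, 100.0, 1.0)
        g2 = np.arange(0.0, 100.0, 2.0)
        with pytest.raises(UsageError):
            lv.weighted_average_spectra(
                {"a": self._spec(50, g1), "b": self._spec(50, g2)},
                {"a": 0.5, "b": 0.5},
            )


class TestNormalizeAndShift:
    def test_maximum_exactly_one(self):
        grid = np.arange(0.0, 100.0, 1.0)
        spec = lv.LineShape(grid, np.random.default_rng(0).random(100) + 0.1)
        out = lv.normalize_and_shift(spec, -3500.0)
        assert out.intensity.max() == 1.0

    def test_shift_is_invertible(self):
        grid = np.arange(0.0, 100.0, 1.0)
        spec = lv.LineShape(grid, np.ones(100))
        out = lv.normalize_and_shift(lv.normalize_and_shift(spec, -3500.0), +3500.0)
        assert np.allclose(out.grid_cm1, grid)

    def test_zero_shift_keeps_grid(self):
        grid = np.arange(0.0, 100.0, 1.0)
        out = lv.normalize_and_shift(lv.LineShape(grid, np.ones(100)), 0.0)
        assert np.array_equal(out.grid_cm1, grid)

    def test_all_zero_rejected(self):
        spec = lv.LineShape(np.arange(3.0), np.zeros(3))
        with pytest.raises(NormalizationError):
            lv.normalize_and_shift(spec)


class TestStokes:
    def test_single_record_conversion(self):
        t = lv.stokes_table([record(3.22, emi=2.82)], {"C": 1.0})
        assert t.rows.loc[0, "ss_cm1"] == pytest.approx((3.22 - 2.82) * EV_TO_CM)
        assert int(round(t.rows.loc[0, "ss_cm1"])) == 3226

    def test_equal_energies_give_zero_shift(self):
        t = lv.stokes_table([record(3.0, emi=3.0)], {"C": 1.0})
        assert t.rows.loc[0, "ss_cm1"] == 0.0

    def test_weighted_row_from_published_style_values(self, table1_c426a):
        t = lv.stokes_from_cluster_rows(table1_c426a)
        assert t.weighted["ss_cm1"] == pytest.approx(3184.56, abs=0.01)
        rounded = t.rounded()
        w = rounded[rounded["cluster"] == "weighted"].iloc[0]
        assert (w["exc_ev"], w["emi_ev"], w["ss_cm1"]) == (3.22, 2.83, 3185)

    def test_weighted_row_consistent_with_cluster_rows(self):
        recs = [record(3.2 + 0.01 * i, cluster=f"c{i % 2}", emi=2.8, snap=i) for i in range(20)]
        t = lv.stokes_table(recs, {"c0": 0.6, "c1": 0.4})
        pops = t.rows["population"].to_numpy()
        w = pops / pops.sum()
        assert t.weighted["ss_cm1"] == pytest.approx(float(w @ t.rows["ss_cm1"]), abs=1e-9)
        assert t.weighted["exc_ev"] == pytest.approx(float(w @ t.rows["exc_ev"]), abs=1e-12)

    def test_record_without_emission_excluded(self, caplog):
        recs = [record(3.22, emi=2.82), record(3.30, snap=1)]
        t = lv.stokes_table(recs, {"C": 1.0})
        assert int(t.rows.loc[0, "n_records"]) == 1

    def test_reporting_deviation_within_rounding_bound(self):
        # a published row: EXC 3.17, EMI 2.78, SS 3154 cm^-1
        assert lv.reporting_deviation(3.17, 2.78, 3154.0) <= 81.0


class TestClusterShift:
    def test_published_blue_shift_scale(self):
        recs = [record(3.27, cluster="C2_OUT"), record(3.22, cluster="C7_IN", snap=1)]
        shift = lv.cluster_shift(recs, "C2_OUT", "C7_IN")
        assert shift == pytest.approx(0.05 * EV_TO_CM)
        assert round(shift / 100.0) * 100 == 400

    def test_antisymmetric(self):
        recs = [record(3.27, cluster="a"), record(3.22, cluster="b", snap=1)]
        assert lv.cluster_shift(recs, "a", "b") == -lv.cluster_shift(recs, "b", "a")

    def test_identical_clusters_give_zero(self):
        recs = [record(3.2, cluster="a"), record(3.2, cluster="b", snap=1)]
        assert lv.cluster_shift(recs, "a", "b") == 0.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(UsageError):
            lv.cluster_shift([record(3.2, cluster="a")], "a", "missing")
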