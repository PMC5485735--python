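"""Region-table validation and spectrum integration."""

import numpy as np
import pytest

from nmrprofiler import (
    ProfileMatrix,
    Region,
    RegionTable,
    Spectrum,
    bin_dataset,
    exclude_glucose,
    integrate_spectrum,
    load_region_table,
)
from nmrprofiler._defaults import build_default_regions
from nmrprofiler.regions import RegionTableError


def spectrum_on_grid(lo=0.5, hi=6.0, step=0.001, fn=lambda p: np.ones_like(p)):
    ppm = np.arange(hi, lo - step / 2, -step)
    return Spectrum(ppm, fn(ppm))


class TestRegionTable:
    def test_default_scheme_bookkeeping(self, rt):
        assert len(rt) == 110
        assert rt.n_glucose == 15
        hi = [r.ppm_hi for r in rt]
        assert hi == sorted(hi, reverse=True)
        # shared boundaries allowed, overlaps not
        for prev, nxt in zip(rt.regions, rt.regions[1:]):
            assert nxt.ppm_hi <= prev.ppm_lo + 1e-12

    def test_packaged_csv_matches_builder(self, rt):
        built = build_default_regions()
        assert rt.to_frame().equals(built.to_frame())

    def test_printed_lipid_region_preserved(self, rt, tmp_path):
        r18 = next(r for r in rt if r.var_id == 18)
        assert (r18.ppm_hi, r18.ppm_lo) == (5.4300, 5.2752)
        assert not r18.is_glucose
        # same row accepted through the file loader
        p = tmp_path / "one.csv"
        p.write_text(
            "var_id,ppm_hi,ppm_lo,assignment,is_glucose\n"
            "18,5.4300,5.2752,-HC=CH- in fatty acid chain,false\n"
        )
        loaded = load_region_table(p)
        assert (loaded[0].ppm_hi, loaded[0].ppm_lo) == (5.4300, 5.2752)

    def test_overlap_rejected_naming_offenders(self):
        with pytest.raises(RegionTableError, match="1") as exc:
            RegionTable([Region(1, 4.0, 3.0), Region(2, 3.5, 2.5)])
        assert "2" in str(exc.value)

    def test_duplicate_and_inverted_bounds_rejected(self):
        with pytest.raises(RegionTableError, match="duplicate"):
            RegionTable([Region(1, 4.0, 3.0), Region(1, 2.0, 1.0)])
        with pytest.raises(RegionTableError, match="ppm_hi"):
            Region(3, 1.0, 2.0)


class TestIntegration:
    @pytest.mark.parametrize(
        "fn,hi,lo,expected",
        [
            (lambda p: np.ones_like(p), 5.0, 4.0, 1.0),      # unit height x unit width
            (lambda p: p, 2.0, 1.0, 1.5),                    # analytic: int_1^2 x dx
            # triangle of height 2 on base 3.4-3.6: area 0.5*0.2*2
            (lambda p: np.clip(2 * (1 - np.abs(p - 3.5) / 0.1), 0, None), 3.6, 3.4, 0.2),
        ],
    )
    def test_known_integrals(self, fn, hi, lo, expected):
        s = spectrum_on_grid(fn=fn)
        table = RegionTable([Region(1, hi, lo)])
        assert integrate_spectrum(s, table)[0] == pytest.approx(expected, rel=1e-6)

    def test_linearity(self, rng):
        ppm = np.arange(6.0, 0.5, -0.003)
        i1, i2 = rng.normal(size=ppm.size), rng.normal(size=ppm.size)
        table = RegionTable([Region(1, 5.2, 4.1), Region(2, 3.0, 1.7)])
        a, b = 2.3, -0.7
        lhs = integrate_spectrum(Spectrum(ppm, a * i1 + b * i2), table)
        rhs = a * integrate_spectrum(Spectrum(ppm, i1), table) + b * integrate_spectrum(
            Spectrum(ppm, i2), table
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_axis_direction_invariance(self, rng):
        ppm = np.arange(0.5, 6.0, 0.002)
        inten = rng.normal(size=ppm.size)
        table = RegionTable([Region(1, 4.4, 2.2)])
        asc = integrate_spectrum(Spectrum(ppm, inten), table)
        desc = integrate_spectrum(Spectrum(ppm[::-1], inten[::-1]), table)
        np.testing.assert_allclose(asc, desc, rtol=1e-12)

    def test_grid_refinement_stability(self):
        # a piecewise-linear peak is integrated exactly by the trapezoid rule,
        # so a 10x finer grid must not change the result
        def peak(p):
            return np.clip(3 * (1 - np.abs(p - 3.0) / 0.5), 0, None)

        coarse = spectrum_on_grid(step=0.01, fn=peak)
        fine_ppm = np.arange(6.0, 0.5 - 0.0005, -0.001)
        fine = Spectrum(fine_ppm, np.interp(fine_ppm[::-1], coarse.ppm[::-1], coarse.intensity[::-1])[::-1])
        table = RegionTable([Region(1, 3.6, 2.4)])
        a = integrate_spectrum(coarse, table)[0]
        b = integrate_spectrum(fine, table)[0]
        assert abs(a - b) / abs(a) < 1e-6

    def test_region_outside_coverage_errors(self):
        s = spectrum_on_grid(lo=1.0, hi=5.0)
        with pytest.raises(ValueError, match="outside spectral coverage"):
            integrate_spectrum(s, RegionTable([Region(7, 5.5, 5.2)]))


class TestBinDataset:
    def test_identical_spectra_identical_rows(self):
        s = spectrum_on_grid(fn=lambda p: np.exp(-((p - 3.0) ** 2)))
        table = RegionTable([Region(1, 4.0, 3.5), Region(2, 3.5, 2.0)])
        pm = bin_dataset([s, s], table)
        assert pm.n_samples == 2
        np.testing.assert_array_equal(pm.values.iloc[0], pm.values.iloc[1])

    def test_empty_dataset_errors(self, rt):
        with pytest.raises(ValueError, match="empty dataset"):
            bin_dataset([], rt)

    def test_error_carries_sample_id(self):
        s = spectrum_on_grid(lo=2.0, hi=5.0)
        table = RegionTable([Region(1, 1.5, 1.0)])
        with pytest.raises(ValueError, match="bad_sample"):
            bin_dataset([s], table, sample_ids=["bad_sample"])


class TestExcludeGlucose:
    def test_default_scheme_110_to_95(self, rt, dataset):
        pm95 = exclude_glucose(dataset.profile, rt)
        assert pm95.n_variables == 95
        flags = {r.var_id: r.is_glucose for r in rt}
        assert not any(flags[v] for v in pm95.var_ids)
        assert pm95.n_samples == dataset.profile.n_samples

    def test_no_flags_is_identity(self, dataset):
        import pandas as pd

        table = RegionTable([Region(1, 4.0, 3.0), Region(2, 2.0, 1.0)])
        pm = ProfileMatrix(
            pd.DataFrame([[1.0, 2.0]], index=pd.Index(["s1"], name="sample_id"),
                         columns=["var_1", "var_2"])
        )
        out = exclude_glucose(pm, table)
        assert out.var_ids == [1, 2]

    def test_all_flags_errors(self):
        import pandas as pd

        table = RegionTable([Region(1, 4.0, 3.0, is_glucose=True)])
        pm = ProfileMatrix(
            pd.DataFrame([[1.0]], index=pd.Index(["s1"], name="sample_id"), columns=["var_1"])
        )
        with pytest.raises(ValueError, match="no variables remain"):
            exclude_glucose(pm, table)
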