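import math

import numpy as np
import pandas as pd
import pytest

from detkit import Frame, Reflection, UnitCell
from detkit.exceptions import DetkitError
from detkit.intensity import (
    aggregate_intensity_stats,
    flag_outlier_frames,
    frame_wilson_fit,
    rolling_average,
    s2_of_reflection,
    s2_of_reflections,
)

from conftest import random_cell


def wilson_frame(frame_id="w0", b=20.0, g=100.0, cell=None, hkl=None, noise=None, rng=None):
    """Frame with I = g * exp(-2 b s^2), optionally with multiplicative noise."""
    cell = cell or UnitCell(20, 30, 40, 90, 90, 90)
    if hkl is None:
        hkl = [(h, k, l) for h in range(3) for k in range(3) for l in range(1, 7)]
    s2 = s2_of_reflections(cell, np.array(hkl))
    intensities = g * np.exp(-2 * b * s2)
    if noise is not None:
        intensities = intensities * np.exp(rng.normal(0, noise, len(hkl)))
    reflections = [Reflection(*ijk, float(i)) for ijk, i in zip(hkl, intensities)]
    return Frame(frame_id=frame_id, cell=cell, reflections=reflections)


class TestScatteringAngle:
    def test_cubic_100(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        assert s2_of_reflection(cell, (1, 0, 0)) == pytest.approx(0.0025)

    def test_long_cell_001(self):
        cell = UnitCell(69, 169, 288, 90, 90, 90)
        assert s2_of_reflection(cell, (0, 0, 1)) == pytest.approx(1 / (4 * 288**2), rel=1e-12)
        assert s2_of_reflection(cell, (0, 0, 1)) == pytest.approx(3.014e-6, rel=1e-3)

    def test_triclinic_matches_reciprocal_basis_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            cell = random_cell(rng)
            # independent oracle: explicit reciprocal basis from cross products
            a, b, c = cell.lengths
            ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
            sg = math.sin(math.radians(cell.gamma))
            v = math.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
            real = np.array(
                [
                    [a, 0, 0],
                    [b * cg, b * sg, 0],
                    [c * cb, c * (ca - cb * cg) / sg, c * v / sg],
                ]
            )
            vol = np.dot(real[0], np.cross(real[1], real[2]))
            recip = np.stack(
                [
                    np.cross(real[1], real[2]),
                    np.cross(real[2], real[0]),
                    np.cross(real[0], real[1]),
                ]
            ) / vol
            hkl = rng.integers(-8, 9, 3)
            if not hkl.any():
                continue
            q = hkl @ recip
            assert s2_of_reflection(cell, hkl) == pytest.approx(
                float(q @ q) / 4.0, rel=1e-9
            )

    def test_zero_reflection_rejected(self):
        with pytest.raises(DetkitError):
            s2_of_reflection(UnitCell(10, 10, 10, 90, 90, 90), (0, 0, 0))


class TestFrameWilsonFit:
    def test_noiseless_exact_recovery(self):
        frame = wilson_frame(b=20.0, g=100.0)
        fit = frame_wilson_fit(frame)
        assert fit.b_factor == pytest.approx(20.0, rel=1e-9)
        assert fit.scale_g == pytest.approx(100.0, rel=1e-9)
        assert fit.n_dropped_nonpositive == 0

    def test_two_point_line(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        # craft intensities at the two observed s2 values so the line has
        # slope -20 and intercept ln(100)
        hkl = [(1, 0, 0), (2, 0, 0)]
        s2 = s2_of_reflections(cell, np.array(hkl))
        y = np.log(100.0) - 20.0 * s2
        reflections = [Reflection(*ijk, float(np.exp(v))) for ijk, v in zip(hkl, y)]
        frame = Frame(frame_id="two", cell=cell, reflections=reflections)
        fit = frame_wilson_fit(frame, min_reflections=2)
        assert fit.slope == pytest.approx(-20.0, rel=1e-9)
        assert fit.b_factor == pytest.approx(10.0, rel=1e-9)
        assert fit.intercept == pytest.approx(math.log(100.0), rel=1e-9)

    def test_intensity_scaling_shifts_intercept_only(self):
        rng = np.random.default_rng(42)
        frame = wilson_frame(b=15.0, g=50.0, noise=0.2, rng=rng)
        fit = frame_wilson_fit(frame)
        scaled = Frame(
            frame_id="s", cell=frame.cell,
            reflections=[
                Reflection(r.h, r.k, r.l, r.i_partial * 7.0) for r in frame.reflections
            ],
        )
        fit2 = frame_wilson_fit(scaled)
        assert fit2.slope == pytest.approx(fit.slope, rel=1e-9)
        assert fit2.intercept - fit.intercept == pytest.approx(math.log(7.0), rel=1e-9)

    def test_nonpositive_dropped_and_counted(self):
        frame = wilson_frame()
        with_bad = Frame(
            frame_id="bad", cell=frame.cell,
            reflections=frame.reflections + [Reflection(9, 9, 9, -5.0), Reflection(8, 8, 8, 0.0)],
        )
        fit_clean = frame_wilson_fit(frame)
        fit_bad = frame_wilson_fit(with_bad)
        assert fit_bad.n_dropped_nonpositive == 2
        assert fit_bad.slope == pytest.approx(fit_clean.slope, rel=1e-12)
        assert fit_bad.intercept == pytest.approx(fit_clean.intercept, rel=1e-12)

    def test_too_few_reflections_refused(self):
        frame = wilson_frame(hkl=[(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        assert frame_wilson_fit(frame, min_reflections=10) is None

    def test_ols_calibration(self):
        """Slope estimates are unbiased and their OLS standard errors give
        ~95% CI coverage under lognormal multiplicative noise (small-scale
        version of the full acceptance check)."""
        from detkit.synthetic import IntensityModel, Population, SyntheticConfig, generate

        cfg = SyntheticConfig(
            populations=(Population(UnitCell(69, 169, 288, 90, 90, 90)),),
            n_frames=150,
            intensity=IntensityModel(
                noise_sigma=0.3, n_reflections=200, partiality_min=1.0, partiality_max=1.0
            ),
            seed=99,
        )
        ds = generate(cfg)
        errors, covered = [], 0
        for frame, (_, row) in zip(ds.frames, ds.truth.iterrows()):
            fit = frame_wilson_fit(frame)
            errors.append(fit.b_factor - row["b_true"])
            if abs(fit.b_factor - row["b_true"]) <= 1.96 * fit.se_b:
                covered += 1
        errors = np.array(errors)
        sem = errors.std(ddof=1) / np.sqrt(len(errors))
        assert abs(errors.mean()) < 3 * sem
        assert 0.90 <= covered / len(errors) <= 0.99


class TestRollingAverage:
    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 2.0])
        y = np.array([30.0, 10.0, 20.0])
        rx, ry = rolling_average(x, y, window=1)
        assert np.allclose(rx, [1, 2, 3])
        assert np.allclose(ry, [10, 20, 30])

    def test_constant_series(self):
        x = np.arange(20.0)
        y = np.full(20, 7.0)
        _, ry = rolling_average(x, y, window=5)
        assert np.allclose(ry, 7.0)
        assert len(ry) == 16

    def test_linear_series_stays_on_line(self):
        x = np.arange(30.0)
        y = 2.0 * x + 1.0
        rx, ry = rolling_average(x, y, window=7)
        assert np.allclose(ry, 2.0 * rx + 1.0)

    def test_window_too_large(self):
        with pytest.raises(DetkitError):
            rolling_average(np.arange(3.0), np.arange(3.0), window=4)


class TestAggregate:
    def test_identical_frames_pooled_equals_per_frame(self):
        frames = [wilson_frame(f"w{i}", b=18.0, g=200.0) for i in range(5)]
        agg = aggregate_intensity_stats(frames)
        assert agg.pooled_slope == pytest.approx(agg.fits["slope"].iloc[0], rel=1e-9)
        assert agg.trend == "decreasing"

    def test_histogram_counts_sum_to_fitted_frames(self):
        rng = np.random.default_rng(43)
        frames = [
            wilson_frame(f"w{i}", b=rng.uniform(10, 25), noise=0.2, rng=rng) for i in range(12)
        ]
        agg = aggregate_intensity_stats(frames)
        for counts, _ in agg.histograms.values():
            assert counts.sum() == len(agg.fits)

    def test_b_distribution_recovered(self):
        from detkit.synthetic import IntensityModel, Population, SyntheticConfig, generate

        cfg = SyntheticConfig(
            populations=(Population(UnitCell(69, 169, 288, 90, 90, 90)),),
            n_frames=200,
            intensity=IntensityModel(
                b_mean=15.0, b_sigma=2.0, noise_sigma=0.05, n_reflections=200,
                partiality_min=1.0, partiality_max=1.0,
            ),
            seed=7,
        )
        ds = generate(cfg)
        agg = aggregate_intensity_stats(ds.frames)
        b = agg.fits["B"]
        sem = b.std(ddof=1) / np.sqrt(len(b))
        assert abs(b.mean() - 15.0) < 3 * sem
        assert b.std(ddof=1) == pytest.approx(2.0, rel=0.25)

    def test_no_eligible_frames_rejected(self):
        frame = wilson_frame(hkl=[(1, 0, 0), (0, 1, 0)])
        with pytest.raises(DetkitError):
            aggregate_intensity_stats([frame])


class TestOutlierFilter:
    def test_identical_fits_no_flags(self):
        frames = [wilson_frame(f"w{i}", b=15.0) for i in range(6)]
        agg = aggregate_intensity_stats(frames)
        flags, surviving = flag_outlier_frames(agg.fits)
        assert flags.sum() == 0
        assert len(surviving) == 6

    def test_single_extreme_b_flagged(self):
        rng = np.random.default_rng(44)
        frames = [
            wilson_frame(f"w{i}", b=15.0 + rng.normal(0, 0.5), noise=0.05, rng=rng)
            for i in range(99)
        ]
        frames.append(wilson_frame("bad", b=500.0))
        agg = aggregate_intensity_stats(frames)
        flags, _ = flag_outlier_frames(agg.fits)
        assert flags.sum() == 1
        assert agg.fits.loc[flags, "frame_id"].iloc[0] == "bad"

    def test_zero_mad_fallback(self):
        table = pd.DataFrame(
            {
                "frame_id": [f"f{i}" for i in range(6)],
                "slope": [-30.0] * 5 + [-300.0],
                "intercept": [4.0] * 6,
            }
        )
        flags, surviving = flag_outlier_frames(table)
        assert flags.sum() == 1
        assert len(surviving) == 5

    def test_too_few_fits_rejected(self):
        with pytest.raises(DetkitError):
            flag_outlier_frames(
                pd.DataFrame({"frame_id": ["a"], "slope": [1.0], "intercept": [1.0]})
            )

    def test_misindexed_contaminants_recovered(self):
        from detkit.synthetic import default_two_form_config, generate

        recall_num = recall_den = fp = tn = 0
        for seed in range(5):
            ds = generate(default_two_form_config(n_frames=100, seed=seed))
            agg = aggregate_intensity_stats(ds.frames)
            t = agg.fits.merge(ds.truth, on="frame_id")
            flags, _ = flag_outlier_frames(agg.fits)
            f = flags.to_numpy()
            m = t["misindexed"].to_numpy()
            recall_num += (f & m).sum()
            recall_den += m.sum()
            fp += (f & ~m).sum()
            tn += (~m).sum()
        assert recall_num / recall_den >= 0.9
        assert fp / tn <= 0.05
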