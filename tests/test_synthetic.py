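"""Generator tests: ellipse shape model, event sampling, donor panels."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from platemech import synthetic as syn
from platemech.features import deformation


def ellipse_perimeter_quadrature(aspect: float, area: float) -> float:
    """Independent arc-length oracle: numerically integrated ellipse
    circumference, accurate far beyond 1e-9 relative."""
    b = math.sqrt(area / (math.pi * aspect))
    a = aspect * b
    integrand = lambda t: math.hypot(a * math.sin(t), b * math.cos(t))
    val, err = quad(integrand, 0.0, 2.0 * math.pi, limit=200)
    assert err < 1e-6 * val
    return val


class TestEllipseGeometry:
    def test_unit_circle(self):
        area, perimeter = syn.ellipse_geometry(1.0, math.pi)
        assert area == pytest.approx(math.pi, abs=0)
        assert perimeter == pytest.approx(2.0 * math.pi, rel=1e-12)

    @pytest.mark.parametrize("aspect", [1.0, 1.3, 2.0, 3.7, 8.0])
    @pytest.mark.parametrize("area", [0.5, 4.0])
    def test_perimeter_matches_quadrature_oracle(self, aspect, area):
        _, perimeter = syn.ellipse_geometry(aspect, area)
        assert perimeter == pytest.approx(
            ellipse_perimeter_quadrature(aspect, area), rel=1e-7)

    def test_aspect_two_deformation_is_area_free(self):
        # oracle: quadrature perimeter fed into the isoperimetric formula
        for area in (0.7, math.pi, 42.0):
            p = ellipse_perimeter_quadrature(2.0, area)
            d_oracle = 1.0 - 2.0 * math.sqrt(math.pi * area) / p
            assert syn.aspect_deformation(2.0) == pytest.approx(d_oracle, abs=1e-9)
        # frozen oracle value for the aspect-2 ellipse
        assert syn.aspect_deformation(2.0) == pytest.approx(0.0828494229, abs=1e-6)

    def test_deformation_monotone_and_isoperimetric_limit(self):
        grid = np.array([1.0, 1.2, 1.8, 3.0, 7.0, 30.0, 300.0, 1e4])
        d = syn.aspect_deformation(grid)
        assert np.all(np.diff(d) > 0)
        assert d[0] == 0.0
        assert d[-1] > 0.9  # deformation -> 1 as the ellipse degenerates

    @pytest.mark.parametrize("aspect,area", [(0.5, 1.0), (np.nan, 1.0),
                                             (2.0, -1.0), (2.0, np.inf)])
    def test_rejects_bad_inputs(self, aspect, area):
        with pytest.raises(ValueError):
            syn.ellipse_geometry(aspect, area)


class TestSolveAspect:
    def test_circle(self):
        assert syn.solve_aspect_for_deformation(0.0) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("d", [0.0828494229, 0.127, 0.3, 0.55])
    def test_round_trip(self, d):
        q = syn.solve_aspect_for_deformation(d)
        assert syn.aspect_deformation(q) == pytest.approx(d, abs=1e-9)
        # and through the full geometry, for an arbitrary area
        area, perimeter = syn.ellipse_geometry(q, 5.0)
        assert deformation(area, perimeter) == pytest.approx(d, abs=1e-9)

    def test_aspect_two(self):
        assert syn.solve_aspect_for_deformation(
            syn.aspect_deformation(2.0)) == pytest.approx(2.0, rel=1e-7)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5, np.nan])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            syn.solve_aspect_for_deformation(bad)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.6))
    def test_round_trip_property(self, d):
        q = syn.solve_aspect_for_deformation(d)
        assert abs(syn.aspect_deformation(q) - d) < 1e-9


class TestSampleEvents:
    def test_seed_reproducibility(self):
        model = syn.preset("ACD-A:none")
        a = syn.sample_events(model, 500, seed=42)
        b = syn.sample_events(model, 500, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = syn.sample_events(model, 500, seed=43)
        assert not np.allclose(a["true_deformation"], c["true_deformation"])

    def test_isoperimetric_identity_holds_exactly(self):
        events = syn.sample_events(syn.preset("Na-Citrate:none"), 2000, seed=3)
        recomputed = 1.0 - 2.0 * np.sqrt(np.pi * events["true_area_um2"]) \
            / events["true_perimeter_um"]
        np.testing.assert_allclose(recomputed, events["true_deformation"], atol=1e-9)
        # aspect ratio 1 <=> deformation 0
        assert np.all((events["aspect_ratio"].to_numpy() > 1)
                      == (events["true_deformation"].to_numpy() > 0))

    def test_medians_converge_to_preset(self):
        model = syn.preset("ACD-A:none")
        events = syn.sample_events(model, 20000, seed=11)
        n = len(events)
        for column, target, cv in (("true_deformation", model.deformation_median,
                                    model.deformation_cv),
                                   ("true_area_um2", model.area_median, model.area_cv)):
            median = float(np.median(events[column]))
            # SE of a log-normal sample median
            se = target * math.sqrt(math.log1p(cv**2)) * 1.2533 / math.sqrt(n)
            assert abs(median - target) < 3 * se

    def test_truncation_bound(self):
        events = syn.sample_events(syn.preset("ACD-A:none:LatB"), 20000, seed=5)
        assert events["true_deformation"].max() <= syn.DEFORMATION_MAX

    def test_degenerate_spread(self):
        from dataclasses import replace
        model = replace(syn.preset("ACD-A:none"), deformation_cv=0.0, donor_sd={})
        events = syn.sample_events(model, 50, seed=0)
        np.testing.assert_allclose(events["true_deformation"],
                                   model.deformation_median, atol=1e-9)

    def test_timestamps_are_increasing(self):
        events = syn.sample_events(syn.preset("r-Hirudin:none"), 1000, seed=8)
        assert np.all(np.diff(events["timestamp_s"]) > 0)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            syn.sample_events(syn.preset("ACD-A:none"), 0, seed=0)


class TestPresets:
    @pytest.mark.parametrize("name", sorted(syn.PRESETS))
    def test_preset_bounds(self, name):
        m = syn.preset(name)
        assert 0 < m.deformation_median <= 0.3
        assert 1 < m.area_median < 10
        assert m.deformation_cv > 0 and m.area_cv > 0
        for cm in m.fluor.values():
            assert cm.gmean > 0 and cm.sigma_log > 0

    @pytest.mark.parametrize("ac,fold", [("ACD-A", 2.76), ("Na-Citrate", 2.58),
                                         ("K2-EDTA", 1.14), ("Li-Heparin", 1.72),
                                         ("r-Hirudin", 2.27)])
    def test_stimulated_presets_encode_fold_factors(self, ac, fold):
        unstim = syn.preset(f"{ac}:none")
        stim = syn.preset(f"{ac}:TRAP-6")
        assert unstim.deformation_median / stim.deformation_median == \
            pytest.approx(fold, rel=1e-9)

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="ACD-A:none"):
            syn.preset("no-such-condition")


class TestDonorPanel:
    def test_zero_jitter_makes_donors_exchangeable(self):
        from dataclasses import replace
        model = replace(syn.preset("ACD-A:none"), donor_sd={})
        panel = syn.simulate_donor_panel([model], n_donors=3, n_events=4000, seed=9)
        medians = panel.groupby("donor_id")["true_deformation"].median()
        # donors share the population median; only Monte-Carlo spread remains
        se = model.deformation_median * math.sqrt(
            math.log1p(model.deformation_cv**2)) * 1.2533 / math.sqrt(4000)
        assert medians.std(ddof=1) < 3 * se

    def test_adding_donors_preserves_earlier_donors(self):
        panel3 = syn.simulate_donor_panel(["ACD-A:none"], n_donors=3,
                                          n_events=200, seed=21)
        panel5 = syn.simulate_donor_panel(["ACD-A:none"], n_donors=5,
                                          n_events=200, seed=21)
        pd.testing.assert_frame_equal(
            panel3, panel5[panel5["donor_id"].isin(panel3["donor_id"].unique())]
            .reset_index(drop=True))

    @pytest.mark.parametrize("ac,fold", [("ACD-A", 2.76), ("K2-EDTA", 1.14)])
    def test_paired_fold_change_recovers_preset(self, ac, fold):
        panel = syn.simulate_donor_panel([f"{ac}:none", f"{ac}:TRAP-6"],
                                         n_donors=6, n_events=2000, seed=17)
        ratios = []
        for _, donor in panel.groupby("donor_id"):
            med = donor.groupby("condition_label")["true_deformation"].median()
            ratios.append(med[f"{ac}:none"] / med[f"{ac}:TRAP-6"])
        mean = float(np.mean(ratios))
        se = float(np.std(ratios, ddof=1)) / math.sqrt(len(ratios))
        assert abs(mean - fold) < 2 * max(se, 0.02 * fold)


class TestRenderFrame:
    def test_blank_frame(self):
        cfg = syn.ImagingConfig()
        image, truth = syn.render_frame(None, cfg)
        assert truth is None
        assert image.shape == cfg.shape

    def test_truth_contour_matches_analytic_geometry(self):
        from platemech import imaging
        cfg = syn.ImagingConfig()
        area, perimeter = syn.ellipse_geometry(2.0, 5.0)
        event = syn.GroundTruthEvent(area, perimeter,
                                     deformation(area, perimeter), 2.0)
        _, truth = syn.render_frame(event, cfg)
        scaled = imaging.Contour(truth.vertices, pixel_size_um=cfg.pixel_size_um)
        assert imaging.contour_area(scaled) == pytest.approx(area, rel=1e-3)
        assert imaging.contour_perimeter(scaled) == pytest.approx(perimeter, rel=1e-3)

    def test_oversized_cell_rejected(self):
        cfg = syn.ImagingConfig()
        area, perimeter = syn.ellipse_geometry(1.0, 250.0)  # radius ~8.9 µm
        with pytest.raises(ValueError, match="fit"):
            syn.render_frame(syn.GroundTruthEvent(area, perimeter, 0.0, 1.0), cfg)

    def test_noise_is_seeded(self):
        cfg = syn.ImagingConfig(noise_sd=0.02)
        area, perimeter = syn.ellipse_geometry(1.5, 5.0)
        event = syn.GroundTruthEvent(area, perimeter,
                                     deformation(area, perimeter), 1.5)
        img1, _ = syn.render_frame(event, cfg, seed=4)
        img2, _ = syn.render_frame(event, cfg, seed=4)
        np.testing.assert_array_equal(img1, img2)


class TestRenderConfocal:
    def test_channels_and_shapes(self):
        img = syn.render_confocal_platelet(1.5, "ring", "uniform")
        assert set(img) == {"tubulin", "actin"}
        assert img["tubulin"].shape == img["actin"].shape

    def test_ring_peak_sits_at_radius(self):
        img = syn.render_confocal_platelet(2.0, "ring", "uniform")
        n = img["tubulin"].shape[0]
        c = (n - 1) // 2
        row = img["tubulin"][c]
        x = (np.arange(n) - c) * 0.08
        peak = abs(x[np.argmax(row[: c + 1])])
        assert peak == pytest.approx(2.0, abs=0.08)

    def test_coiled_ring_is_narrower(self):
        ring = syn.render_confocal_platelet(1.5, "ring", "uniform")["tubulin"]
        coiled = syn.render_confocal_platelet(1.5, "coiled", "uniform")["tubulin"]
        # condensed annulus: less total mass at identical peak radius
        assert coiled.sum() < ring.sum()

    def test_radius_bounds(self):
        for bad in (0.4, 5.5):
            with pytest.raises(ValueError):
                syn.render_confocal_platelet(bad, "ring", "uniform")
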