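"""Mixture decomposition, class assignment and signature detectors."""

import numpy as np
import pytest

from cntnmech.curve import ForceCurve
from cntnmech.pipeline import CurveAnalysis, UnfoldingEvent, analyze_curve, preprocess
from cntnmech.population import (
    MixtureFit,
    classify_events,
    detect_intermediate_hump,
    detect_long_plateau,
    detect_partial_fniii,
    fit_gaussian_mixture,
    label_analyses,
)
from cntnmech.simulate import (
    ScriptedEvent,
    SimConfig,
    UnfoldingScript,
    cntn4_event_model,
    draw_event_sequence,
    synthesize_curve,
)
from cntnmech.wlc import InsufficientDataError

# the measured CNTN4 unfolding-length decomposition, used as a reference
# mixture for classification tests
REF_MIX = MixtureFit(
    k=3,
    means=np.array([9.5, 17.4, 30.6]),
    sds=np.array([3.3, 3.3, 3.7]),
    weights=np.array([0.25, 0.35, 0.40]),
    method="histogram-LS",
    gof=0.0,
)


class TestMixture:
    def test_three_component_recovery(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([
            rng.normal(9.5, 3.3, 1000),
            rng.normal(17.4, 3.3, 1000),
            rng.normal(30.6, 3.7, 1000),
        ])
        for method in ("histogram-LS", "EM"):
            fit = fit_gaussian_mixture(vals, 3, method=method, seed=0)
            assert fit.means == pytest.approx([9.5, 17.4, 30.6], abs=0.5)

    def test_methods_agree_on_separated_mixture(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(10, 2, 1500), rng.normal(40, 3, 1500)])
        a = fit_gaussian_mixture(vals, 2, method="histogram-LS", seed=0)
        b = fit_gaussian_mixture(vals, 2, method="EM", seed=0)
        assert a.means == pytest.approx(b.means, abs=0.5)

    def test_single_component_matches_moments(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(50, 8, 2000)
        fit = fit_gaussian_mixture(vals, 1, seed=0)
        assert fit.means[0] == pytest.approx(vals.mean(), rel=0.02)
        assert fit.sds[0] == pytest.approx(vals.std(), rel=0.05)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_gaussian_mixture(np.arange(5.0), 3)

    def test_weights_normalized_and_sorted(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(10, 2, 800), rng.normal(30, 2, 200)])
        fit = fit_gaussian_mixture(vals, 2, seed=0)
        assert fit.weights.sum() == pytest.approx(1.0)
        assert np.all(np.diff(fit.means) > 0)


class TestClassify:
    def test_published_component_assignment(self):
        labels = classify_events([30.6, 9.5, 17.4], REF_MIX)
        assert labels.tolist() == ["FnIII", "IgC2", "IgC2"]

    def test_tie_breaks_toward_fniii(self):
        # build an exact two-way posterior tie between components 2 and 3
        mix = MixtureFit(2, np.array([20.0, 30.0]), np.array([3.0, 3.0]),
                         np.array([0.5, 0.5]), "histogram-LS", 0.0)
        assert classify_events([25.0], mix)[0] == "FnIII"

    def test_nan_maps_to_unassigned(self):
        assert classify_events([np.nan], REF_MIX)[0] == "unassigned"

    def test_missing_mixture_rejected(self):
        with pytest.raises(ValueError):
            classify_events([10.0], None)

    def test_label_recovery_on_synthetic_classes(self):
        rng = np.random.default_rng(10)
        acc = []
        for rep in range(20):
            ig = rng.normal(9.5, 3.3, 200)
            ig2 = rng.normal(17.4, 3.3, 200)
            fn = rng.normal(30.6, 3.7, 300)
            vals = np.concatenate([ig, ig2, fn])
            truth = np.array(["IgC2"] * 400 + ["FnIII"] * 300)
            labels = classify_events(vals, REF_MIX)
            acc.append(np.mean(labels == truth))
        assert np.mean(acc) >= 0.95


def _analysis(dls, labels=None, curve_id="c"):
    events = []
    for i, dl in enumerate(dls):
        e = UnfoldingEvent(i, 50 * (i + 1), 80.0, 60.0 + 25 * i, dl)
        if labels:
            e.label = labels[i]
        events.append(e)
    return CurveAnalysis(curve_id, events, 250.0)


class TestHumpDetector:
    def test_two_stage_pair_merged(self):
        a = _analysis([np.nan, 13.0, 17.0, 31.0])
        reports, merged = detect_intermediate_hump(a)
        assert len(reports) == 1
        assert reports[0].magnitude == pytest.approx(13.0)
        dls = [e.dL for e in merged.events]
        assert pytest.approx(30.0) in dls
        assert len(merged.events) == len(a.events) - 1

    def test_hump_free_curve_empty(self):
        a = _analysis([np.nan, 9.0, 17.0, 31.0])
        reports, merged = detect_intermediate_hump(a)
        assert reports == []
        assert len(merged.events) == len(a.events)

    def test_lower_bound_inclusive_at_11nm(self):
        a = _analysis([np.nan, 11.0, 19.5, 30.0])
        reports, _ = detect_intermediate_hump(a)
        assert len(reports) == 1

    def test_simulated_hump_round_trip(self, quiet_config):
        ev = ScriptedEvent("domain", "fn", "FnIII", 30.0, 150.0,
                           hump=True, hump_dl=13.0, hump_force=70.0)
        script = UnfoldingScript((ev,), lc0=60.0, detach_force=250.0,
                                 adhesion=None, seed=6)
        curve, truth = synthesize_curve(script, quiet_config)
        a = analyze_curve(curve)
        assert a.n_peaks == 2  # intermediate + completion
        reports, merged = detect_intermediate_hump(a, curve)
        assert len(reports) == 1
        assert reports[0].magnitude == pytest.approx(13.0, abs=0.3)
        assert merged.events[-1].dL == pytest.approx(30.0, abs=0.3)


class TestPlateauDetector:
    def test_simulated_horseshoe_round_trip(self, arch):
        em = cntn4_event_model(p_horseshoe=1.0, p_hump=0.0, p_partial=0.0,
                               p_adhesion=0.0, random_pickup=False,
                               horseshoe_force_sd=1e-9,
                               plateau_len_range=(40.0, 40.0))
        found = 0
        for seed in range(7, 13):
            cfg = SimConfig(noise_sd_pN=5.0, seed=seed)
            script = draw_event_sequence(arch, em, seed)
            curve, _ = synthesize_curve(script, cfg)
            a = analyze_curve(curve)
            label_analyses([a], REF_MIX)
            reports = detect_long_plateau(preprocess(curve), a)
            if not reports:
                continue
            found += 1
            assert reports[0].magnitude == pytest.approx(20.0, abs=3.0)
            # the measured span covers the scripted 40 nm shelf plus up to
            # a few nm of entry/exit ramp at the detector's smoothing scale
            assert 36.0 <= reports[0].extra["span_nm"] <= 47.0
            assert reports[0].valid_position
        assert found >= 4

    def test_feature_free_curves_mostly_empty(self, arch, plain_event_model):
        cfg = SimConfig(noise_sd_pN=5.0, seed=8)
        n_flagged = 0
        for seed in range(40):
            script = draw_event_sequence(arch, plain_event_model, 100 + seed)
            curve, _ = synthesize_curve(script, cfg)
            a = analyze_curve(curve)
            label_analyses([a], REF_MIX)
            if detect_long_plateau(preprocess(curve), a):
                n_flagged += 1
        assert n_flagged == 0

    def test_late_shelf_flagged_invalid_position(self):
        # handcrafted trace: one peak, then a 40 nm shelf at 20 pN placed
        # after an FnIII-labeled event
        sep = np.arange(0.1, 120, 0.1)
        force = np.zeros(sep.size)
        rise = (sep > 20) & (sep <= 50)
        force[rise] = np.linspace(5, 90, rise.sum())
        shelf = (sep > 50) & (sep <= 95)
        force[shelf] = 20.0
        curve = ForceCurve(sep, force, {"source_id": "hand"})
        ev = UnfoldingEvent(0, int(np.flatnonzero(sep <= 50)[-1]), 90.0, 55.0, 30.0)
        ev.label = "FnIII"
        a = CurveAnalysis("hand", [ev], 250.0)
        reports = detect_long_plateau(curve, a)
        assert len(reports) == 1
        assert not reports[0].valid_position


class TestPartialDetector:
    def test_flagged_after_igc2_with_few_fniii(self):
        a = _analysis([np.nan, 9.5, 23.5, 30.0, 31.0],
                      labels=["IgC2", "IgC2", "FnIII", "FnIII", "FnIII"])
        reports = detect_partial_fniii(a)
        assert len(reports) == 1
        assert reports[0].extra["n_fniii_following"] == 2

    def test_ordering_rule_blocks_early_partial(self):
        a = _analysis([np.nan, 23.5, 9.5, 30.0],
                      labels=["IgC2", "FnIII", "IgC2", "FnIII"])
        assert detect_partial_fniii(a) == []

    def test_full_fniii_length_not_flagged(self):
        a = _analysis([np.nan, 9.5, 30.6, 31.0],
                      labels=["IgC2", "IgC2", "FnIII", "FnIII"])
        assert detect_partial_fniii(a) == []

    def test_simulated_partial_round_trip(self, arch, quiet_config):
        # under a quasi-static ramp the realized rupture order is
        # force-ordered, so the 23-24 nm partial event lands after all
        # IgC2 events only on curves where its drawn force exceeds
        # theirs; the detector must agree with the ground truth on
        # every curve
        em = cntn4_event_model(p_partial=1.0, p_hump=0.0, p_horseshoe=0.0,
                               p_adhesion=0.0, random_pickup=False)
        n_flagged = 0
        for seed in range(9, 29):
            script = draw_event_sequence(arch, em, seed)
            curve, truth = synthesize_curve(script, quiet_config)
            a = analyze_curve(curve)
            label_analyses([a], REF_MIX)
            reports = detect_partial_fniii(a)
            dom = truth[truth["kind"].isin(["domain", "partial"])]
            i_partial = dom.index[dom["kind"] == "partial"]
            expected = False
            if len(i_partial):
                after = dom.loc[i_partial[0] + 1:]
                expected = (after["dclass"] != "IgC2").all()
            if expected and a.n_peaks == script.n_domain_events():
                assert len(reports) == 1
                assert 22.6 <= reports[0].magnitude <= 24.9
                n_flagged += 1
            elif not expected:
                assert reports == []
        assert n_flagged >= 3
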