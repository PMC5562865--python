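"""Ground-truth scripts and quasi-static curve synthesis."""

import numpy as np
import pytest
from scipy import stats

from cntnmech.simulate import (
    ScriptedEvent,
    SimConfig,
    UnfoldingScript,
    cntn4_event_model,
    draw_event_sequence,
    synthesize_curve,
    synthesize_dataset,
)
from cntnmech.wlc import WLCParams, wlc_force


class TestScripts:
    def test_full_attachment_gives_one_event_per_module(self, arch, plain_event_model):
        script = draw_event_sequence(arch, plain_event_model, 5)
        assert script.n_domain_events() == 10
        assert all(e.dL > 0 for e in script.events)

    def test_seed_is_mandatory(self, arch, plain_event_model):
        with pytest.raises(ValueError):
            draw_event_sequence(arch, plain_event_model, None)

    def test_partial_placed_after_igc2_with_at_most_three_fniii(self, arch):
        em = cntn4_event_model(p_partial=1.0, p_hump=0.0, p_horseshoe=0.0,
                               random_pickup=False)
        for seed in range(3, 13):
            script = draw_event_sequence(arch, em, seed)
            kinds = [e.kind for e in script.events]
            assert kinds.count("partial") == 1
            i = kinds.index("partial")
            ev = script.events[i]
            assert 23.1 <= ev.dL <= 24.4
            assert all(e.dclass != "IgC2" for e in script.events[i + 1:])
            n_fn_after = sum(1 for e in script.events[i + 1:] if e.dclass == "FnIII")
            assert n_fn_after <= 3

    def test_horseshoe_precedes_all_fniii(self, arch):
        em = cntn4_event_model(p_horseshoe=1.0, p_hump=0.0, p_partial=0.0,
                               random_pickup=False)
        for seed in range(20):
            script = draw_event_sequence(arch, em, seed)
            kinds = [e.kind for e in script.events]
            i = kinds.index("horseshoe")
            assert all(e.dclass != "FnIII" for e in script.events[:i])

    def test_igc2_clamp_respected(self, arch, plain_event_model):
        limits = {d.name: d.n_extensible * arch.l_aa for d in arch.domains}
        for seed in range(50):
            script = draw_event_sequence(arch, plain_event_model, seed)
            for e in script.events:
                if e.dclass == "IgC2":
                    assert e.dL <= limits[e.name] + 1e-9

    def test_fniii_draw_mean_matches_truncated_normal_oracle(self, arch):
        em = cntn4_event_model(p_hump=0.0, p_partial=0.0, p_horseshoe=0.0,
                               random_pickup=False)
        draws = []
        for seed in range(1, 1001):
            script = draw_event_sequence(arch, em, seed)
            draws += [e.dL for e in script.events if e.dclass == "FnIII"]
        draws = np.asarray(draws)
        # oracle: truncated-normal mean at the per-domain window; the
        # clamp window differs per module, use the loosest common bounds
        mu, sd = em.fniii_dl_mean, em.fniii_dl_sd
        los, his = [], []
        for d in arch.by_class("FnIII"):
            lo = max(em.min_dl, mu - 3 * sd)
            hi = min(mu + 3 * sd, d.n_res * arch.l_aa)
            los.append(lo)
            his.append(hi)
        oracle = np.mean([
            stats.truncnorm.mean((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
            for lo, hi in zip(los, his)
        ])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - oracle) < 2 * se + 1e-6


class TestSynthesis:
    def test_empty_script_is_low_force_until_detachment(self, quiet_config):
        script = UnfoldingScript((), lc0=60.0, detach_force=150.0,
                                 adhesion=None, seed=1)
        curve, truth = synthesize_curve(script, quiet_config)
        assert np.all(np.diff(curve.separation) > 0)
        assert truth["kind"].tolist() == ["detach"]
        # a single monotone rise, then baseline
        i_det = int(truth["sample_index"].iloc[0])
        assert np.all(curve.force[i_det + 1:] == 0.0)

    def test_single_event_round_trip(self, quiet_config):
        from cntnmech.pipeline import analyze_curve

        ev = ScriptedEvent("domain", "d1", "FnIII", 30.0, 150.0)
        script = UnfoldingScript((ev,), lc0=60.0, detach_force=250.0,
                                 adhesion=None, seed=2)
        curve, truth = synthesize_curve(script, quiet_config)
        a = analyze_curve(curve)
        assert a.n_peaks == 1
        assert a.events[0].dL == pytest.approx(30.0, abs=0.1)

    def test_noiseless_branch_sits_on_wlc_through_compliance(self, quiet_config):
        ev = ScriptedEvent("domain", "d1", "FnIII", 30.0, 120.0)
        script = UnfoldingScript((ev,), lc0=60.0, detach_force=200.0,
                                 adhesion=None, seed=3)
        curve, truth = synthesize_curve(script, quiet_config)
        i_rupt = int(truth["sample_index"].iloc[0])
        p = WLCParams(quiet_config.Lp, 60.0, quiet_config.T)
        x = curve.separation[10:i_rupt]
        assert np.max(np.abs(wlc_force(x, p) - curve.force[10:i_rupt])) < 1e-3

    def test_conservation_of_contour_length(self, arch, plain_event_model,
                                            quiet_config):
        from cntnmech.pipeline import analyze_curve

        script = draw_event_sequence(arch, plain_event_model, 11)
        curve, _ = synthesize_curve(script, quiet_config)
        a = analyze_curve(curve)
        total = script.lc0 + sum(e.dL for e in script.events)
        # last fitted branch (closing the final event) carries the full contour
        final_lc = a.events[-1].Lc + a.events[-1].dL
        assert final_lc == pytest.approx(total, rel=0.005)

    def test_determinism_bit_identical(self, arch, quiet_config):
        em = cntn4_event_model()
        cfg = SimConfig(seed=9)
        c1, t1 = synthesize_dataset(5, arch, em, cfg, seed=9)
        c2, t2 = synthesize_dataset(5, arch, em, cfg, seed=9)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.separation, b.separation)
            assert np.array_equal(a.force, b.force)
        assert t1.equals(t2)

    def test_bell_mode_rupture_force_rises_with_speed(self):
        forces = {}
        for v in (0.1, 1.0):  # one decade of pulling speed
            cfg = SimConfig(v_um_per_s=v, noise_sd_pN=0.0, rupture_mode="bell",
                            rate_per_nm=5.0, seed=0)
            f = []
            for seed in range(200):
                ev = ScriptedEvent("domain", "d", "FnIII", 25.0, 0.0)
                script = UnfoldingScript((ev,), lc0=40.0, detach_force=400.0,
                                         adhesion=None, seed=seed)
                _, truth = synthesize_curve(script, cfg)
                dom = truth[truth["kind"] == "domain"]
                if len(dom):
                    f.append(float(dom["f_at_rupture"].iloc[0]))
            forces[v] = np.mean(f)
        assert forces[1.0] > forces[0.1] + 5.0


class TestDatasets:
    def test_counts_and_truth_rows(self, arch, plain_event_model):
        cfg = SimConfig(seed=4, noise_sd_pN=0.0)
        curves, truth = synthesize_dataset(10, arch, plain_event_model, cfg, seed=4)
        assert len(curves) == 10
        assert truth["curve_id"].nunique() == 10
        per = truth[truth["kind"] == "domain"].groupby("curve_id").size()
        assert (per == 10).all()

    def test_junk_fraction_feeds_quality_filter(self, arch, plain_event_model):
        from cntnmech.pipeline import analyze_curve, filter_curves

        cfg = SimConfig(seed=11)
        curves, truth = synthesize_dataset(
            100, arch, plain_event_model, cfg, junk_fraction=0.5, seed=11)
        analyses = [analyze_curve(c) for c in curves]
        selected, _ = filter_curves(analyses)
        n_junk = truth.groupby("curve_id")["is_junk"].any().sum()
        # junk curves have <4 peaks by construction; intact full-length
        # curves virtually always keep >=4; binomial scatter around 50
        assert 35 <= len(selected) <= 65
        assert len(selected) == pytest.approx(100 - n_junk, abs=8)

    def test_dataset_seed_required(self, arch, plain_event_model):
        with pytest.raises(ValueError):
            synthesize_dataset(3, arch, plain_event_model, SimConfig())
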