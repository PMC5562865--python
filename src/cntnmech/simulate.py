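"""Synthetic saw-tooth force-curve generator.

A constant-velocity pull of a multidomain chain through a Hookean
cantilever is simulated quasi-statically: at every piezo position ``z``
the tip-sample separation ``x`` solves the force balance

    k_c (z - x) = F_wlc(x; Lc)

between cantilever restoring force and worm-like-chain tension of the
currently released contour length ``Lc``.  Scripted unfolding events
raise ``Lc`` by their length increment when the tension reaches their
rupture force (phenomenological mode) or by a Bell--Evans survival draw
(kinetic mode), producing the characteristic saw-tooth.  The generator
also emulates the secondary signatures seen in contactin pulling
experiments: two-stage FnIII unfolding through a 13-18 nm intermediate
("hump"), an initial 23.1-24.4 nm partial unfolding of the first FnIII
module, a ~20 pN constant-force plateau from the opening of the
horseshoe arrangement of the N-terminal IgC2 modules, nonspecific
tip-surface adhesion near contact, and Gaussian force noise.

Every curve carries its ground-truth script, so the downstream
inference pipeline can be validated by round trips.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import ProteinArchitecture, cntn4_architecture
from .curve import ForceCurve
from .wlc import KB_PN_NM, wlc_contour_from_point

__all__ = [
    "EventModel",
    "SimConfig",
    "ScriptedEvent",
    "UnfoldingScript",
    "SimulationError",
    "cntn4_event_model",
    "draw_event_sequence",
    "synthesize_curve",
    "synthesize_dataset",
]


class SimulationError(RuntimeError):
    """Force-balance solver failure or inconsistent script."""


def _check_mixture(means, sds, weights, what: str) -> None:
    if not (len(means) == len(sds) == len(weights)):
        raise ValueError(f"{what}: means/sds/weights length mismatch")
    if any(s <= 0 for s in sds):
        raise ValueError(f"{what}: sds must be positive")
    if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"{what}: weights must be non-negative and sum to 1")


@dataclasses.dataclass(frozen=True)
class EventModel:
    """Per-class event statistics and feature probabilities.

    Length increments (nm) are drawn from class-conditional Gaussians:
    a two-component mixture for the disulfide-clamped IgC2 modules and a
    single component for FnIII.  Rupture forces (pN) are drawn from
    two-component mixtures per class.  Draws are truncated at
    ``trunc_sds`` standard deviations and (IgC2/FnIII) at the physical
    contour limit of the drawing domain when ``clamp`` is on.
    """

    igc2_dl_means: tuple[float, ...] = (9.5, 17.4)
    igc2_dl_sds: tuple[float, ...] = (3.3, 3.3)
    igc2_dl_weights: tuple[float, ...] = (0.5, 0.5)
    fniii_dl_mean: float = 30.6
    fniii_dl_sd: float = 3.7
    igc2_f_means: tuple[float, ...] = (61.0, 95.0)
    igc2_f_sds: tuple[float, ...] = (12.9, 26.4)
    igc2_f_weights: tuple[float, ...] = (0.5, 0.5)
    fniii_f_means: tuple[float, ...] = (79.4, 145.0)
    fniii_f_sds: tuple[float, ...] = (21.5, 48.6)
    fniii_f_weights: tuple[float, ...] = (0.5, 0.5)
    p_hump: float = 0.15
    hump_dl_range: tuple[float, float] = (13.0, 18.0)
    hump_force_mean: float = 60.0
    hump_force_sd: float = 15.0
    p_partial: float = 0.1
    partial_dl_range: tuple[float, float] = (23.1, 24.4)
    p_horseshoe: float = 0.1
    horseshoe_force: float = 20.0
    horseshoe_force_sd: float = 1.5
    plateau_len_range: tuple[float, float] = (35.0, 45.0)
    p_adhesion: float = 0.1
    adhesion_height_range: tuple[float, float] = (30.0, 150.0)
    detach_force_mean: float = 250.0
    detach_force_sd: float = 100.0
    detach_force_bounds: tuple[float, float] = (50.0, 600.0)
    min_dl: float = 2.0
    f_floor: float = 35.0
    trunc_sds: float = 3.0
    clamp: bool = True
    random_pickup: bool = True

    def __post_init__(self) -> None:
        for p, name in (
            (self.p_hump, "p_hump"),
            (self.p_partial, "p_partial"),
            (self.p_horseshoe, "p_horseshoe"),
            (self.p_adhesion, "p_adhesion"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        _check_mixture(self.igc2_dl_means, self.igc2_dl_sds, self.igc2_dl_weights, "IgC2 dL")
        _check_mixture(self.igc2_f_means, self.igc2_f_sds, self.igc2_f_weights, "IgC2 F")
        _check_mixture(self.fniii_f_means, self.fniii_f_sds, self.fniii_f_weights, "FnIII F")
        if self.fniii_dl_sd <= 0 or self.hump_force_sd <= 0:
            raise ValueError("standard deviations must be positive")


def cntn4_event_model(**overrides) -> EventModel:
    """Event model parameterized by the measured CNTN4 populations."""
    return EventModel(**overrides)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Acquisition and mechanics settings of one simulated experiment."""

    v_um_per_s: float = 0.5
    k_c_N_per_m: float = 0.02
    rate_per_nm: float = 10.0
    noise_sd_pN: float = 5.0
    baseline_offset_pN: float = 0.0
    rupture_mode: str = "phenomenological"
    bell_k0: float = 1e-4
    bell_dx: float = 0.4
    Lp: float = 0.4
    T: float = 300.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.v_um_per_s <= 0 or self.k_c_N_per_m <= 0 or self.rate_per_nm <= 0:
            raise ValueError("v, k_c and rate must be positive")
        if self.noise_sd_pN < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rupture_mode not in ("phenomenological", "bell"):
            raise ValueError(f"unknown rupture_mode {self.rupture_mode!r}")

    @property
    def k_c_pN_per_nm(self) -> float:
        return self.k_c_N_per_m * 1000.0

    @property
    def loading_rate_pN_per_s(self) -> float:
        """Nominal loading rate r_f = k_c * v."""
        return self.k_c_pN_per_nm * self.v_um_per_s * 1000.0

    @property
    def kBT(self) -> float:
        return KB_PN_NM * self.T


@dataclasses.dataclass(frozen=True)
class ScriptedEvent:
    """One scripted unfolding (or plateau) in ground truth."""

    kind: str  # "domain" | "partial" | "horseshoe"
    name: str
    dclass: str  # "IgC2" | "FnIII" | "" for horseshoe
    dL: float
    f_rupt: float
    hump: bool = False
    hump_dl: float = 0.0
    hump_force: float = 0.0
    span: float = 0.0  # plateau span in nm, horseshoe only


@dataclasses.dataclass(frozen=True)
class UnfoldingScript:
    """Ground-truth record of one curve."""

    events: tuple[ScriptedEvent, ...]
    lc0: float
    detach_force: float
    adhesion: tuple[float, float, float] | None  # (position, height, width)
    seed: int

    def n_domain_events(self) -> int:
        return sum(1 for e in self.events if e.kind != "horseshoe")


def _trunc_normal(rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal; degenerates to clip when the
    window is (nearly) empty."""
    if hi <= lo:
        return lo
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mu, lo), hi))


def draw_event_sequence(
    arch: ProteinArchitecture, em: EventModel, rng_seed: int
) -> UnfoldingScript:
    """Draw one ground-truth unfolding script.

    Every module contributes one event whose increment and rupture force
    follow the class-conditional distributions of ``em``.  IgC2 modules
    are tied to the mixture component whose mean is nearest their
    predicted unfolding length, so the two measured IgC2 length
    populations map onto short- and long-loop modules.  Event order is a
    random interleaving; the partial-FnIII event (when drawn) replaces
    the first FnIII module and is placed after all IgC2 events with the
    remaining FnIII events after it; the horseshoe plateau (when drawn)
    is inserted before the first FnIII-class event.
    """
    if rng_seed is None:
        raise ValueError("rng_seed is required: scripts must be reproducible")
    rng = np.random.default_rng(rng_seed)
    l_aa = arch.l_aa
    igc2_means = np.asarray(em.igc2_dl_means)

    # nonspecific pickup: the tip grabs the chain at a random position
    # along the contour while the substrate holds one terminus, so a
    # random-length terminal-anchored span of modules is load-bearing.
    # With pickup off the whole chain is engaged (full attachment).
    domains = arch.domains
    if em.random_pickup:
        k = int(rng.integers(1, len(domains) + 1))
        from_n_terminus = rng.random() < 0.5
        domains = domains[:k] if from_n_terminus else domains[-k:]

    events: list[ScriptedEvent] = []
    for d in domains:
        if d.dclass == "IgC2":
            predicted = d.n_extensible * l_aa - d.d_fold
            comp = int(np.argmin(np.abs(igc2_means - predicted)))
            mu, sd = em.igc2_dl_means[comp], em.igc2_dl_sds[comp]
            clamp_hi = d.n_extensible * l_aa if em.clamp else math.inf
            dl = _trunc_normal(
                rng, mu, sd,
                max(em.min_dl, mu - em.trunc_sds * sd),
                min(mu + em.trunc_sds * sd, clamp_hi),
            )
            fcomp = rng.choice(len(em.igc2_f_weights), p=em.igc2_f_weights)
            fmu, fsd = em.igc2_f_means[fcomp], em.igc2_f_sds[fcomp]
            f = _trunc_normal(
                rng, fmu, fsd,
                max(em.f_floor, fmu - em.trunc_sds * fsd),
                fmu + em.trunc_sds * fsd,
            )
            events.append(ScriptedEvent("domain", d.name, "IgC2", dl, f))
        else:
            mu, sd = em.fniii_dl_mean, em.fniii_dl_sd
            clamp_hi = d.n_res * l_aa if em.clamp else math.inf
            dl = _trunc_normal(
                rng, mu, sd,
                max(em.min_dl, mu - em.trunc_sds * sd),
                min(mu + em.trunc_sds * sd, clamp_hi),
            )
            fcomp = rng.choice(len(em.fniii_f_weights), p=em.fniii_f_weights)
            fmu, fsd = em.fniii_f_means[fcomp], em.fniii_f_sds[fcomp]
            f = _trunc_normal(
                rng, fmu, fsd,
                max(em.f_floor, fmu - em.trunc_sds * fsd),
                fmu + em.trunc_sds * fsd,
            )
            hump = False
            hump_dl = hump_force = 0.0
            if rng.random() < em.p_hump:
                cand = rng.uniform(*em.hump_dl_range)
                if dl - cand >= 5.0 and f - 10.0 > em.f_floor:
                    hump = True
                    hump_dl = float(cand)
                    hump_force = _trunc_normal(
                        rng, em.hump_force_mean, em.hump_force_sd,
                        em.f_floor, f - 10.0,
                    )
            events.append(
                ScriptedEvent("domain", d.name, "FnIII", dl, f, hump, hump_dl, hump_force)
            )

    arch_first_fn = next((d.name for d in arch.domains if d.dclass == "FnIII"), None)
    partial = (
        rng.random() < em.p_partial
        and any(e.name == arch_first_fn for e in events)
    )
    if partial:
        igc2_ev = [e for e in events if e.dclass == "IgC2"]
        fniii_ev = [e for e in events if e.dclass == "FnIII"]
        first_fn = next(e for e in fniii_ev if e.name == arch_first_fn)
        rest_fn = [e for e in fniii_ev if e is not first_fn]
        # the partial event is observed strictly after the IgC2 phase, so
        # its threshold is pinned just above the strongest engaged IgC2
        if igc2_ev:
            f = max(e.f_rupt for e in igc2_ev) + float(rng.uniform(2.0, 10.0))
        else:
            fcomp = rng.choice(len(em.fniii_f_weights), p=em.fniii_f_weights)
            fmu, fsd = em.fniii_f_means[fcomp], em.fniii_f_sds[fcomp]
            f = _trunc_normal(
                rng, fmu, fsd,
                max(em.f_floor, fmu - em.trunc_sds * fsd),
                fmu + em.trunc_sds * fsd,
            )
        partial_ev = ScriptedEvent(
            "partial", first_fn.name, "FnIII",
            float(rng.uniform(*em.partial_dl_range)), f,
        )
        order = list(rng.permutation(len(igc2_ev)))
        ordered = [igc2_ev[i] for i in order] + [partial_ev]
        order_fn = list(rng.permutation(len(rest_fn)))
        ordered += [rest_fn[i] for i in order_fn]
    else:
        order = list(rng.permutation(len(events)))
        ordered = [events[i] for i in order]

    # the horseshoe is a bent arrangement of the first four IgC2 modules;
    # its opening plateau can only appear when that whole region bears load
    first_igc2 = [d.name for d in arch.domains if d.dclass == "IgC2"][:4]
    engaged_names = {d.name for d in domains}
    horseshoe_possible = all(name in engaged_names for name in first_igc2)
    if horseshoe_possible and rng.random() < em.p_horseshoe:
        pf = _trunc_normal(
            rng, em.horseshoe_force, em.horseshoe_force_sd,
            5.0, em.horseshoe_force + em.trunc_sds * em.horseshoe_force_sd,
        )
        span = float(rng.uniform(*em.plateau_len_range))
        fn_idx = [i for i, e in enumerate(ordered) if e.dclass == "FnIII"]
        hi_pos = fn_idx[0] if fn_idx else len(ordered)
        pos = int(rng.integers(0, hi_pos + 1))
        ordered.insert(pos, ScriptedEvent("horseshoe", "horseshoe", "", 0.0, pf, span=span))

    adhesion = None
    if rng.random() < em.p_adhesion:
        adhesion = (
            float(rng.uniform(1.0, 4.0)),
            float(rng.uniform(*em.adhesion_height_range)),
            float(rng.uniform(1.0, 2.5)),
        )

    detach = _trunc_normal(
        rng, em.detach_force_mean, em.detach_force_sd, *em.detach_force_bounds
    )
    lc0 = sum(d.d_fold + d.linker_after * l_aa for d in domains)
    return UnfoldingScript(tuple(ordered), lc0, detach, adhesion, int(rng_seed))


def _wlc_f(x: float, Lc: float, c: float) -> float:
    r = x / Lc
    return c * (0.25 / (1.0 - r) ** 2 - 0.25 + r)


def _balance(z: float, Lc: float, kc: float, c: float, x_lo: float) -> float:
    """Solve k_c (z - x) = F_wlc(x; Lc) for x by bisection.

    The residual g(x) = k_c (z - x) - F_wlc(x) is strictly decreasing,
    positive at ``x_lo`` (previous equilibrium) and negative near full
    extension, so simple bisection is robust and fast.
    """
    hi = min(z, Lc * (1.0 - 1e-9))
    lo = min(x_lo, hi)
    if kc * (z - hi) - _wlc_f(hi, Lc, c) >= 0.0:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if kc * (z - mid) - _wlc_f(mid, Lc, c) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def synthesize_curve(
    script: UnfoldingScript, cfg: SimConfig
) -> tuple[ForceCurve, pd.DataFrame]:
    """Render one script into a sampled retraction trace.

    Returns the noisy :class:`ForceCurve` and a per-event ground-truth
    table (rupture positions, released increments, feature tags).
    """
    kc = cfg.k_c_pN_per_nm
    c = cfg.kBT / cfg.Lp
    dz = 1.0 / cfg.rate_per_nm
    v_nm_s = cfg.v_um_per_s * 1000.0
    dt = dz / v_nm_s
    rng = np.random.default_rng((int(script.seed), 1))

    # expand hump events into two sub-ruptures
    queue: list[dict] = []
    for e in script.events:
        if e.kind == "horseshoe":
            queue.append({"ev": e, "stage": 0, "force": e.f_rupt})
        elif e.hump:
            queue.append({"ev": e, "stage": 1, "dL": e.hump_dl, "force": e.hump_force})
            queue.append({"ev": e, "stage": 2, "dL": e.dL - e.hump_dl, "force": e.f_rupt})
        else:
            queue.append({"ev": e, "stage": 0, "dL": e.dL, "force": e.f_rupt})

    phenom = cfg.rupture_mode == "phenomenological"

    def next_item() -> dict | None:
        """Next unit to rupture.  Under a quasi-static ramp the pending
        unit with the lowest threshold force yields first, so the
        realized order is force-ordered (the scripted order is kept
        verbatim in kinetic mode, where disorder arises from the rate
        draws).  A hump intermediate commits its domain: the completion
        stage must rupture before any other unit."""
        if not queue:
            return None
        if not phenom:
            return queue[0]
        for item in queue:
            if item.get("committed"):
                return item
        avail = [it for it in queue if it.get("stage") != 2]
        return min(avail, key=lambda it: it["force"])

    lc_total = script.lc0 + sum(e.dL for e in script.events)
    span_total = sum(e.span for e in script.events if e.kind == "horseshoe")
    z_max = lc_total + span_total + script.detach_force / kc + 20.0

    xs: list[float] = []
    fs: list[float] = []
    truth_rows: list[dict] = []
    Lc = script.lc0
    x_prev = 0.0
    z = 0.0
    plateau_end: float | None = None
    plateau_force = 0.0
    plateau_item: dict | None = None
    detached = False
    detach_row: dict | None = None

    while z < z_max and not detached:
        z += dz
        if plateau_end is not None:
            x = z - plateau_force / kc
            if x <= x_prev:  # entry transient: keep separation increasing
                x = x_prev + 1e-6
            F = plateau_force
            if x >= plateau_end:
                Lc = wlc_contour_from_point(x, plateau_force, cfg.Lp, cfg.T)
                item = plateau_item
                queue.remove(item)
                e = item["ev"]
                truth_rows.append({
                    "kind": "horseshoe", "name": e.name, "dclass": "",
                    "dL_true": Lc - item["lc_before"], "f_script": e.f_rupt,
                    "f_at_rupture": plateau_force, "x_rupture": x, "z_rupture": z,
                    "sample_index": len(xs), "hump": False, "span": e.span,
                })
                plateau_end = None
        else:
            x = _balance(z, Lc, kc, c, x_prev)
            F = kc * (z - x)
            item = next_item()
            if item is not None and item["ev"].kind == "horseshoe":
                e = item["ev"]
                if F >= e.f_rupt:
                    plateau_force = e.f_rupt
                    x = z - plateau_force / kc
                    if x <= x_prev:
                        x = x_prev + 1e-6
                    F = plateau_force
                    plateau_end = x + e.span
                    item["lc_before"] = Lc
                    plateau_item = item
            elif item is not None:
                ruptured = False
                if phenom:
                    ruptured = F >= item["force"]
                else:
                    haz = cfg.bell_k0 * math.exp(F * cfg.bell_dx / cfg.kBT)
                    ruptured = rng.random() < -math.expm1(-haz * dt)
                if ruptured:
                    e = item["ev"]
                    truth_rows.append({
                        "kind": e.kind, "name": e.name, "dclass": e.dclass,
                        "dL_true": item["dL"], "f_script": item["force"],
                        "f_at_rupture": F, "x_rupture": x, "z_rupture": z,
                        "sample_index": len(xs),
                        "hump": item["stage"] == 1, "span": 0.0,
                    })
                    # the crest sample itself is recorded; the released
                    # contour takes effect from the next piezo step
                    Lc += item["dL"]
                    if item["stage"] == 1:
                        for other in queue:
                            if other.get("stage") == 2 and other["ev"] is e:
                                other["committed"] = True
                                break
                    queue.remove(item)
            else:
                if F >= script.detach_force:
                    detached = True
                    detach_row = {
                        "kind": "detach", "name": "detach", "dclass": "",
                        "dL_true": 0.0, "f_script": script.detach_force,
                        "f_at_rupture": F, "x_rupture": x, "z_rupture": z,
                        "sample_index": len(xs), "hump": False, "span": 0.0,
                    }
        if x <= x_prev:
            x = x_prev + 1e-9
        xs.append(x)
        fs.append(F)
        x_prev = x

    if queue and not detached:
        raise SimulationError(
            f"force-balance march ended at z={z:.1f} nm with {len(queue)} events pending"
        )
    if detach_row is not None:
        truth_rows.append(detach_row)

    # contact-free tail after detachment (baseline for offset correction)
    n_attached = len(xs)
    tail_len = max(30.0, 0.15 * (xs[-1] if xs else 50.0))
    n_tail = int(tail_len / dz)
    x_last = xs[-1] if xs else 0.0
    for i in range(1, n_tail + 1):
        xs.append(x_last + i * dz)
        fs.append(0.0)

    sep = np.asarray(xs)
    force = np.asarray(fs)
    if script.adhesion is not None:
        x0, h, w = script.adhesion
        bump = h * np.clip(1.0 - np.abs(sep - x0) / w, 0.0, None)
        bump[n_attached:] = 0.0
        force = force + bump
    force = force + cfg.baseline_offset_pN
    if cfg.noise_sd_pN > 0:
        force = force + rng.normal(0.0, cfg.noise_sd_pN, size=force.size)

    meta = {
        "v_um_per_s": cfg.v_um_per_s,
        "k_c_N_per_m": cfg.k_c_N_per_m,
        "seed": script.seed,
        "source_id": f"sim-{script.seed}",
    }
    curve = ForceCurve(sep, force, meta)
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "name", "dclass", "dL_true", "f_script", "f_at_rupture",
                 "x_rupture", "z_rupture", "sample_index", "hump", "span"],
    )
    return curve, truth


def _noise_only_curve(seed: int, cfg: SimConfig, length_nm: float = 200.0) -> ForceCurve:
    """A failed-attachment trace: baseline noise only."""
    rng = np.random.default_rng((int(seed), 1))
    dz = 1.0 / cfg.rate_per_nm
    sep = np.arange(dz, length_nm, dz)
    force = cfg.baseline_offset_pN + rng.normal(0.0, max(cfg.noise_sd_pN, 0.1), sep.size)
    return ForceCurve(sep, force, {
        "v_um_per_s": cfg.v_um_per_s, "k_c_N_per_m": cfg.k_c_N_per_m,
        "seed": int(seed), "source_id": f"sim-{seed}",
    })


def synthesize_dataset(
    n_curves: int,
    arch: ProteinArchitecture | None = None,
    em: EventModel | None = None,
    cfg: SimConfig | None = None,
    junk_fraction: float = 0.0,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Generate a batch of curves plus a ground-truth table.

    ``junk_fraction`` of curves emulate rejected traces: failed
    attachment (flat noise) or early detachment after fewer than four
    events.  Per-curve seeds derive deterministically from ``seed`` (or
    ``cfg.seed``), so identical inputs give bit-identical batches.
    """
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    arch = arch if arch is not None else cntn4_architecture()
    em = em if em is not None else cntn4_event_model()
    cfg = cfg if cfg is not None else SimConfig()
    master_seed = seed if seed is not None else cfg.seed
    if master_seed is None:
        raise ValueError("a seed is required (pass seed= or set cfg.seed)")
    rng = np.random.default_rng(master_seed)
    curve_seeds = rng.integers(0, 2**31 - 1, size=n_curves)
    junk_draw = rng.random(n_curves)
    junk_kind = rng.integers(0, 2, size=n_curves)

    curves: list[ForceCurve] = []
    truth_parts: list[pd.DataFrame] = []
    for i in range(n_curves):
        cid = f"curve_{i:04d}"
        cseed = int(curve_seeds[i])
        is_junk = junk_draw[i] < junk_fraction
        if is_junk and junk_kind[i] == 0:
            curve = _noise_only_curve(cseed, cfg)
            truth = pd.DataFrame(columns=["kind", "name", "dclass", "dL_true",
                                          "f_script", "f_at_rupture", "x_rupture",
                                          "z_rupture", "sample_index", "hump", "span"])
            jk = "no_attach"
        else:
            script = draw_event_sequence(arch, em, cseed)
            if is_junk:
                keep = int(np.random.default_rng((cseed, 2)).integers(1, 4))
                kept = [e for e in script.events if e.kind != "horseshoe"][:keep]
                script = dataclasses.replace(script, events=tuple(kept))
                jk = "early_detach"
            else:
                jk = ""
            curve, truth = synthesize_curve(script, cfg)
        curve.meta["source_id"] = cid
        curve.meta["junk"] = jk
        if truth.empty:
            # keep every curve visible in the truth table, events or not
            truth = pd.DataFrame([{
                "kind": "none", "name": "", "dclass": "", "dL_true": np.nan,
                "f_script": np.nan, "f_at_rupture": np.nan, "x_rupture": np.nan,
                "z_rupture": np.nan, "sample_index": -1, "hump": False, "span": 0.0,
            }])
        truth.insert(0, "curve_id", cid)
        truth["is_junk"] = is_junk
        truth["junk_type"] = jk
        curves.append(curve)
        truth_parts.append(truth)

    truth_df = pd.concat(truth_parts, ignore_index=True)
    if out_dir is not None:
        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for curve in curves:
            _io.write_curve_file(curve, out / f"{curve.source_id}.tsv")
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    return curves, truth_df
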