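"""From raw retraction trace to per-event (ΔL, Fmax).

The inference chain mirrors standard single-molecule force-spectroscopy
practice: baseline correction, saw-tooth rupture detection, segmentation
of the trace into rising branches, a worm-like-chain fit per branch
(persistence length fixed by default so contour lengths stay comparable),
and contour-length increments ΔL_i = Lc_{i+1} - Lc_i between consecutive
branches.  Curve-level quality filters keep traces with at least four
clear maxima and single out the strong-attachment subset (7-10 peaks and
a high final detachment force) in which the whole molecule was stretched.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .curve import ForceCurve
from .wlc import InsufficientDataError, WLCFit, fit_wlc_segment

__all__ = [
    "UnfoldingEvent",
    "CurveAnalysis",
    "preprocess",
    "detect_ruptures",
    "extract_events",
    "analyze_curve",
    "filter_curves",
    "events_to_table",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class UnfoldingEvent:
    """One saw-tooth: peak force, fitted contour length, increment."""

    index: int
    peak_sample: int
    Fmax: float
    Lc: float
    dL: float  # nan for the first event of a curve
    branch_fit: WLCFit | None = None
    label: str = "unassigned"


@dataclasses.dataclass
class CurveAnalysis:
    """Per-curve result of the extraction chain.

    ``n_peaks`` counts visible force maxima.  It equals the number of
    events straight out of extraction; after a two-stage intermediate
    unfolding is merged into one event the visible count is preserved
    in ``n_visible_peaks`` so quality filters still see every maximum.
    """

    curve_id: str
    events: list[UnfoldingEvent]
    detachment_force: float
    passes_quality: bool = False
    strong_attachment: bool = False
    n_visible_peaks: int | None = None

    @property
    def n_peaks(self) -> int:
        if self.n_visible_peaks is not None:
            return self.n_visible_peaks
        return len(self.events)


def _median_dx(curve: ForceCurve) -> float:
    return float(np.median(np.diff(curve.separation)))


def _smooth(force: np.ndarray, dx: float, window_nm: float) -> np.ndarray:
    w = max(3, int(round(window_nm / dx)))
    if w % 2 == 0:
        w += 1
    return ndimage.uniform_filter1d(force, size=w, mode="nearest")


def preprocess(
    raw: ForceCurve, smooth_window_nm: float = 0.0, baseline_fraction: float = 0.1
) -> ForceCurve:
    """Subtract the force baseline (median of the final contact-free
    fraction of samples); optionally apply moving-median smoothing.

    Separations are never touched.
    """
    if len(raw) < 50:
        raise ValueError(f"curve too short to preprocess: {len(raw)} samples")
    n_tail = max(5, int(len(raw) * baseline_fraction))
    baseline = float(np.median(raw.force[-n_tail:]))
    force = raw.force - baseline
    if smooth_window_nm > 0:
        dx = _median_dx(raw)
        w = max(3, int(round(smooth_window_nm / dx)))
        force = ndimage.median_filter(force, size=w, mode="nearest")
    meta = dict(raw.meta)
    meta["baseline_pN"] = baseline
    return ForceCurve(raw.separation.copy(), force, meta)


def detect_ruptures(
    curve: ForceCurve,
    min_drop: float = 20.0,
    min_peak_force: float = 30.0,
    min_separation: float = 8.0,
    drop_window_nm: float = 2.0,
    smooth_nm: float = 0.5,
) -> np.ndarray:
    """Indices of rupture peaks.

    A rupture is a local maximum of the (lightly smoothed) force with
    prominence and a subsequent fall of at least ``min_drop`` pN within
    ``drop_window_nm`` nm of separation, pre-drop force at least
    ``min_peak_force`` pN, and separation beyond ``min_separation`` nm
    (peaks closer to the surface are treated as nonspecific adhesion).
    Returns strictly increasing sample indices; empty result allowed.
    """
    dx = _median_dx(curve)
    fs = _smooth(curve.force, dx, smooth_nm)
    w_drop = max(1, int(round(drop_window_nm / dx)))
    peaks, _ = signal.find_peaks(fs, height=min_peak_force, prominence=min_drop * 0.8)
    out: list[int] = []
    n = fs.size
    for p in peaks:
        if curve.separation[p] < min_separation:
            continue
        lo = p + 1
        hi = min(n, p + 1 + w_drop)
        if lo >= n:
            continue
        if fs[p] - np.min(fs[lo:hi]) < min_drop:
            continue
        # refine to the raw-trace maximum in a +-0.3 nm neighborhood
        r = max(1, int(round(0.3 / dx)))
        a, b = max(0, p - r), min(n, p + r + 1)
        out.append(int(a + np.argmax(curve.force[a:b])))
    out = sorted(set(out))
    return np.asarray(out, dtype=int)


def extract_events(
    curve: ForceCurve,
    peaks: np.ndarray,
    Lp: float = 0.4,
    T: float = 300.0,
    min_branch_force: float = 10.0,
    min_peak_force: float = 30.0,
    smooth_nm: float = 0.5,
) -> CurveAnalysis:
    """Per-branch WLC fits and contour-length increments.

    Each peak terminates a rising branch running from the preceding
    valley (first sample above ``min_branch_force``) to the peak.  The
    branch is fitted with a fixed-Lp WLC giving Lc; the event records
    Fmax as the smoothed force at the peak and dL as the difference of
    consecutive fitted contour lengths (undefined for the first event).
    A trailing peak after which the force never rises again is the
    detachment of the molecule from the tip: its force is recorded
    separately and it contributes no unfolding event.  Branches whose
    fit fails are dropped with a logged warning and events renumbered.
    """
    curve_id = curve.source_id
    if len(peaks) == 0:
        return CurveAnalysis(curve_id, [], float("nan"))
    dx = _median_dx(curve)
    fs = _smooth(curve.force, dx, smooth_nm)
    f3 = ndimage.uniform_filter1d(curve.force, size=3, mode="nearest")
    peaks = np.asarray(peaks, dtype=int)

    def crest(p: int) -> float:
        # crest force: largest 3-sample mean near the peak; the rupture
        # drop is instantaneous so this tracks the last pre-drop samples
        # without the upward bias of a raw argmax under noise
        r = max(2, int(round(0.3 / dx)))
        a, b = max(0, p - r), min(f3.size, p + r + 1)
        return float(np.max(f3[a:b]))

    detachment_force = float("nan")
    detach_peak = -1
    last = peaks[-1]
    tail = fs[min(last + int(round(2.0 / dx)), fs.size - 1):]
    if tail.size == 0 or np.max(tail) < min_peak_force:
        detachment_force = crest(last)
        detach_peak = int(last)
        peaks = peaks[:-1]

    # segmentation trace: heavier smoothing than peak detection so noise
    # wiggles do not truncate a rising branch
    fseg = _smooth(curve.force, dx, 1.0)

    w_guard = max(3, int(round(1.0 / dx)))

    def branch_start(p: int, lo: int, vtol: float = 8.0) -> int:
        """Walk back from the peak to the start of its final rising
        segment: stop once the segmentation trace climbs ``vtol`` pN
        above the running minimum (i.e. a preceding peak/valley, such
        as an undetected sub-threshold rupture, has been crossed).
        The walk starts one smoothing width before the peak so the
        peak's own smeared edge is not mistaken for a preceding peak."""
        i = max(lo, p - w_guard)
        fmin = fseg[i]
        while i > lo:
            nxt = fseg[i - 1]
            if nxt > fmin + vtol:
                break
            fmin = min(fmin, nxt)
            i -= 1
        return i

    # fit a WLC branch for every peak, including the detachment peak:
    # its rising branch carries the final contour state and closes the
    # increment of the last unfolding event
    fit_targets = list(peaks) + ([detach_peak] if detach_peak >= 0 else [])
    branches: list[tuple[int, float, WLCFit]] = []
    prev_peak = 0
    prev_lc: float | None = None
    for p in fit_targets:
        seg_lo = prev_peak + 1 if prev_peak else 0
        valley = branch_start(p, seg_lo)
        rise = np.flatnonzero(fs[valley:p + 1] >= min_branch_force)
        prev_peak = p
        if rise.size == 0:
            log.warning("%s: branch before sample %d never exceeds %g pN; dropped",
                        curve_id, p, min_branch_force)
            continue
        start = valley + int(rise[0])
        sep = curve.separation[start:p + 1]
        force = curve.force[start:p + 1]
        keep = np.diff(sep, prepend=sep[0] - 1.0) > 0
        sep, force = sep[keep], force[keep]
        try:
            fit = fit_wlc_segment(sep, force, Lp=Lp, T=T)
        except (InsufficientDataError, ValueError) as exc:
            log.warning("%s: branch ending at sample %d unfittable (%s); dropped",
                        curve_id, p, exc)
            continue
        if not fit.converged:
            log.warning("%s: WLC fit did not converge for branch at sample %d; dropped",
                        curve_id, p)
            continue
        lc = fit.params.Lc
        if prev_lc is not None and lc <= prev_lc:
            log.warning("%s: non-increasing Lc (%.1f -> %.1f) at sample %d; branch dropped",
                        curve_id, prev_lc, lc, p)
            continue
        branches.append((int(p), float(lc), fit))
        prev_lc = lc

    # the rupture at peak k releases the contour measured by the NEXT
    # branch: dL_k = Lc_{k+1} - Lc_k, paired with the crest force at k.
    # The trailing event of a curve without a fitted detachment branch
    # has an undefined increment.
    events: list[UnfoldingEvent] = []
    for k, (p, lc, fit) in enumerate(branches):
        if p == detach_peak:
            continue
        if k + 1 < len(branches):
            dl = branches[k + 1][1] - lc
        else:
            dl = float("nan")
        events.append(UnfoldingEvent(
            index=len(events), peak_sample=p,
            Fmax=crest(p), Lc=lc, dL=dl, branch_fit=fit,
        ))
    return CurveAnalysis(curve_id, events, detachment_force)


def analyze_curve(
    raw: ForceCurve,
    min_drop: float = 20.0,
    min_peak_force: float = 30.0,
    Lp: float = 0.4,
    T: float = 300.0,
) -> CurveAnalysis:
    """Convenience chain: preprocess -> detect_ruptures -> extract_events."""
    curve = preprocess(raw)
    peaks = detect_ruptures(curve, min_drop=min_drop, min_peak_force=min_peak_force)
    return extract_events(curve, peaks, Lp=Lp, T=T, min_peak_force=min_peak_force)


def filter_curves(
    analyses: list[CurveAnalysis],
    min_peaks: int = 4,
    strong_range: tuple[int, int] = (7, 10),
    strong_detach_force: float = 150.0,
) -> tuple[list[CurveAnalysis], list[CurveAnalysis]]:
    """Quality selection and the strong-attachment subset.

    ``selected``: curves with at least ``min_peaks`` unfolding peaks.
    ``strong``: selected curves with a peak count in ``strong_range``
    and detachment force of at least ``strong_detach_force`` pN.
    Flags are set on the analyses in place; filtering is idempotent.
    """
    selected: list[CurveAnalysis] = []
    strong: list[CurveAnalysis] = []
    lo, hi = strong_range
    for a in analyses:
        a.passes_quality = a.n_peaks >= min_peaks
        a.strong_attachment = (
            a.passes_quality
            and lo <= a.n_peaks <= hi
            and np.isfinite(a.detachment_force)
            and a.detachment_force >= strong_detach_force
        )
        if a.passes_quality:
            selected.append(a)
        if a.strong_attachment:
            strong.append(a)
    return selected, strong


def events_to_table(analyses: list[CurveAnalysis]) -> pd.DataFrame:
    """Flatten analyses into the events TSV schema."""
    rows = []
    for a in analyses:
        for e in a.events:
            rows.append({
                "curve_id": a.curve_id,
                "index": e.index,
                "Fmax_pN": e.Fmax,
                "Lc_nm": e.Lc,
                "dL_nm": e.dL,
                "label": e.label,
                "n_peaks": a.n_peaks,
                "detachment_force_pN": a.detachment_force,
                "strong_attachment": a.strong_attachment,
            })
    return pd.DataFrame(rows, columns=[
        "curve_id", "index", "Fmax_pN", "Lc_nm", "dL_nm", "label",
        "n_peaks", "detachment_force_pN", "strong_attachment",
    ])
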