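"""Population statistics and characteristic-signature detectors.

Gaussian-mixture decomposition of the pooled unfolding-length (ΔL) and
rupture-force (Fmax) measurements, posterior class assignment of events
to the IgC2 / FnIII module families, and detectors for three recurring
spectral signatures of contactin pulling curves:

* a 13-18 nm intermediate ("hump") inside an otherwise full ~30 nm
  FnIII unfolding,
* a long (>= 30 nm) near-constant-force plateau at low force, the
  opening of the horseshoe arrangement of the N-terminal modules,
* an initial 23.1-24.4 nm partial unfolding of the first FnIII module.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
from lmfit import Parameters, minimize as lm_minimize
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .curve import ForceCurve
from .pipeline import CurveAnalysis
from .wlc import InsufficientDataError

__all__ = [
    "MixtureFit",
    "FeatureReport",
    "fit_gaussian_mixture",
    "classify_events",
    "label_analyses",
    "detect_intermediate_hump",
    "detect_long_plateau",
    "detect_partial_fniii",
]


@dataclasses.dataclass
class MixtureFit:
    """Gaussian mixture for one measured population.

    Components are sorted by ascending mean; weights are positive and
    sum to one.  ``gof`` is the Poisson-weighted chi-square of the
    binned fit for the histogram method and the log-likelihood for EM.
    """

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    method: str
    gof: float
    degenerate: bool = False

    def pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return out

    def responsibilities(self, x) -> np.ndarray:
        """Posterior component probabilities, shape (n, k)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = np.stack([
            w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            for w, m, s in zip(self.weights, self.means, self.sds)
        ], axis=1)
        tot = comp.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return comp / tot


@dataclasses.dataclass
class FeatureReport:
    """One detected spectral signature on one curve."""

    curve_id: str
    feature: str  # "hump" | "plateau" | "partial_fniii"
    location: float  # separation, nm
    magnitude: float  # nm (lengths) or pN (plateau force)
    valid_position: bool = True
    extra: dict = dataclasses.field(default_factory=dict)


def _histogram_ls(
    values: np.ndarray, k: int, bin_width: float, rng: np.random.Generator,
    n_restarts: int, hist_range: tuple[float, float],
):
    # Poisson-weighted chi-square histogram fit: residuals are scaled by
    # the counting error sqrt(max(n_i, 1)) of each bin, so sparse shoulder
    # and tail bins carry their proper statistical weight instead of being
    # drowned by the tall central bins
    edges = np.arange(hist_range[0], hist_range[1] + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    norm = values.size * bin_width
    density = counts / norm
    sigma = np.sqrt(np.maximum(counts, 1)) / norm
    centers = 0.5 * (edges[:-1] + edges[1:])

    lo, hi = float(values.min()), float(values.max())
    base_means = np.quantile(values, (np.arange(k) + 0.5) / k)
    spread = max((hi - lo) / (2.0 * k), bin_width)
    inits = [base_means]
    if k > 1:
        km = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31)))
        km.fit(values.reshape(-1, 1))
        inits.append(np.sort(km.cluster_centers_.ravel()))
        gm = GaussianMixture(n_components=k, n_init=2,
                             random_state=int(rng.integers(2**31)))
        gm.fit(values.reshape(-1, 1))
        inits.append(np.sort(gm.means_.ravel()))
    n_inits = max(n_restarts, len(inits) + 2)
    while len(inits) < n_inits:
        inits.append(base_means + rng.normal(0, spread / 2, k))

    best = None
    for means0 in inits:
        params = Parameters()
        for j in range(k):
            params.add(f"m{j}", value=float(np.clip(means0[j], lo, hi)),
                       min=hist_range[0], max=hist_range[1])
            params.add(f"s{j}", value=spread, min=bin_width / 10.0, max=(hi - lo) or 1.0)
            params.add(f"a{j}", value=1.0 / k, min=0.0)

        def resid(p):
            model = np.zeros_like(centers)
            for j in range(k):
                m, s, a = p[f"m{j}"].value, p[f"s{j}"].value, p[f"a{j}"].value
                model += a * np.exp(-0.5 * ((centers - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            return (model - density) / sigma

        res = lm_minimize(resid, params, method="leastsq")
        ssr = float(np.sum(res.residual ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, res.params)

    ssr, p = best
    means = np.array([p[f"m{j}"].value for j in range(k)])
    sds = np.array([p[f"s{j}"].value for j in range(k)])
    amps = np.array([max(p[f"a{j}"].value, 0.0) for j in range(k)])
    if amps.sum() == 0:
        amps = np.ones(k)
    weights = amps / amps.sum()
    return means, sds, weights, ssr


def fit_gaussian_mixture(
    values,
    k: int,
    method: str = "histogram-LS",
    bin_width: float = 1.0,
    hist_range: tuple[float, float] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Decompose a measured population into ``k`` Gaussian components.

    ``histogram-LS`` (default) fits a sum of Gaussians to the binned
    density by Poisson-weighted least squares, mirroring how
    unfolding-length and force histograms are conventionally
    decomposed; ``EM`` runs
    expectation-maximization on the raw values.  Both use ``n_restarts``
    seeded restarts and keep the best goodness of fit.  Components with
    a standard deviation below a quarter of the bin width are flagged
    degenerate.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if k < 1:
        raise ValueError("k must be >= 1")
    if values.size < 10 * k:
        raise InsufficientDataError(
            f"need >= {10 * k} values for a {k}-component fit, got {values.size}"
        )
    rng = np.random.default_rng(seed)
    if method in ("histogram-LS", "histls"):
        if hist_range is None:
            hist_range = (
                max(0.0, float(values.min()) - bin_width),
                float(np.quantile(values, 0.995)) + 2 * bin_width,
            )
        vals = values[(values >= hist_range[0]) & (values <= hist_range[1])]
        means, sds, weights, gof = _histogram_ls(
            vals, k, bin_width, rng, n_restarts, hist_range
        )
    elif method == "EM":
        gm = GaussianMixture(n_components=k, n_init=n_restarts, random_state=seed)
        gm.fit(values.reshape(-1, 1))
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        gof = float(gm.score(values.reshape(-1, 1)) * values.size)
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    degenerate = bool(np.any(sds < bin_width / 4.0))
    return MixtureFit(k, means, sds, weights, method, gof, degenerate)


def classify_events(dl_values, dl_mixture: MixtureFit) -> np.ndarray:
    """Label unfolding lengths by maximum posterior responsibility.

    All components except the largest-mean one are IgC2 (the clamped
    short populations); the largest-mean component is FnIII.  Exact
    posterior ties break toward the larger-mean component, i.e. FnIII.
    Returns an array of labels; non-finite inputs map to "unassigned".
    """
    if dl_mixture is None:
        raise ValueError("a fitted dL mixture is required")
    x = np.atleast_1d(np.asarray(dl_values, dtype=float))
    labels = np.full(x.shape, "unassigned", dtype=object)
    ok = np.isfinite(x)
    if ok.any():
        resp = dl_mixture.responsibilities(x[ok])
        # argmax on reversed columns -> ties resolve toward larger mean
        comp = resp.shape[1] - 1 - np.argmax(resp[:, ::-1], axis=1)
        labels[ok] = np.where(comp == dl_mixture.k - 1, "FnIII", "IgC2")
    return labels


def label_analyses(analyses: list[CurveAnalysis], dl_mixture: MixtureFit) -> None:
    """Assign class labels to every event in place.

    A first event (undefined ΔL) is labeled from its absolute contour
    length only if it is the sole event; otherwise left unassigned.
    """
    for a in analyses:
        dls = np.array([e.dL for e in a.events])
        labels = classify_events(dls, dl_mixture)
        for e, lab in zip(a.events, labels):
            e.label = str(lab)


def detect_intermediate_hump(
    analysis: CurveAnalysis,
    curve: ForceCurve | None = None,
    partial_range: tuple[float, float] = (11.0, 18.0),
    full_mean: float = 30.6,
    full_tol: float = 2.0,
    min_completion: float = 8.0,
    merge: bool = True,
) -> tuple[list[FeatureReport], CurveAnalysis]:
    """Two-stage FnIII unfolding through a 13-18 nm intermediate.

    Flags consecutive event pairs whose first increment falls in
    ``partial_range`` and whose summed increment matches a full FnIII
    unfolding length (``full_mean`` within ``full_tol``).  With
    ``merge=True`` the returned analysis replaces each pair by one
    merged FnIII event carrying the summed increment; the input analysis
    is never modified.  Note the default extraction chain keeps split
    increments: merging by increment arithmetic alone cannot distinguish
    a genuine intermediate from two adjacent short events, so it is
    opt-in for feature reporting.
    """
    reports: list[FeatureReport] = []
    out = copy.deepcopy(analysis)
    events = out.events
    i = 0
    merged: list = []
    while i < len(events):
        e = events[i]
        nxt = events[i + 1] if i + 1 < len(events) else None
        is_pair = (
            nxt is not None
            and np.isfinite(e.dL)
            and np.isfinite(nxt.dL)
            and partial_range[0] <= e.dL <= partial_range[1]
            and nxt.dL >= min_completion
            and abs((e.dL + nxt.dL) - full_mean) <= full_tol + 0.0
        )
        if is_pair:
            loc = float("nan")
            if curve is not None:
                loc = float(curve.separation[e.peak_sample])
            reports.append(FeatureReport(
                analysis.curve_id, "hump", loc, float(e.dL),
                extra={"full_dL": float(e.dL + nxt.dL)},
            ))
            if merge:
                m = copy.copy(nxt)
                m.dL = float(e.dL + nxt.dL)
                m.label = "FnIII"
                merged.append(m)
                i += 2
                continue
        merged.append(e)
        i += 1
    for j, e in enumerate(merged):
        e.index = j
    if merge and len(merged) != len(out.events):
        out.n_visible_peaks = analysis.n_peaks
    out.events = merged
    return reports, out


def detect_long_plateau(
    curve: ForceCurve,
    analysis: CurveAnalysis | None = None,
    min_span: float = 30.0,
    band: float = 10.0,
    level_range: tuple[float, float] = (10.0, 40.0),
    smooth_nm: float = 2.0,
) -> list[FeatureReport]:
    """Long near-constant-force plateaus at low force.

    Reports contiguous regions spanning at least ``min_span`` nm of
    separation where the smoothed force keeps a peak-to-peak excursion
    within ``band`` pN around a level inside ``level_range`` and shows
    no systematic drift beyond ``band``/2 between its edges (a plateau
    is flat; a shallow worm-like-chain rise is not).  When a labeled
    analysis is supplied, ``valid_position`` marks whether the plateau
    ends before the first FnIII-labeled event, the placement expected
    of the horseshoe-opening signal.
    """
    sep = curve.separation
    dx = float(np.median(np.diff(sep)))
    w = max(3, int(round(smooth_nm / dx)))
    fs = ndimage.uniform_filter1d(curve.force, size=w, mode="nearest")

    lo_ok = level_range[0] - band
    hi_ok = level_range[1] + band
    candidate = (fs >= lo_ok) & (fs <= hi_ok)
    reports: list[FeatureReport] = []

    first_fn_sep = np.inf
    if analysis is not None:
        for e in analysis.events:
            if e.label == "FnIII":
                first_fn_sep = float(curve.separation[e.peak_sample])
                break

    n = fs.size
    i = 0
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and candidate[j + 1]:
            j += 1
        # maximal flat sub-windows inside the candidate run (two pointers);
        # the drift test runs on a window trimmed by the smoothing width so
        # entry/exit transients do not mask or fake a slope
        trim = w
        a = i
        best: tuple[int, int] | None = None
        b = i
        while a <= j:
            while b + 1 <= j:
                seg = fs[a:b + 2]
                if seg.max() - seg.min() <= band:
                    b += 1
                else:
                    break
            span = sep[b] - sep[a]
            level = float(np.mean(fs[a:b + 1]))
            ta, tb = a + trim, b - trim
            if tb - ta > 10:
                n_edge = max(1, (tb - ta + 1) // 10)
                net = float(np.mean(fs[tb - n_edge + 1:tb + 1])
                            - np.mean(fs[ta:ta + n_edge]))
            else:
                net = float(fs[b] - fs[a])
            if (
                span >= min_span
                and level_range[0] <= level <= level_range[1]
                and abs(net) <= band / 2
            ):
                if best is None or (sep[b] - sep[a]) > (sep[best[1]] - sep[best[0]]):
                    best = (a, b)
            a += 1
            if b < a:
                b = a
        if best is not None:
            a, b = best
            # trim the approach/exit ramps: keep the core whose force
            # stays near the window median
            med = float(np.median(fs[a:b + 1]))
            for tol in (band / 3.0, band / 10.0):
                while a < b and abs(fs[a] - med) > tol:
                    a += 1
                while b > a and abs(fs[b] - med) > tol:
                    b -= 1
                med = float(np.median(fs[a:b + 1]))
            level = float(np.mean(fs[a:b + 1]))
            if sep[b] - sep[a] >= min_span:
                reports.append(FeatureReport(
                    curve.source_id, "plateau",
                    float(sep[a]), level,
                    valid_position=bool(sep[b] <= first_fn_sep),
                    extra={"span_nm": float(sep[b] - sep[a]), "end_nm": float(sep[b])},
                ))
        i = j + 1
    return reports


def detect_partial_fniii(
    analysis: CurveAnalysis,
    dl_range: tuple[float, float] = (23.1, 24.4),
    dl_tol: float = 0.5,
    max_following_fniii: int = 3,
) -> list[FeatureReport]:
    """Initial partial unfolding of the first FnIII module.

    Flags events whose increment falls in ``dl_range`` (widened by the
    measurement tolerance ``dl_tol``), that occur after every
    IgC2-labeled event of the curve, and that are followed by at most
    ``max_following_fniii`` FnIII-labeled events.  Requires labeled
    events (see :func:`label_analyses`).
    """
    reports: list[FeatureReport] = []
    events = analysis.events
    lo, hi = dl_range[0] - dl_tol, dl_range[1] + dl_tol
    for i, e in enumerate(events):
        if not np.isfinite(e.dL) or not (lo <= e.dL <= hi):
            continue
        if any(ev.label == "IgC2" for ev in events[i + 1:]):
            continue
        n_fn_after = sum(1 for ev in events[i + 1:] if ev.label == "FnIII")
        if n_fn_after > max_following_fniii:
            continue
        reports.append(FeatureReport(
            analysis.curve_id, "partial_fniii", float("nan"), float(e.dL),
            extra={"n_fniii_following": n_fn_after, "event_index": e.index},
        ))
    return reports
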