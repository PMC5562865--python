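# Methods

## Chain mechanics and the pulling model

A retraction is simulated quasi-statically: at each piezo position `z`
the tip–sample separation `x` solves the force balance
`k_c (z − x) = F_wlc(x; L_c)` between the Hookean cantilever
(`k_c = 0.02 N/m = 20 pN/nm`) and the Marko–Siggia worm-like chain of
the currently released contour `L_c`. The balance residual is solved to
better than 10⁻³ pN by bisection, warm-started from the previous
sample. Defaults follow the experimental acquisition they emulate:
pulling speed 0.5 µm/s, nominal loading rate `k_c·v = 10⁴ pN/s`.
Sampling density (10 samples per nm of piezo travel) and Gaussian force
noise (σ = 5 pN) are package choices — realistic for a soft cantilever
at this speed — as no acquisition noise figure is prescribed by the
populations being emulated.

Temperature enters only through `k_B T` (4.142 pN·nm at the default
300 K), computed from the CODATA Boltzmann constant.

## Event model

Each module contributes one scripted unfolding event:

* **ΔL draws.** FnIII: Gaussian 30.6 ± 3.7 nm. IgC2: a two-component
  Gaussian mixture (9.5 ± 3.3 and 17.4 ± 3.3 nm); each IgC2 module is
  tied to the component nearest its architecture-predicted length, so
  the two length populations map onto short- and long-loop modules.
  Draws are truncated at ±3 σ, at a 2 nm floor, and at the module's
  extensible contour (`(n_res − n_protected)·l_aa` for IgC2,
  `n_res·l_aa` for FnIII).
* **Rupture-force draws.** Per-class two-component mixtures:
  IgC2 61.0 ± 12.9 / 95.0 ± 26.4 pN, FnIII 79.4 ± 21.5 / 145.0 ± 48.6
  pN, equal weights (component weights are not constrained by the
  published decompositions). Draws are truncated at ±3 σ and floored at
  35 pN, just above the 30 pN detection threshold.
* **Attachment.** By default the substrate holds one (random) terminus
  and the tip grabs a uniform random position along the contour, so a
  random terminal-anchored span of modules bears load. This reproduces
  the experimental scale of ~5–6 resolvable events per accepted curve;
  full-length attachment (`random_pickup=False`) gives exactly one
  event per module and underlies the strong-attachment subset.
* **Secondary features.** With probability 0.15 an FnIII event unfolds
  in two stages through a 13–18 nm intermediate whose threshold is
  drawn below the event's main rupture force. With probability 0.1 the
  first FnIII module unfolds partially (23.1–24.4 nm); its threshold is
  pinned just above the strongest engaged IgC2 so the observed
  placement — after the IgC2 phase, with at most three full FnIII peaks
  in the spectrum — emerges under the force ramp. With probability 0.1
  (and only when the first four IgC2 modules all bear load) a ~20 pN
  constant-force plateau spanning 35–45 nm of separation renders the
  opening of the horseshoe arrangement; on exit the released contour is
  recovered from the plateau force and exit separation. Nonspecific
  tip–surface adhesion adds a force bump below ~6 nm separation with
  probability 0.1.
* **Rupture scheduling.** In the default phenomenological mode the
  pending unit with the lowest threshold ruptures first — the only
  order consistent with a quasi-static ramp — so curves are mostly
  sequential (weak IgC2 early) with class interleaving arising from the
  overlapping force mixtures; a hump's completion stage is committed
  immediately after its intermediate. The Bell–Evans kinetic mode
  (`k(F) = k₀·exp(F·Δx/k_BT)`, defaults k₀ = 10⁻⁴ s⁻¹, Δx = 0.4 nm)
  replaces thresholds with per-step survival draws and yields rupture
  forces in the 50–150 pN decade at the nominal loading rate, rising
  with pulling speed.

Every curve carries its script as ground truth, including per-event
rupture positions and the realized rupture forces.

## Inference chain

1. **Baseline**: median force of the final contact-free 10 % of samples
   subtracted; optional moving-median smoothing (off by default).
2. **Rupture detection**: local maxima of a 0.5 nm-smoothed trace with
   ≥ 30 pN peak force, ≥ 20 pN prominence-backed fall within 2 nm of
   separation, and separation ≥ 8 nm (closer peaks are treated as
   surface adhesion). Peak indices are refined on the raw trace.
3. **Branch segmentation**: each peak's rising branch is walked back on
   a 1 nm-smoothed trace until the force climbs 8 pN above the running
   minimum — i.e. until a preceding peak or an undetected sub-threshold
   rupture is crossed — so every fitted branch belongs to a single
   contour state.
4. **WLC fits**: fixed `L_p = 0.4 nm` (free-`L_p` mode available),
   bounded scalar least squares for `L_c`; non-convergence is flagged
   and the branch dropped with a logged warning.
5. **Increments**: the rupture at peak *i* releases the contour
   measured by the next branch, `ΔL_i = L_c,i+1 − L_c,i`, pairing each
   peak's crest force with the length it released. The detachment
   peak's branch closes the final increment; a curve without one leaves
   its trailing increment undefined. Crest force is the largest
   3-sample mean near the peak (measured bias +1.3 ± 2.5 pN against
   ground truth at σ = 5 pN noise).
6. **Quality filters**: curves with ≥ 4 visible maxima are selected;
   the strong-attachment subset additionally has 7–10 peaks and a
   detachment force ≥ 150 pN.
7. **Hump merging**: consecutive increment pairs with a first stage in
   11–18 nm summing to a full FnIII length within 2 nm are merged into
   one FnIII event (visible-peak counts are preserved for the
   filters). This mirrors how a two-stage unfolding is reported as one
   FnIII event with an intermediate; `--keep-hump-stages` opts out.

## Population statistics

Histograms (1 nm bins for ΔL, 10 pN for force) are decomposed by
Poisson-weighted chi-square fits of Gaussian sums (lmfit), with
multi-start initialization (quantiles, k-means, EM, jittered restarts)
and the best chi-square kept; an EM alternative (scikit-learn) is
provided. The weighting matters: unweighted least squares lets the
tall central bins dominate and collapses the overlapping IgC2 pair;
calibration on draws from known mixtures shows the weighted fit
roughly halves both bias and scatter of the recovered component means.
The ΔL fit window is bounded above by the architecture's largest
single-module contour gain (≈ 37 nm): larger increments are
necessarily multi-event sums left by sub-threshold ruptures. Events
are classified by maximum posterior responsibility under the
3-component ΔL mixture (components 1–2 → IgC2, 3 → FnIII; ties break
toward FnIII); per-class force histograms are then decomposed with
k = 2.

The plateau detector scans a 2 nm-smoothed trace for runs ≥ 30 nm whose
peak-to-peak excursion stays within 10 pN around a level in 10–40 pN
and whose edge-trimmed drift is below 5 pN (a plateau is flat; a
shallow WLC rise is not), then trims the reported window to its flat
core. The partial-unfolding detector flags increments of 23.1–24.4 nm
(± 0.5 nm measurement tolerance) occurring after every IgC2-labeled
event with at most three FnIII-labeled events following.

## Domain architecture

The packaged CNTN4 table (six IgC2 with one disulfide clamp each, then
four FnIII) stores per-module residue counts, clamped residue counts,
linker lengths and a folded N–C span `d_fold = 4.5 nm`. Predicted
unfolding length is `(extensible residues)·l_aa − d_fold` with
`l_aa = 0.38 nm/aa` by default (0.36–0.40 supported). The residue
partitions are synthetic placeholders chosen to satisfy the published
constraints (module sizes, ectodomain length, per-class stretched-length
ranges 10–18 nm and 29–33 nm); they are not a sequence-annotation
transcription, and the data file says so.

## Elastic-network stiffness

A Cα anisotropic network model with uniform springs (γ = 1) inside a
15 Å cutoff — the conventional Cα-ANM choice; the published per-domain
summary states bin thresholds but no cutoff. The effective spring
constant between residues i and j is the inverse compliance
`1/Σ_k λ_k⁻¹ [(u_k[j] − u_k[i])·r̂_ij]²` over non-zero modes (zero-mode
tolerance 10⁻⁸ of the largest eigenvalue, which also drops degenerate
bending modes of pathological geometries). Per-residue constants are
means over all partners — the averaging convention, like γ, sets the
scale of the soft/moderate/stiff bin thresholds (defaults 12 and 15),
which is why outputs carry a units note. Disulfide-protected IgC2
residues are excluded from their domain's bins; a fully masked domain
reports NaN fractions with a validity flag rather than silent zeros.
Correctness is pinned to an independent oracle (full-Hessian
Moore–Penrose pseudo-inverse) to 10⁻⁶ relative, plus rigid-motion
invariance and contact-densification monotonicity properties.

## What the synthetic data does and does not show

The generator reproduces the measured population structure (class
ΔL/force mixtures, per-curve event counts, quality-filter yields) and
the three secondary signatures, with full ground truth. It does not
model tip chemistry, surface-adsorbed conformations, instrument drift,
non-Markovian refolding, or genuine unfolding kinetics beyond the
optional Bell–Evans mode — so passing round trips validate the
inference chain against the stated event model, not against every
failure mode of real instrument data. Sub-threshold ruptures (force
drops < 20 pN) are a real feature of the emulation: they thin the
short-ΔL population and occasionally fuse increments, which is why the
recovered smallest component sits ~0.5 nm below its generating mean and
why the ΔL fit window is bounded.

## Problem sizes

The main recovery run uses 600 curves (≈ 2,600–2,900 accepted
increments, matching the scale of the emulated campaign), the plateau
run 100 curves, the strong-attachment subset 21 of ~190 strong curves
from a 500-curve run; the full test suite and the acceptance script
each run in well under a minute on one CPU.
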