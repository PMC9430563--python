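# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `agardrift`. It states how things are
computed; all quantitative claims about accuracy are made (and re-made on
every run) by the test suite and `scripts/acceptance.py`, not here.

## Coordinate and axis conventions

The in-memory layout is always `(T, C, Z, Y, X)`, 0-based. Z index 0 is the
slice nearest the objective; for an inverted microscope imaging through the
agar that is the bottom of the dish, so the agar surface and the colony on
it sit at increasing Z and *descend toward Z = 0* as the medium evaporates
and is consumed. A slice index is a sample plane at depth `z·Δz` μm; a
pixel index is a sample at `x·Δxy` μm. Files written in other axis orders
are permuted to the canonical order on read; files with no axis metadata
and more than one anonymous non-spatial dimension are refused rather than
guessed at. Uncalibrated files are readable (unit defaults of 1 μm / 1 min
with an `uncalibrated` flag), but every conversion to real-world units
refuses to run on them.

## Surface-drift model

Surface position is affine in time: `slice(t) = z₀ + D·(t − t₀)`, with the
displacement value D in slices/timepoint. This linearity is an empirical
property of closed-dish evaporation plus consumption over multi-day runs;
the model deliberately has no curvature term (nonlinear drift is out of
scope — if drift is visibly nonlinear the right fix is splitting the series
and fitting segments).

**Automatic estimation** takes, per reference timepoint, the argmax over Z
of the mean plane intensity of one channel. The mean is accumulated in
double precision (8-bit planes would overflow integer accumulation), and
argmax ties break toward lower Z, the side from which the surface is first
encountered. Flat (all-equal) profiles carry no focus information; such
timepoints are dropped with a warning, and fewer than two usable timepoints
is an error that points the user at manual mode, the right tool when
fluorescence is weak or only transmitted light is usable. A variance- or
gradient-based focus metric would be a reasonable alternative operator; the
intensity argmax is used because it is the rule this workflow defines, and
the alternative is explicitly out of scope.

**Fitting**: two points give the exact two-point slope; more are combined
by ordinary least squares, which reduces to the two-point formula and needs
no tuning. The model records an RMS residual when over-determined.
Negative D is legal (upright systems, swelling media).

**Rates**: `D·Δz/(Δt/60)` converts to μm/h of signed axial velocity along
+Z. The *descent* rate reported to users is its negation, positive when the
surface approaches the objective. Published descriptions of this kind of
experiment quote surface descent figures that differ between sections of
the same report (≈2.5 μm/h in one place, ≈250 μm/24 h ≈ 10.4 μm/h in
another); the tool therefore treats the rate strictly as data to be
estimated per experiment, never as a constant.

## Floating-window crop

`start(t) = clamp(round(surface(t) + offset), 0, Z − W)` with rounding half
away from zero, computed per-timepoint on the real-valued prediction — never
by accumulating rounded steps, which would drift systematically over
hundreds of timepoints. The default offset of −W/4 places the predicted
surface a quarter-window above the output floor, because colonies grow away
from the agar: most of the window should cover the space above the surface.
`offset=0` starts the window exactly at the surface instead; both anchorings
are therefore available. Windows that would leave the acquired volume are
clamped to the edge and the affected timepoints recorded, rather than
failing — long experiments can legitimately outrun the acquired volume.

Execution is chunked: each timepoint is staged as a temporary single-
timepoint TIFF, then the output OME-TIFF is assembled by streaming planes,
so peak memory is bounded by one timepoint regardless of T. A JSON manifest
written after each staged timepoint makes an interrupted run resumable; a
manifest whose plan no longer matches is discarded. Retained pixels are
copied bit-exactly, and calibration plus channel colors travel with them.

## Acquisition planner

Pure arithmetic, kept separate from image processing: total drift
`rate × duration`; slices `⌈thickness/Δz⌉`; timepoints
`⌊duration·60/interval⌋` (counting acquisition intervals, not
fence-posts); images `T × Z × C`; duration per timepoint
`n_slices × sec_per_slice`; bytes `bytes_per_timepoint × T` with decimal Gb
(10⁹ bytes). Per-timepoint size is always a user input measured from a
pilot acquisition — container overhead means it is not derivable from pixel
dimensions, and attempting to derive it produces confidently wrong plans. A
warning fires when one timepoint takes longer than the interval, since in
multiposition runs every stack must complete within it. Slice and timepoint
counts can be given explicitly (acquisition software sometimes reports
counts that differ from the raw arithmetic); explicit values take
precedence over derived ones.

## Front analytics

The leading edge is measured on a Z-projection (max by default; the
projection is a recorded parameter) binarised by Otsu's threshold or a
fixed value, with connected components under `min_component_px` pixels
(8-connectivity, default 5) discarded as noise. The front is the extremal
surviving foreground coordinate along the axis of advance, in μm. This
operator is an explicit, reproducible stand-in for what is traditionally a
manual measurement; determinism is the point.

Rates are per-gap differences divided by the interval in hours, smoothed by
a **trailing** (causal) 4-value moving average advancing one timepoint at a
time; the head of the series uses the shorter available window. A centered
window would phase-shift less but is not what "advancing one timepoint at a
time" describes; the trailing form is used and the alternative noted here.
Undetected positions are NaN and propagate: rates touching a gap are NaN,
never interpolated. Negative rates are meaningful (retreat). Regions of the
same colony are combined pointwise as mean ± sample SD (n−1); a single
region reports no SD. Colony separation is the minimum Euclidean distance
between foreground pixels of the two masks (kd-tree; verified against the
exhaustive pairwise scan in tests), zero at contact.

## Spot heights

Foci are 3-D local maxima (26-connectivity) at or above `min_intensity`,
thinned so no two survivors are closer than `min_separation` μm using the
real voxel anisotropy — with 1–3 μm Z-steps versus sub-μm XY pixels,
voxel-space distances would be badly wrong. Among conflicting candidates
the brighter wins; exact ties go to the lexicographically lower (z, y, x).
The detector's parameters are deliberately few and explicit, since the
commercial tools usually used for this step do not document theirs.

Height is `(z_spot − surface_slice(t))·Δz`, referenced to the drift-model
prediction rather than per-timepoint surface re-detection: after cropping,
colony fluorescence often swamps the surface signal, while the fitted line
stays valid. Negative heights (below the fitted surface) are reported and
counted, not clipped. Aggregation is mean ± sample SD per (timepoint,
channel) with spot counts.

## Synthetic scenes and what they do (not) show

The generator draws: a flat surface slab (default 4 μm thick, brightness
120 over background 10) at `z_um(t) = z₀ − rate·hours`, split across
adjacent slices by fractional overlap with each slice's ±Δz/2 integration
window so sub-slice positions render correctly; colony discs of radius
`r₀ + v·hours` attached to the surface, either solid pancakes or discrete
Gaussian foci (σ ≈ 0.8 px lateral, 0.6 slices axial) at
N(mean_height, sd) heights; additive Gaussian noise clipped to the pixel
range. Default conditions mirror the imaging regime the pipeline targets:
2 μm Z-step, 30-minute frames, 2.5 μm/h descent, front speeds of a few to
tens of μm/h, subpopulations at ~6 μm and ~1 μm above the surface, 8-bit
pixels. One seed determines the stack bit-for-bit, and the exported ground
truth records exactly what was drawn (only foci actually inside the imaged
field are listed).

Not modelled, and therefore not demonstrated by passing tests: optical PSF
and depth-dependent attenuation, Poisson photon statistics, photobleaching,
XY stage drift, real colony morphology (wrinkles, lobed edges), or
autofluorescent debris. The recovery results say the algorithms are
correct under their stated assumptions — linear drift, surface brighter
than background, colony fronts that are intensity steps — not that those
assumptions hold for any particular microscope.

## Problem sizes

Test and acceptance scenes are sized for fast, repeatable runs while still
exercising the relevant regimes: the canonical drift scene uses 145
timepoints (72 h at 30-minute intervals, ~0.63 slices/timepoint of
sub-slice drift) at 16×16 px; noisy-recovery sweeps use 20 seeds of 25
timepoints; the crop oracle uses 50 randomized stacks up to (6, 2, 30, 8,
8); front and spot scenes use 64–128 px fields over 4–6 h. The estimators
operate per-plane/per-timepoint, so accuracy is set by timepoint count and
geometry, not field size.

## Known limitations

* Strictly linear drift; no piecewise or robust fitting.
* The automatic estimator assumes the brightest Z is the surface; a colony
  much brighter than the agar interface can capture the argmax (use manual
  anchors or a transmitted-light channel then).
* Front detection assumes one dominant colony component per field after
  the size filter; merging colonies are not separated.
* OME-TIFF (plus ImageJ-style TIFF on read) is the only container;
  proprietary vendor formats should be converted upstream.
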