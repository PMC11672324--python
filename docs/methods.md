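# Methods

`woundsight` quantifies plasma-membrane wound repair from two-channel
time-lapse movies: a membrane-impermeable wound dye (channel 0) reports
whether the wound is open, and a fluorescent event marker (channel 1) shows
exocytic/endocytic punctae.  Because the study it mirrors deposits no raw
data, the package ships a synthetic-movie generator with known ground truth,
and every analysis stage is validated against what the generator planted.

## The synthetic data model

### Event point process

Punctae are born as an inhomogeneous spatio-temporal Poisson process over a
filled-ellipse cell footprint:

* **Steady background** — homogeneous rate ρ (default 2 × 10⁻³ events
  µm⁻² s⁻¹) throughout the movie.  With the default 4 s mean lifetime this
  sustains a visible punctae density of ~8 × 10⁻³ µm⁻², a typical
  steady-state endocytic-marker density.
* **Exocytic burst** — during the (0, 10] s window after wounding, ring k's
  birth rate is multiplied by `exo_boost_by_ring[k−1]` (default 5 in ring 1,
  1 elsewhere), reproducing the wound-proximal burst of early-endosome
  fusion events.
* **Endocytic burst** — after the resealing phase (default 30 s), events
  appear at `endo_boost` × ρ over the cell (default 5×).  With probability
  `assoc_prob` (default 0.9) an event is planted at a uniformly chosen
  earlier exocytic site plus isotropic Gaussian jitter of `assoc_sd`
  (default 1 µm); otherwise uniformly over the cell.  This directly encodes
  the "endocytosis at previous exocytic sites" structure the
  nearest-neighbor statistic is designed to detect.

Each puncta lives for an Exp(4 s) lifetime and is rendered as a Gaussian
spot (σ = 0.3 µm, amplitude 200 counts).  The nominal SNR is
amplitude / read-noise (default 200/20 = 10).

The Poisson process was chosen as the simplest generative model consistent
with independently appearing punctae; boosts are parameterized as *total*
rate multipliers (a ring at boost 5 carries 5× the background rate during
the window).

### Dye channel

Channel 0 draws the cell outline bright (surface labeling) with a dim
interior, then adds influx after wounding: saturating `I₀(1 − e^(−t/τ))`
(τ defaults to reseal_time/3) when the wound reseals, linear `c·t` when it
fails, plus a Gaussian accumulation at the wound site (the delineation).
Photobleaching is multiplicative `e^(−0.005 t)` and is applied to the
structural signal and the event channel but not to the influx term —
freshly entering dye has not been illuminated.  Gaussian read noise
(optional Poisson shot noise) is added last.

### Acquisition defaults

512×512 frames, 2 pre-wound frames plus 100 post-wound frames at 1 s
intervals (the frame interval is configurable; 1 s is a representative
confocal time-lapse rate), a 2.5 µm² circular wound, 30 s resealing phase.
The default pixel size is 0.25 µm: the assay's stated geometry (a 2.5 µm²
wound spanning 20 px) implies 0.089 µm/px, but at that sampling a 512-px
field is only 46 µm wide and cannot contain the six-ring partition with
20 µm diameter increments (outer radius ≈ 61 µm); 0.25 µm/px gives a 128 µm
field that hosts all six rings.

### What the generator does not emulate

pH-sensitive reporter photophysics, 3-D structure, cell migration or
retraction, spatially varying background, and separate spectral channels for
exo- and endo-markers (all planted events render into one event channel).
Passing tests therefore demonstrate that the *computations* recover planted
structure under realistic noise — not that the detector would match an
interactively trained pixel classifier on real movies.

## Detection

The interactive pixel-classification step of the original workflow is
replaced by a deterministic chain: difference-of-Gaussians band-pass at the
spot scale (narrow σ = 0.3 µm, wide 2×), a threshold placed at the q-quantile
of the estimated background noise (`median + z_q·1.4826·MAD` of the
band-passed frame, default q = 0.99999), connected components, and an area
filter (defaults 0.1–10 µm², matched to the synthetic PSF since the original
size bounds are not stated).  Thresholding against a robust noise estimate
rather than an intensity quantile keeps the operating point calibrated
regardless of how much of the frame the punctae cover.  Filtering uses
periodic boundary handling, which makes detection exactly equivariant to
integer pixel shifts.  A `STRICT_PRESET` (q = 0.9999995) mirrors the
stricter thresholding used for nearest-neighbor mapping, where false
punctae are costlier than missed ones.  Externally produced probability
maps enter through `binarize_probability_maps` under the identical
labeling/filter contract.

At SNR 5 the default detector achieves precision ≈ 0.99 and recall ≈ 0.98
against planted ground truth (greedy one-to-one matching within 1 µm).

## Ring quantification

Rings are disjoint half-open annuli `(r_{k−1}, r_k]` growing from the wound
radius √(wound_area/π) in `increment/2` radial steps (20 µm diameter
increments, 6 rings by default).  The wound disk itself is excluded — the
ablation destroys signal there.  A cumulative nested-disk mode and a
cell-mask-intersected area mode are available, but the defaults follow the
per-region reading with full annulus areas.  The count matrix divides each
ring's per-frame count by its count at the last pre-wound frame (zero
baselines clamp to 1, at the cost of underestimating fold changes in those
cells) and by the ring area in µm².  `steady_state_matrix` drops the
baseline division for non-wounded controls.

## Resealing kinetics

The influx curve is mean wound-dye intensity over the wounded cell minus a
nearby unwounded cell (background and bleaching correction), normalized to
the last pre-wound frame.  The subtraction direction is wounded −
unwounded: the literal protocol sentence reads inverted, but influx must
increase the curve.  The plateau-vs-linear call — made by eye in the
original — is codified as a slope-ratio rule: least-squares slopes over the
first and last thirds of the post-wound record; ratio < 0.2 → resealed,
ratio ≥ 0.2 with positive late slope → failed, flat or negative early slope
→ indeterminate.  All three knobs (windows, threshold) are parameters.  On
generator output at default noise the rule classifies 40/40 movies
correctly, and the verdict is invariant to intensity scaling and offsets.

The hydrogel metrics are the around-wound curve (mean dye intensity in a
20 µm diameter wound-centered disk, normalized to whole-cell pre-wound
intensity) and the delineation area fraction; the scrape-assay repair
percentage is `100·(wounded − unrepaired)/wounded` from flow counts.

## Spatial statistics

Object-based colocalization counts an `a`-puncta as colocalized when its
mask shares ≥ 1 pixel with any `b`-mask (or, under the centroid rule, when
the nearest `b`-centroid lies within a tolerance); the colocalized counts
then pass through the same baseline-and-area normalization as plain counts.

The nearest-neighbor series pools exocytic punctae from circle 1 during
(0, 10] s post-wound as a fixed reference (with 1 s frames and 2 pre-wound
frames this is frames 3–10 of the recording), then maps every later puncta
to its nearest reference site with a k-d tree.  The per-frame summary is
the arithmetic mean (median available); frames without punctae propagate
NaN — a zero would fake perfect association.  Series are normalized to the
first post-wound frame.  The circle-6 control calibrates chance proximity.
On coupled synthetic movies the circle-1 series dips after resealing in
20/20 seeds while the control stays flat; with the coupling removed the dip
disappears (3/20).  Because the generator renders all events into one
channel, the pre-resealing baseline for this comparison is taken from the
(10, 30] s window, after the exocytic burst has decayed — otherwise the
reference punctae themselves deflate it.

## Hole energetics and tether forces

The enthalpy of a circular membrane hole of radius R is
`H(R) = 2E + 2πRλ − πR²σ` (λ line tension, σ membrane tension, E an
arbitrary additive baseline).  H is concave (d²H/dR² = −2πσ < 0), so the
stationary point `R_c = λ/σ` is an energy *barrier*: holes below R_c reseal,
above it they grow, decided by the sign of dH/dR.  The barrier height is
πλ²/σ.  At λ = 1 pN and σ = 1e−5 N/m, R_c = 100 nm; one order of magnitude
less tension gives 1 µm — the quantitative sense in which locally lowered
tension rescues micron-scale wounds.  The package exposes the critical
*length* λ/σ and leaves the radius-versus-diameter reading to the caller.
Fates are cross-checked in the tests against an explicit-Euler gradient
flow on H.

Tether traces (1000 s⁻¹ sampling) yield (peak, plateau): the peak is the
global maximum after contact; the plateau window starts where the smoothed
post-peak force first comes within `level_snr` (default 1) baseline-noise
units of the trace's terminal level, plus a 10-sample guard, and runs to the
trace end.  With baseline subtraction enabled (default) the outputs are
invariant to constant force offsets.  On synthetic traces with a ≥ 500-sample
plateau at σ = 1 pN the recovered plateau stays within 3σ/√n of truth.

## Numerical and scale choices

* All geometry is physical (µm); pixels appear only at rendering and
  raster I/O.  SI units internally for the energetics; pN/nm/µm at the
  interface.
* Boundary points belong to the inner annulus (half-open rings); k-d tree
  ties resolve deterministically.
* Test and validation runs use reduced fields (96–160 px), shorter movies
  (12–50 frames) and proportionally scaled ring increments (3–5.5 µm),
  with per-ring event counts kept at the levels the full-scale geometry
  would produce (e.g. steady rate 4 × 10⁻³ µm⁻² s⁻¹ in the association
  experiment); biological calibrations — burst factor 5, association 0.9
  with 1 µm jitter, SNR 5, 30 s resealing — are never scaled.
* Degenerate inputs refuse loudly: empty movies, non-positive normalization
  references, empty nearest-neighbor references, zero wounded cells,
  plateau traces with no peak above noise.

## Known limitations

Detection does not fit sub-pixel Gaussians and does not track punctae across
frames (events are counted, not linked); overlapping punctae closer than
about two spot widths merge into one object.  The resealing classifier
assumes monotone influx shapes; oscillatory artifacts return
"indeterminate".  Ring areas default to full annuli, which underestimates
densities in rings that extend past the cell boundary — use the
mask-intersection mode when the outer rings matter quantitatively.  The
hole-energetics model ignores bending energy and pressure coupling, and the
tether analysis reports forces, not absolute tensions (that conversion
needs the bending rigidity).
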