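# Methods

This note records the models, estimators and numerical choices behind
`afmwlc`, what the synthetic data generator does and does not emulate, and
the known biases of the pipeline.

## 1. Chain generation

**Open chains.** A 2D worm-like chain of contour length `L_c` is built as
an equilateral polyline with segment length `a` (default 2 nm, well below
the 8 nm analysis step so resampling error is negligible) whose turning
angles are i.i.d. `N(0, a/Lp)` and whose initial heading is uniform.  This
is the exact discrete-time analogue of the continuous 2D WLC: heading
differences over arc length `L` are `N(0, L/Lp)`, so
`⟨cos θ(L)⟩ = exp(−L/(2·Lp))` and `var θ(L) = L/Lp`.  These two laws are
the generator's oracle role — downstream estimators are tested against
them.

**Closed chains.** Closed rings are sampled from the same bending energy
`E = Lp/(2a) · Σ θ_i²` restricted to exactly closed configurations, using
crankshaft-reflection Metropolis moves: a random sub-arc is reflected
across the chord joining its endpoints.  The reflection is an ambient
isometry, so all segment lengths and the closure are preserved exactly; in
heading coordinates the move is an affine involution with unit Jacobian
and leaves the closure constraint invariant, so detailed balance holds for
the constrained Boltzmann measure.  Only the two turning angles at the arc
junctions change the energy (interior angles are negated, leaving θ²
invariant), giving O(1) energy updates.  Chains start from the regular
polygon and run 800 sweeps per vertex by default; small-separation
statistics equilibrate within ~200 sweeps and the persistence-length fit
is insensitive to further sweeps.  Final configurations that self-intersect
or wind more than once are rejected and resampled (the imaging experiment
can only analyze non-overlapping rings anyway); kept rings are oriented
counter-clockwise, so their turning angles sum to exactly +2π.

The sampler was validated against an independent brute-force oracle at
n = 16 segments: open chains with angle sums bridged to 2π, accepted when
the ends meet within a small tolerance.  On the matched (simple, winding
+1) sector the two ensembles agree in turning-angle variance to a few
percent and in short-range tangent correlations to ~0.01; the residual
difference is bounded by the oracle's closure tolerance.  This test runs
in the suite.

An earlier design — distributing the position end-gap of an angle-bridged
open chain uniformly over the vertices — was measured and discarded: at
the study condition (856 nm contour, Lp 56 nm) the median end-gap is
~280 nm, so the correction would displace vertices by two orders of
magnitude more than a segment length and destroy the local angle
statistics.

## 2. Rendering

A chain becomes a height map by taking, at every pixel center, the maximum
over the polyline of a Gaussian ridge profile
`h(d) = H · exp(−d²/(2σ_r²))` (distance `d` computed via a KD-tree over a
densely resampled polyline, quantization ≤ 0.06 px), convolving with an
isotropic Gaussian of width `σ_t` (tip point-spread), optionally adding
free-protein background dots, and adding i.i.d. Gaussian pixel noise.  For
a long straight ridge the transverse profile after blur is the analytic
two-Gaussian convolution with peak `H·σ_r/√(σ_r²+σ_t²)`; the renderer
reproduces it to <1% and the test suite asserts it.

Defaults (all configurable): pixel 2 nm on 512×512 images; ridge height
0.6 nm (bare DNA) to 1.0 nm (protein-coated filament) with hard bounds
0.3–3.0 nm; ridge width σ_r = 2.5 nm and tip blur σ_t = 1.5 nm, giving an
apparent molecule FWHM of ≈ 6.9 nm — typical of duplex DNA imaged with a
sharp tip, and narrow enough that a phantom 2D chain at Lp 56 nm usually
renders without its close approaches merging (with a ~10 nm apparent
width most molecules would be discarded as overlapping); noise s.d.
0.05 nm.  Background protein dots are 1 nm high, σ = 2 nm.  Compacted
particles are rendered as filled rounded rectangles, 45 × 17 nm at 1.5 nm
height, used only to exercise the compact-class filter.

The plectoneme generator draws a gently curved superhelical axis of
prescribed length (a sinusoidal heading modulation of ±0.25 rad) and
renders it at doubled ridge height — two interwound strands unresolved at
this resolution — with optional short branches whose lengths count toward
the recorded true axis length.

What the renderer does **not** emulate: scanner drift, line flattening
artifacts, tip asymmetry or double-tip imaging, sample deformation, and
excluded-volume interactions between molecules (each image carries one
molecule).  Passing tests therefore demonstrate estimator correctness on
idealized but physically scaled images, not robustness to instrument
artifacts.

## 3. Segmentation and tracing

Pixels above half the robust ridge height (90th percentile of pixels
clearly above background; Otsu fallback for degenerate images) are
labelled by 8-connectivity.  Components touching the border or with less
than 50 nm of skeletal length are discarded.  Classification: crest height
(95th percentile over the mask — the particle's measured height) above
1.2 nm ⇒ compact; a pruned skeleton with 0 endpoints and no branch
points ⇒ circular; 2 endpoints ⇒ linear; anything else ⇒ reject
(overlapping or branched molecules are excluded from analysis, as is
standard practice).

Tracing orders the skeleton pixel graph (redundant diagonal edges of
right-angle triangles removed; side branches ≤ 3 px pruned) between its
two endpoints, or around the ring starting from the smallest (row, col)
pixel and proceeding counter-clockwise (positive shoelace area).  Each
point is then refined to the transverse brightness maximum: the height
profile is sampled by bilinear interpolation along the local normal
(±6 nm, 7 samples), a quadratic is fitted and the point moves to the
parabola apex; two passes with a halved window.  The refined path is
smoothed with a 3-point moving average.

Open ends lose length to skeleton erosion inside the Gaussian end cap.
Each end is therefore extended along its outward tangent to the measured
half-crest crossing minus the analytic cap overshoot `σ_eff·√(2 ln 2)`,
with `σ_eff` estimated from transverse log-quadratic fits at interior
points.  A noiseless straight 328 nm rod traces to within 0.3%; wiggly
ensembles at Lp 56 nm trace ~2% short (chord shortening at the 8 nm step
plus residual end effects), inside the 3% recovery tolerance asserted by
the tests.

Finally the centerline is resampled by linear interpolation at a uniform
8 nm arc step ("half the cross-sectional diameter"); the final segment of
an open trace may be shorter.  Coordinates: pixel (r, c) sits at
physical ((c+0.5)·pixel, (r+0.5)·pixel) nm; all outputs are in nm.

## 4. Worm-like-chain statistics

**Correlation.** Tangents are the unit vectors of consecutive resampled
segments.  For each separation `L = k·step` the cosine of the angle
between tangents at (s, s+L) is averaged over all valid pairs pooled
across molecules (pairs weighted equally); circular traces contribute
wrap-around pairs.  Standard errors are leave-one-molecule-out jackknife.
`⟨cos θ(0)⟩` is identically 1.

**Chord averaging.** A segment tangent is the chord direction over one
8 nm step, i.e. approximately the window-averaged heading; for a WLC this
makes the measured correlation `exp(−(L − h/3)/(2·Lp))` with `h` the step
— a small constant excess at every separation.  A single-exponential model
cannot absorb this offset, and weighting the fit by the (tiny) jackknife
errors of the small-L bins would bias Lp upward by ~20%.  The fit is
therefore **unweighted** by default over its range (slope-dominated, which
cancels a common-factor offset to first order); `weighted=True` restores
1/se² weighting for curves where the model is exact.  The default fit
range is (one step, 2× a log-linear initial guess); the fit uses bounded
Levenberg–Marquardt (scipy `curve_fit`, bounds 0.1–10⁶ nm) and raises an
error when the optimum pins at a bound or the decay over the range is
under 1% (unidentifiable).

**Bending angles.** Signed heading differences at a fixed contour
separation, pooled over positions and molecules, wrapped to (−π, π],
histogrammed as a density (36 bins).  Separations that are not multiples
of the trace step are handled by re-resampling the trace at the requested
separation; note the chord effect above then applies at that scale
(variance ≈ (2/3)·L/Lp for adjacent chords rather than L/Lp for
instantaneous tangents).

**Contour statistics.** Per-molecule contour lengths (sum of consecutive
point distances, plus the closing segment for rings), with ensemble mean,
s.d. (ddof = 1) and a percent-change helper against a reference mean.

**Uncertainty.** Molecule-level bootstrap (resample molecules with
replacement, recompute curve and fit; default 200 replicates, minimum 10;
an error if more than 20% of replicates fail), reported as a 2.5–97.5%
percentile interval.  Chosen because single-molecule fits are too noisy
for per-molecule averaging and the between-molecule unit is the natural
exchangeable one.

**Known bias.** The full closed-ring calibration experiment (30 rings at
Lp 56 nm, fit over 8–120 nm) recovers Lp with a systematic +5…+10%
stiffening — the sum of the chord excess (~+4%), conditioning rings on
being non-self-intersecting (~+3%), ring-closure anticorrelation (~−2%)
and tracer smoothing (~+1%) — with ±7% seed-to-seed scatter at n = 30.
This is a property of the estimator protocol on ideal data, documented
rather than corrected; linear-molecule ensembles are essentially unbiased.

## 5. Topology

Classification on a segmented region proceeds: compact (crest height), then
plectoneme (skeleton branch points, or a skeleton-crest height above 1.6×
a bare-DNA calibration height — gently interwound bodies may skeletonize
without branching, but carry two unresolved strands and hence doubled
height), then open circle (no endpoints) or linear (two endpoints); a
single-endpoint skeleton is an explicit classification error.  Contour
length is traced for linear and circular molecules; a plectoneme's
underlying DNA length is not observable from its image and is reported as
unknown.

The superhelical-axis length is the summed Euclidean path length of the
pruned skeleton graph, with edges on cycles counted half (an apical end
loop's perimeter covers its axis extension twice).  On constructed
plectonemes the measurement lands within 8% of truth; on a straight
doubled-height rod it recovers the rod length within 5%.

Linking-number bookkeeping is pure arithmetic with the sign convention:
each bound protein dimer (9 bp footprint) unwinds the duplex by a given
angle, so `ΔTw = −n·φ/360` turns; a covalently closed circle keeps
`ΔLk = 0` and converts the deficit into writhe `Wr = −ΔTw > 0` (positive
supercoiling of an initially relaxed circle); a nicked circle or linear
molecule absorbs it (`Wr = 0`, `ΔLk = ΔTw`).  White's relation
`ΔLk = ΔTw + Wr` holds to machine precision in every state produced, and
the relative contour extension is `occupancy · Δrise/rise` with textbook
defaults (10.5 bp/turn, 0.34 nm/bp) exposed as parameters.  The per-dimer
unwinding angle and rise change are free parameters, not asserted values.

## 6. Reproducibility and problem sizes

All randomness flows from a single master seed through
`numpy.random.SeedSequence` derivation (children kept below 2³¹); reruns
of any stage, the pipeline, and the acceptance script are byte-identical.
The study-scale experiments use 30 closed plasmid-scale molecules
(856 nm ≈ 2686 bp) for the persistence-length calibration, 40 linear
1000 bp-scale molecules (328 nm) for contour recovery, pools of 30–40
molecules for angle and height statistics (50 random positions per
molecule for heights, excluding 10 nm at open ends to avoid end-cap bias),
and a 40-molecule labelled topology suite.  Monte-Carlo law checks in the
test suite use 300–400 chains.

## 7. Limitations

- Phantom chains: no excluded volume within or between molecules; the
  non-crossing filter is applied after sampling, which slightly stiffens
  the analyzable closed-ring ensemble (§4).
- One molecule per rendered image; the per-image threshold assumes
  comparable ridge heights within an image.
- No tip-shape deconvolution beyond the Gaussian blur model; heights are
  "as imaged".
- The compacted-particle model is a bounding-box stand-in used only to
  test the compact filter; no internal structure is modelled.
- Plectoneme rendering collapses the two interwound strands onto the
  superhelical axis at doubled height; strand-level winding is not
  resolved, matching what the measurement can see at this resolution.
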