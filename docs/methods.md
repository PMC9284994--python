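# Methods

## PRFS temperature reconstruction

The proton resonance frequency of water protons decreases approximately
linearly with temperature.  At echo time TE the phase of a spoiled
gradient-echo image therefore shifts by γ·α·B₀·TE per °C, with
γ = 2π·42.576×10⁶ rad/s/T, α the PRFS thermal coefficient (nominal
−0.01 ppm/°C for aqueous tissue, not calibrated per subject) and B₀ the
static field.  At the default 3 T / TE = 13.2 ms this is
−0.1059 rad/°C, giving a single-echo dynamic range of ±π/0.1059 ≈
±29.7 °C before the phase difference aliases.

**Referenced route.**  The baseline phase is the circular mean of the
pre-heating frames (the frame count is configurable; averaging reduces
baseline noise).  Phase differences are formed on the unit circle
(`angle(e^{iφ}·conj(z_base))`) so they are correctly wrapped.  The B₀
drift is modeled per slice as a 2-D polynomial of total degree ≤ 2 in
pixel coordinates normalized to [−1, 1] (for conditioning), fitted by
least squares to the phase difference inside a reference ring — the
brain mask minus its erosion by `width_px` (default 3) 4-connected
shells — and evaluated over the whole slice before subtraction.  A
rank-deficient design (e.g. a degenerate reference geometry) raises an
error naming the deficiency.  Order 2 empirically minimizes the
baseline-frame temperature SD when the injected drift is quadratic;
orders 1 and 3 under- and over-fit respectively (asserted in the test
suite on simulated data).

**Referenceless route.**  When a baseline is unusable the wrapped phase
difference is unwrapped with a Goldstein branch-cut algorithm: residues
are detected on 2×2 loops, opposite charges are paired greedily by
nearest-neighbour distance with row-major tie-breaking, unpaired
residues are cut to the nearest border, and a flood fill integrates
wrapped gradients without crossing the rasterized cuts; pixels
reachable only across a cut are flagged rather than guessed.  The
output is unique up to a global 2πk offset, which is absorbed by the
4th-order polynomial background subsequently fitted on the (unflagged)
edge ring and subtracted.

**ROI curves.**  Mean ΔT over a user-specified ROI per frame, its
maximum ("absolute maximal temperature increase") and the time from
sonication end to the first frame with mean ΔT ≤ ε.  ε defaults to 1 °C
because "return to baseline" is otherwise undefined for an
asymptotically decaying curve; curves that never return are flagged
rather than assigned a time.

## CEM43 dosimetry

Thermal damage is quantified as cumulative equivalent minutes at 43 °C.
Each interval between adjacent frames contributes R^(43−T)·Δt with Δt
in minutes, T the mean of the two endpoint temperatures (a trapezoid-
style average of the absolute temperature baseline + ΔT), and R = 0.50
for T ≥ 43 °C, 0.25 below.  The absolute baseline is a declared
parameter (default 37 °C): MR thermometry measures only changes.
Necrotic pixels are those with CEM43 strictly greater than the
threshold (default 70, an empirical necrosis threshold for soft
tissue); volume is the raw count times pixel area times slice
thickness, with no interpolation or connectivity filtering, so the
volume is exactly `pixel_count × voxel_volume`.  Isodose contours are
marching-squares level sets returned in physical millimetres.

## Histology volumetry

Traced lesion areas arrive as a CSV of (slice index, area in cm²,
full-thickness flag); tracing itself is manual and out of scope.  A
ruler spanning a known length calibrates pixels per cm; pixel areas
divide by the squared scale.  Volume is Σ area × 5 mm slice thickness
over sections the lesion passes fully through; sections where it does
not reach the posterior face contribute zero by default (an optional
`partial_fraction` relaxes this, since the full-thickness convention
otherwise discards real volume).

## Agreement statistics

Differences are `a − b` (histology minus MRTI by convention), SDs use
the n−1 denominator, limits of agreement are mean ± 1.96·SD with the
fixed normal quantile, and the percent difference normalizes by the
grand mean of all 2n measurements — the only convention under which
the bundled study table's mean difference of 0.052 cm³ corresponds to
11.1%.  The paired t-test is two-sided with n−1 degrees of freedom; a
zero-SD difference series yields t = ±∞, p = 0 (or t = 0, p = 1 when
identical).  Correlation reports Pearson r and r² from one computation
plus the OLS slope/intercept of b on a.

## The simulator

`simulate_temperature` integrates a Pennes-style bioheat equation for
the temperature rise ΔT on the acquisition grid:

    ∂ΔT/∂t = κ∇²ΔT − w·ΔT + Q(x, t)

with explicit finite differences, insulated (zero-flux) boundaries via
edge padding (chosen because it conserves total heat exactly, which the
tests assert), and automatic sub-stepping at 0.9× the explicit
stability bound dt ≤ 1/(2κΣ1/h² + w); a user-supplied step above the
bound raises an error naming it.

Parameters and defaults:

| parameter | default | rationale |
|---|---|---|
| grid, FOV | 256×256, 15×15 cm, 5 slices | acquisition matrix of the emulated protocol |
| slice thickness | 5 mm | protocol used 3–5 mm; 5 matches the histology sectioning |
| frame interval | 10 s | volumetric refresh rate of the emulated protocol |
| κ | 0.14 mm²/s | brain-tissue thermal diffusivity |
| w | 0.008 s⁻¹ | grey-matter-scale perfusion; with κ it reproduces the recorded 90–180 s return-to-baseline times |
| baseline temperature | 37 °C | normothermia; not measured in vivo |
| source radius / length | 0.75 / 7 mm | applicator element dimensions |
| radial decay | 14 mm | amplitude absorption scale of ~7 MHz ultrasound in brain |
| power scale | 0.4 °C/s/W | calibrated once so the 3 W / 120 s condition peaks at ~11 °C mean over a 5-mm ROI, inside the 7–23 °C range recorded in vivo, with lesions at the observed tenth-of-a-cm³ scale; never refit |
| phase noise | 0.02 rad | high-SNR gradient-echo phase noise (≈0.19 °C per frame) |

The source is a cylinder at `probe_position` with a smooth axial taper
over the 7 mm element; 180° sectors use a clipped-cosine angular weight
(sectored cylindrical radiators roll off toward the sector edges — a
binary half-plane mask lets pure conduction blur the back side far more
than the directional lesions observed in practice).  Directionality is
verified under the low-dose direction-check condition (1.5 W, 30 s)
where conduction has not yet crossed the sector plane; during a full
120 s burn, physical conduction necessarily carries heat around it.

Rendering inverts the PRFS relation: wrapped phase = wrap(background +
γαB₀TE·ΔT + drift(t) + noise), with a fixed smooth anatomical
background, a 2nd-order spatial polynomial drift whose coefficients
ramp linearly over the acquisition (matching the model the referenced
correction inverts), and additive Gaussian phase noise (the high-SNR
limit of Rician noise; phase noise is what PRFS consumes).  Identical
config and seed give bit-identical output.

Synthetic histology resamples the true necrosis mask onto 5-mm sections
by overlap-weighted area redistribution (volume-preserving up to one
voxel quantum) and optionally applies multiplicative tracing noise.

**What the simulator does not emulate:** k-space/reconstruction
effects, susceptibility artifacts near the applicator, motion,
tissue heterogeneity or temperature-dependent perfusion, and acoustic
propagation (no refraction, standing waves or transducer efficiency
spread).  Passing tests therefore demonstrate the correctness of the
computational chain under the stated noise/drift model, not in-vivo
accuracy.

## Numerical choices and problem sizes

- Baseline = circular mean of all pre-heating frames (2 by default).
- Polynomial fits are per slice in normalized coordinates; drift
  surfaces are evaluated everywhere from edge-ring fits.
- Unwrap flood fill adds integer multiples of 2π, so wrap(unwrapped)
  equals the input bitwise-nearly wherever unflagged.
- The end-to-end volume-recovery experiment runs ten sonications at the
  recorded power/duration/pattern settings on the full 256×256 grid
  with default noise and randomized quadratic drift; the unit suite
  exercises the same code paths on 48–128 px grids to stay fast.
- Thresholding is strict (>), tie-free by construction on simulated
  data.

## Known limitations

- Single-echo referenced PRFS aliases beyond ±29.7 °C; the hottest core
  pixels of a 6 W / 180 s sonication exceed this and read wrong, but
  their cumulative dose passes the necrosis threshold before aliasing
  begins, so thresholded volumes are unaffected.  Temporal unwrapping
  is not implemented.
- The drift polynomial fitted on the brain-edge ring absorbs any real
  heating that reaches the ring; on long simulations this biases
  temperatures by ~0.05 °C (asserted < 0.1 °C in the tests), which is
  below the phase-noise floor.
- The heating model has a single global power-scale constant; it cannot
  reproduce the animal-to-animal spread of recorded temperature rises
  at equal nominal power (efficiency and tissue variability are not
  modeled).
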