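# Methods

This note records the physical models, numerical choices and known
limitations behind `scintqa`, in the order the data flows: proton
transport → scintillation quenching → camera geometry → image pipeline →
synthetic scenes → QA metrics.

## Proton transport

The transport model is a one-dimensional condensed-history surrogate for
a full Monte Carlo treatment-head simulation. It is built for central-axis
depth curves of clinical beams in the 0.1–250 MeV window and makes three
deliberate simplifications: no lateral scatter (broad fields near lateral
equilibrium are assumed), no secondary-particle transport, and nuclear
interactions reduced to removal of primaries.

**Stopping power.** Electronic stopping power comes from the Bethe
formula with the full T_max kinematics, using each material's effective
Z/A (Bragg additivity over mass fractions) and a material-level mean
excitation energy: water 75 eV, PMMA 74 eV, polyvinyltoluene 64.7 eV,
air 85.7 eV — standard tabulated values, overridable per material. Shell
and density-effect corrections are omitted; they matter below ~1 MeV and
above several hundred MeV. Against published proton tables for water the
implementation agrees to 0.02% at 100 MeV and 0.6% at 10 MeV, and the
60 MeV CSDA range agrees to 0.2%; these anchors are frozen in the test
suite.

**Built-in materials.** BC-408 is polyvinyltoluene with the data-sheet
density 1.03 g/cm³ and H:C atom ratio 1.104 (mass fractions H 0.0848,
C 0.9152, Z/A = 0.5414); water, PMMA (C₅H₈O₂, ρ = 1.19) and dry air are
included for degrader and reference calculations.

**Histories.** Each history samples its energy from the beam's Gaussian
(default 60 ± 0.36 MeV), crosses the collimator-to-surface air gap
(default 70 mm, treated as an upstream layer), and steps through the slab
stack. Steps are capped at min(0.1 mm, 1% of residual range, the bin
width, distance to the next boundary); in air only the 1%-of-range rule
applies since nothing is scored there. Energy-loss straggling is Gaussian
with the Bohr variance per step (with the relativistic spin-0 correction
factor); it is the dominant peak-broadening mechanism beyond the initial
energy spread. Below the 0.5 MeV transport cutoff (residual range of a
few µm) the remaining energy is deposited locally.

**Nuclear attenuation.** Nonelastic nuclear interactions remove primary
protons with probability ρ·Δs/λ per step, λ = 1100 mm water-equivalent by
default; removed protons deposit nothing locally. This mimics the
fluence decline that depresses the Bragg peak relative to the entrance
plateau in full simulations; it can be disabled, in which case total
deposited energy equals total initial energy to better than 1e-6
(an enforced invariant).

**Scoring.** Depth-dose and LET are histogrammed in 0.125 mm bins
(matching the finest practical voxel pitch for a 10 cm block at camera
resolution). Each step's deposit is shared between the (at most two)
bins it overlaps in proportion to overlap length — midpoint binning
would alias the common 0.1 mm step against the 0.125 mm grid and imprint
a spurious 1-1-2 sawtooth on the plateau. LET(z) is the *track-averaged*
electronic stopping power of primaries: Σ S·ds / Σ ds over all primary
sub-steps in the bin. Path-length weighting matters: an unweighted
per-step mean over-weights the shrinking adaptive sub-steps near end of
range and inflates the peak LET by ~40%.

**Peak localization.** The Bragg-peak depth is the vertex of a parabola
fitted through the five bins around the maximum (tie-break to the
shallowest bin); for noiseless single-energy runs the raw argmax bin is
the better-defined quantity and the tests use it there.

## Birks quenching

The per-bin model is light(z) = L₀·D(z)/(1 + kB·LET(z)) with kB in
mm/MeV. The correction curve is its exact algebraic inverse,
f(z) = 1 + kB·LET(z), so correction ∘ quenching is the identity on the
dose shape for any kB ≥ 0 — a property enforced to 1e-12 in the tests.

**Fitting kB.** `fit_birks` supports two forms. The classic
light-versus-LET curve, L = L₀·LET/(1 + kB·LET), implicitly assumes dose
∝ LET, i.e. constant primary fluence; with nuclear attenuation on, the
secular fluence decline masquerades as extra quenching and biases kB by
about +14% on otherwise perfect data. When the simulated depth-dose is
supplied, the fit uses the exact per-bin relation
L = L₀·D/(1 + kB·LET), which is unbiased wherever the profiles are
registered — this is the recommended and default analysis route, since
any workflow that has simulated LET also has simulated dose.

**Fit window.** Bins from the entrance to the light maximum plus the
distal 80%→20% falloff are used; beyond the 20% point the track-averaged
LET of the few surviving protons spikes while the light is ~0, and those
points carry no usable information. Under the LET-only model even the
80→20 window is unusable (the fluence is collapsing there — fitted kB
triples); `window="prepeak"` is advised for that form.

**Uncertainty.** The 95% CI is the asymptotic linearized covariance from
the least-squares fit with a t quantile. Weights are uniform by default
with an inverse-variance option; with correctly specified weights the CI
covers the true kB at the nominal rate (the test asserts coverage ≥ 92%
over 200 replicates, the 95% nominal minus two binomial standard errors
at that sample size — an allowance fixed before the experiment).

**Registration.** Measured and simulated profiles are aligned at the
distal 50% falloff crossing — the sharpest feature of a Bragg curve and
the least sensitive to quenching — then resampled by linear
interpolation. Range *comparisons* in the QA module are deliberately done
in the absolute depth frame so that a range shift is detected, with
registration applied only for point-wise deviation maps.

**Normalization.** Corrected profiles are normalized to the mean over the
2–7 mm entrance window by default (the plateau is quenching-stable);
peak and area normalizations are available. The same window defines the
peak/plateau ratio (max over plateau mean).

## Camera geometry

Sign convention: x is signed along the viewing axis, positive toward the
camera, |x| < r. A plane at offset x appears brighter by r²/(r−x)²
(solid angle) and stretched along depth by (r+x)/r. Near planes therefore
contribute more intensity than far planes — the physically required
asymmetry — and the two factors agree to first order in x/r (2.5% here:
r = 500 mm, 25 mm field).

**Forward projection.** The cylindrical beam cross-section is discretized
into 64 chord-weighted planes (converged to ≪0.1% for this geometry; 32
is the documented minimum). The image column profile is the chord-
weighted sum of intensity-scaled, depth-magnified copies of the midline
profile.

**Inversion.** The forward sum is assembled as a linear operator on the
pixel grid and inverted by Tikhonov least squares with a second-
difference penalty, λ² scaled to the operator's mean diagonal energy and
a dimensionless smoothness knob (default 0.03). The forward kernel is a
depth-proportional smoothing (±2.5% of depth, ~0.75 mm at the 60 MeV
peak) whose raw inverse amplifies per-pixel noise four orders of
magnitude; the curvature penalty caps the amplification at ~10× while
leaving features wider than a couple of pixels intact. The default was
chosen from the bias/variance sweep: analytic round-trip error ≤1% (with
the structural error concentrated in the boundary half-pixel at the
block face) and the smallest closed-loop peak error across seeds. The
kernel reduces exactly to the identity as the field diameter → 0 or
r → ∞.

## Image pipeline

Stage order: dark subtraction → 3×3 median filter → flat-field division →
ROI accumulation over the repeated frames → central-axis band extraction
(±2 mm around the intensity centroid) → perspective inversion →
resampling to the 0.125 mm grid. Median before flat-field avoids
amplifying impulse noise at low-gain pixels. The vignetting gain field is
the dark-subtracted flat, median-filtered (3×3) *before* normalizing to
its maximum — without that filter a single hot pixel sets the maximum and
rescales the entire gain field by a random few percent — and gains are
clipped below 0.05. Every stage is linear under positive scaling of the
input (the median commutes with it), so the chain preserves relative
dosimetry; a stage failure aborts with the stage name.

## Synthetic scenes

The renderer inverts the correction chain: simulate dose/LET, quench,
optionally add the distal exponential tail artifact (default 5.1% of
peak, 3 mm decay constant — the optical re-scatter feature reported for
scintillator photographs; its physical origin is out of scope), forward-
project over the beam cylinder, blur with a 1 px Gaussian PSF, apply a
radial quadratic vignetting field (25% corner falloff), add dark offset
(100 counts), Poisson shot noise, Gaussian read noise (2 counts), hot
pixels (rate 1e-5, saturating), and quantize to the 14-bit range.

Scale anchors: the exposure constant (1400 counts per Gy at the light
peak per frame) folds the scintillator yield (~8000 photons/MeV), solid
angle and quantum efficiency into one number, set so the highest
characterization dose (9 Gy) fills ~80% of the dynamic range without
saturating — absolute radiometry is not attempted, the system is a
relative dosimeter. Default scene: 4.5 Gy, three frames, 320×480 px at
0.1 mm/px, beam entering at column 24. Monitor-unit bookkeeping uses
1 MU = 0.9 Gy (pristine peak) and 0.7 Gy (SOBP mid-modulation).

What the generator does *not* emulate: internal optical photon transport
(absorption/re-emission beyond the parametric tail), Cerenkov light
(~1e-5 of scintillation for these beams), lens distortion,
depth-of-field variation, cyclotron RF interference, and the coupling
between lateral position and per-plane projection (the lateral chord
profile is rendered separably from depth — a ~(x/r)² approximation).
Passing closed-loop tests therefore demonstrate the correctness of the
geometry/quenching inversions under realistic counting statistics, not
robustness to every optical artifact of a physical lens.

Noise levels were set to reproduce the sub-1% short-term repeatability
reported for camera-scintillator systems; with three accumulated frames
and band averaging the synthetic repeatability CV is ~0.15%.

## QA metrics and SOBP

Range points d90/d80/d50 are linear interpolations of the first distal
crossing below the given fraction of the maximum. SOBPs are weighted sums
of pristine peaks simulated on one common grid; quenching is applied per
component (each with its own LET) before summation, which is what makes a
quenched SOBP tilt downward toward the distal end. Flat-modulation
weights come from non-negative least squares against a unit target over
the modulation interval; component energies are generated from the
0.84 mm PMMA modulator-step geometry, giving ~1 mm range spacing in the
scintillator. Simulation sizes: 100k histories for reference curves
(plateau bin noise ~0.5%), 2.5k per SOBP component, 8–30k for scene
truth in the test suite — chosen so each statistical assertion sits well
above its Monte Carlo noise floor.

## Known limitations

- The water/BC-408 Bragg-peak depth difference predicted at 60 MeV is
  0.79 mm (water-equivalence ratio 1.026, consistent with published
  stopping-power tables for vinyltoluene-based scintillator). Smaller
  figures (~0.25 mm) are sometimes quoted for this detector; they cannot
  be reproduced from the data-sheet density and standard mean excitation
  energies, which would require an effective water-equivalence ratio of
  ~1.008.
- The 1-D transport overestimates the 60 MeV peak/plateau ratio by
  ~10% (5.6 versus 5.1 measured by an ionization chamber): chamber
  volume averaging, beam divergence, secondary-particle build-up and
  multiple-scattering detour are not modelled, and primaries removed by
  the nuclear term deposit nothing locally.
- kB is treated as energy-independent and the quadratic Birks extension
  is out of scope.
- The pipeline ingests 16-bit grayscale TIFF; raw camera formats and
  demosaicing are upstream of this package.
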