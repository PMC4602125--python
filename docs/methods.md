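# Methods

This note documents the models, numerical choices and design decisions
behind `infarctvt`, and what the synthetic data do and do not establish.

## Membrane model

Membrane kinetics follow the Luo–Rudy dynamic (LRd) guinea-pig ventricular
model with the split delayed rectifier (I_Kr, I_Ks): fast sodium current,
L-type calcium current as a GHK flux with calcium-dependent inactivation,
inward rectifier, plateau potassium current, Na/Ca exchange, Na/K pump,
nonspecific Ca-activated current, sarcolemmal Ca pump, background Na and
Ca currents, and a two-compartment sarcoplasmic reticulum (network and
junctional) with uptake, leak, translocation and calcium-induced calcium
release. The constants are pinned in `lrd.py` as a versioned block; they
are an external fixture of this package, not a tuning target.

Two deliberate simplifications of the calcium subsystem, documented here
because the published model leaves them to the implementer:

* **Rapid buffering.** Troponin/calmodulin (myoplasm) and calsequestrin
  (junctional SR) buffering is applied through the instantaneous-buffering
  factor `β(Ca) = 1/(1 + Σ B_tot K_m/(K_m+Ca)²)` rather than buffer ODEs.
* **Release trigger.** Calcium-induced calcium release starts when the
  local voltage crosses −35 mV upward (with a 50 ms episode refractory
  period) and follows `G_rel(t) = Ḡ_rel (1−e^{−t/τ_on}) e^{−t/τ_off}`
  with τ_on = τ_off = 2 ms. Ḡ_rel = 22 ms⁻¹ was chosen once so that the
  calcium transient peaks near 1 µM under 600 ms pacing, then frozen.

The quiescent resting state shipped in `lrd.RESTING_STATE` was obtained by
relaxing the model equations to equilibrium with a stiff implicit
integrator (reproducible via `relax_to_rest`); the net membrane current at
that state is ~2·10⁻⁸ µA/µF and a paced-free second of simulation moves
the voltage by ~2·10⁻⁵ mV.

Gray-zone (GZ) remodeling multiplies peak I_Na by 0.38, I_Ca(L) by 0.31,
I_Kr by 0.30 and I_Ks by 0.20. In this implementation that yields, at
600 ms pacing, a GZ action potential with peak +31 mV vs +56 mV, maximum
upstroke velocity reduced by ~25–40 %, and APD90 longer by ~18 % — the
correct qualitative phenotype; the APD prolongation is modest because the
reduced L-type current partially offsets the reduced delayed rectifiers.

## Tissue model

The monodomain equation

    β C_m ∂V/∂t = ∇·(σ ∇V) − β I_ion + β I_stim

is discretized on node-centred structured grids (1D cables, 2D sheets,
small 3D slabs) with no-flux boundaries. The per-node conductivity tensor
is the in-plane rotation of diag(σ_l, σ_t, σ_t) by the local fiber angle;
face conductances use harmonic means so flux stays continuous across
tissue-type boundaries, and the mixed-derivative term is added with
centred differences where fiber angles are oblique. Time integration is
operator-split per step: explicit diffusion, then the membrane update
(Rush–Larsen for gates, forward Euler for voltage and concentrations) at a
fixed default dt = 0.02 ms, refused if it violates the explicit diffusion
stability bound. The compiled kernel uses voltage-indexed lookup tables
(0.01 mV grid, linear interpolation) and refreshes the Nernst potentials
every 25 steps; it agrees with the transparent NumPy reference to ~1 % in
all state variables over a paced beat.

Parameters:

* σ_l = 0.28 S/m, σ_t = 0.026 S/m (normal myocardium); GZ transverse
  conductivity scaled by 0.1; C_m = 1 µF/cm².
* **Surface-to-volume ratio β = 4900 cm⁻¹** is the package's single
  calibration constant: chosen once so the default conductivities give
  45 cm/s longitudinal conduction velocity on a cable at 0.1 mm node
  spacing (dt = 0.02 ms), then frozen. Halving dt and spacing moves the
  measured CV by ~1 %.
* Scar is passive: it keeps diffusive coupling (isotropically at σ_t) and
  carries only a linear leak (0.05 mS/µF) to the resting potential. A
  zero-conductivity alternative is available via
  `ConductivityParams(scar_coupled=False)`.
* Activation time is the instant of maximum dV/dt during an upstroke
  (armed when V crosses −60 mV upward, committed when V reaches −20 mV
  with a peak slope above 5 mV/ms); a −40 mV-crossing convention is
  selectable. Activations are recorded on the fly, so activation maps and
  reentry detection need no stored frames.

Numerical resolution limits worth knowing: transverse propagation in
normal tissue requires node spacing ≤ 0.2 mm (at 0.2 mm it runs at
~4.8 cm/s, below the continuum value — discrete-limit slowing), and the
gray zone's 10×-reduced transverse conductivity cannot sustain propagation
at any practical spacing, i.e. GZ conducts effectively along fibers only.
These are properties of explicit finite differences at desk scale and are
the reason the packaged reentry fixture routes all conduction along
corridors and fiber-aligned channels.

## Programmed stimulation

The default protocol is 6 S1 beats at 600 ms from one site, then S2
starting at 90 % of the S1 cycle length and shortened in 10 ms decrements
to a 120 ms minimum; on failure S3, then S4, are added, each starting at
90 % of the preceding coupling interval (symmetric rule; the decrement,
minimum coupling and S3/S4 rule are package defaults, configurable).
Induction is declared when sentinel nodes register at least two
activations later than one paced cycle after the last stimulus; the VT
cycle length is the median inter-activation interval, and induced episodes
are continued to 3 s. Stimuli are 2 ms, 60 µA/µF, in a 1.2 mm ball.

Implementation note: the quiet interval between the drive-train snapshot
and each candidate extrastimulus is identical across trials, so it is
simulated once and checkpointed at every tested onset; each trial restarts
from its checkpoint, bit-identically to simulating the wait inline.

## The reentry fixture

`isthmus_fixture_grid()` is a 12.8 × 18 mm sheet (0.2 mm nodes) shaped
like a θ: 2 mm conduction corridors around the perimeter, two passive
scar blocks (3.2 × 14 mm), and a shared 2.4 mm gray-zone isthmus between
them whose internal fibers run along the channel (border-zone fiber
disarray); a 2 mm normal-tissue plug at the channel's exit mouth lets the
returning wavefront re-ignite the channel, while the gray-zone entrance
mouth keeps its long refractoriness for unidirectional block. Under the
default protocol the S2 at a 170 ms coupling blocks at the channel, travels
around both scars through the slow (transverse) lateral corridors and
re-enters: sustained figure-of-eight VT at a ~399 ms cycle length, with
phase winding ±1 around the two scar blocks and the organizing centre on a
designed anchoring-scar centroid. The fixture was designed analytically
(the loop time must exceed the channel's functional refractory period,
~170 ms isolated and ~300 ms in situ) and verified by simulation; it ships
as a regression target.

## Phantoms and segmentation

Phantom voxels take the label of the geometry primitive containing their
centre (voxel-centre convention: position = origin + (index + 0.5)·spacing
everywhere in the package); intensities are per-class Gaussians truncated
at zero (normal tissue with its own SD, a shared additive acquisition
noise for all classes), seeded and bit-reproducible. Partial volume enters
only through k-space downsampling, never at generation, so native ground
truth stays exact. No published intensity statistics exist for the kind of
scans emulated here; the defaults (normal 100 ± 5, GZ 160, scar 220,
noise SD 5) are the package's documented free parameters.

Two bath conventions are used deliberately:

* The default phantom has a **bright bath** (500), the configuration in
  which Otsu bath/myocardium separation is exact on noise-free images and
  Dice > 0.99 on noisy ones.
* The packaged resolution-study phantoms use a **signal-free (dark) bath**,
  as in ex-vivo scans in susceptibility-matched fluid. With a bright bath,
  partial-volume bleed after downsampling inflates the myocardial
  mean + 3 SD far above the blurred infarct peak and the measured infarct
  shrinks — the opposite of the real behaviour. With a dark bath and
  threshold statistics restricted to the wall interior (eroded by the
  target resolution, `downsampled_thresholds`; the stand-in for
  conservatively drawn manual boundaries), the infarct volume grows with
  downsampling while the total ventricular volume is preserved, matching
  the physics the pipeline is meant to show.

In the resolution study, the myocardium boundary at every resolution comes
from the phantom ground truth — the stand-in for the manual/spline
boundary segmentation used clinically; Otsu remains the automatic method
for native-resolution images and is exercised separately. The infarct
region of interest is supplied as a mask (ground truth dilated by a
configurable margin), replacing per-slice manual drawing. Boundary
conventions: intensity exactly at normal_max is normal; exactly at
gz_upper is GZ.

## Analysis

The pseudo-ECG is the standard monodomain far-field approximation:
φ(e) ∝ ∫ ∇V_m · ∇(1/r) dv over tissue, evaluated from stored voltage
frames with the proportionality constant fixed at 1 (waveform shape, not
amplitude, is the contract; electrodes default to ±100 mm from the tissue
centre). MAD comparisons between runs crop each trace at the upstroke of
its dominant deflection and resample to a common length by linear
interpolation.

Reentry localization builds a phase map (Hilbert transform of the
mean-subtracted frames over the last second) and runs two detectors over
frames sampled from the middle half of the window (the Hilbert phase is
unreliable at window edges): free phase singularities by the winding
number of 2×2 node plaquettes, and anatomical anchors by the winding
number along a closed contour around each face-connected scar component.
The anchor is the component with the largest |winding| (ties broken by
distance to the mean singular position, then by component id); the
organizing centre is its centroid, following the convention of marking the
midpoint of the anchoring scar. Patterns: two opposite chiralities on the
analyzed surface → figure-of-eight; rotational activity only on interior
slices → breakthrough; otherwise → reentry. For 3D grids the analyzed
surface is the top z-slice.

## Problem sizes and what the tests show

All simulations are desk-scale by design: cables of 200–400 nodes, sheets
of ≲ 6 000 nodes, phantoms of ≲ 4·10⁵ voxels, chosen so the full test
suite and the acceptance script each run on one CPU in minutes. The
synthetic phantoms emulate LGE contrast, class noise and partial volume,
but not acquisition physics (Rician noise, bias fields, gadolinium-leak
artifacts), realistic biventricular anatomy, or fiber architecture beyond
parametric rules — so passing tests establish the correctness and internal
consistency of the pipeline's mechanics, not clinical accuracy on real
hearts. Quantities that depend on the real anatomy (absolute volumes,
circuit distances between resolutions, morphology-match rates) are
exercised structurally, not reproduced numerically.

## Known limitations

* Explicit diffusion restricts node spacing and time step jointly; the
  gray-zone transverse direction is effectively non-conducting at desk
  scale (see above).
* The scar-winding localization assumes the circulating wave is resolved
  by the frame cadence (default 2 ms) and ≥ 2 cycles of frames.
* `resolution_study` simulates a mid-wall 2D slice of the segmented
  volume rather than the full 3D ventricle, and its induction behaviour
  at 0.39 mm slice spacing is longitudinal-dominated.
* The paired t-test helper treats volumes as matched samples and reports
  signed infinity for zero-variance nonzero differences rather than
  attempting a continuity correction.
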