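# Methods

`proswing` studies how swing-phase knee flexion damping (KFD_sw) shapes
the swing of a transfemoral prosthetic limb. It has two halves: an
analysis pipeline that turns marker trajectories and vertical
ground-reaction forces into swing-phase outcome measures, and a
synthetic gait generator that produces marker-level walking trials with
known ground truth. The generator exists because motion-capture data of
this kind are rarely shareable; it defines the study conditions under
which the pipeline is validated.

## Outcome measures

All measures are computed per stride over the swing phase (ipsilateral
foot off → next ipsilateral foot contact), time-normalized to 0–100 %:

- **Effective leg length (ELL)** — 3-D Euclidean distance from the hip
  joint center to the virtual toe (vTOE). A functional analog of knee
  flexion: the limb must shorten to pass the stance limb. A
  sagittal-projected variant is available behind a flag
  (`PipelineParams.ell_sagittal`) for sensitivity analysis; the default
  is the unqualified 3-D distance.
- **Toe clearance (TC)** — vertical height of vTOE above the floor
  plane (z = 0). Negative values mean the rigid-body estimate dips
  below the floor; they are preserved, never clamped.
- **Joint angles** — hip flexion α (thigh anterior tilt from the
  downward vertical), knee flexion β (posterior rotation of the shank
  relative to the thigh; 0 when collinear), ankle dorsiflexion γ
  (deviation of the foot–shank angle from the standing calibration).
- **Toe-height sensitivities (TZS)** — planar partial derivatives of
  vTOE height with respect to each joint rotation:
  ∂z/∂α = x_TOE − x_HIP, ∂z/∂β = x_KNE − x_TOE, ∂z/∂γ = x_TOE − x_ANK
  (m/rad), evaluated at the instant of minimum toe clearance. Each
  follows from rotating the chain distal to the joint about the lab's
  medial-lateral axis; the test-suite checks them against a central
  finite-difference oracle on random poses.
- **Scalar features per stride** — ELL_MIN, TC_MIN, the swing-percent
  timings ELL_MAX_t, TC_MIN_t, KE_MAX_t (maximum knee extension,
  searched from the frame of peak knee flexion to the end of swing so a
  pre-flexion extended pose is never selected), the mid-swing time MSWt
  (swing ankle passes the stance ankle along the walking direction),
  relative timings (feature − MSWt, positive = after mid-swing),
  swing-time symmetry STS = 100·t_pros/(t_pros + t_sound) (50 % =
  symmetric), and three compensation measures: walking speed (mid-hip
  progression; a stand-in for the whole-body center of mass), hip
  height at TC_MIN_t, and the lateral hip–ankle distance at TC_MIN_t (a
  circumduction proxy).
- All argmin/argmax ties break toward the earlier frame, everywhere,
  for determinism.

## Pipeline

1. **Gap interpolation** — cubic spline over marker gaps of ≤ 5 frames;
   longer gaps stay flagged and invalidate the stride. Interpolation is
   an explicit step, never silent.
2. **Filtering** — 4th-order bidirectional (zero-phase) 6 Hz low-pass
   Butterworth on raw marker coordinates, before any derived signal.
   Even-reflective edge padding of 3×order samples; boundary samples
   therefore differ from an infinite-signal filter, so trials include
   lead-in/lead-out beyond the strides of interest.
3. **Virtual toe** — heel and toe markers of the standing calibration
   are projected onto the floor; vTOE is placed on the projected
   heel→toe axis at `foot_length + radius_sign·marker_radius` from the
   projected heel. The marker-radius convention is ambiguous in
   practice; the default `radius_sign = +1` treats the heel-marker
   center as one radius posterior of the heel surface, and the sign is
   configurable (`--radius-sign {+1,-1,0}`) and logged. During walking
   vTOE is reconstructed per frame from the least-squares optimal
   proper rigid transform (Kabsch) of the heel/toe/metatarsal triad,
   assuming the unloaded foot is rigid.
4. **Events** — foot off is kinetic: the first force sample strictly
   below 5 N after ≥ 50 ms continuously at/above it (the debounce
   rejects noise spikes), mapped to the nearest kinematic frame with
   ties toward the earlier frame (960 → 120 Hz is 8:1). Foot contact is
   kinematic: a candidate at each local maximum of the ankle's anterior
   position relative to the mid-hip point, confirmed at the first
   subsequent frame with ankle height within 10 mm of standing height
   and vertical speed below 0.05 m/s. Unconfirmable strides are
   flagged and excluded from averaging rather than guessed — the
   codified stand-in for manual event verification. Mid-swing
   minimizes the along-direction ankle separation within the stride.
   The walking direction is the floor-projected net mid-hip
   displacement, snapped to the nearest lab axis by default.
5. **Trend analysis** — features are averaged over the first five
   accepted strides per condition (chronological; the selection rule
   among more candidates is otherwise arbitrary), then regressed on the
   damping coefficient with linear and quadratic ordinary least squares
   (plain normal equations; R² = 1 − SSE/SST, defined as 1 when
   SST = 0, which is logged). R² is unadjusted. Cross-participant
   reports average R² unweighted. A qualitative direction check reports
   whether condition means move the way increased damping moves them:
   TC_MIN ↓, ELL_MIN ↑, TC_MIN_t ↓, ELL_MAX_t ↓, KE_MAX_t ↓, STS ↓
   toward 50, TZS_HIP ↓ (Spearman sign of association; sign of the
   difference for two conditions). No p-values are produced by design.

## The synthetic gait generator

Planar sagittal kinematics with lateral offsets added kinematically.
The sound limb and all stance phases are prescribed; the only simulated
dynamics are those the damping manipulation acts on: the prosthetic
swing knee.

**Pendulum model.** The prosthetic shank+foot is one rigid body about
the knee (the prosthetic ankle is passive and the unloaded foot rigid):
mass 2.2 kg, COM 0.22 m from the knee, inertia 0.16 kg·m² — a light
energy-storage-and-return build. The knee pivot follows the prescribed
thigh, so the equation of motion contains gravity plus
pivot-acceleration terms:

    I·φ̈ = −m·d·(g·sin φ + a_Kx·cos φ + a_Kz·sin φ) + τ_knee,  β = α − φ

with device torques: viscous damping −c·β̇ only while flexing (β̇ > 0;
the one-way clutch), smoothed Coulomb friction of magnitude
`friction_torque`, and an extension bumper (400 Nm/rad, 15 Nm/(rad/s))
engaged at β < 0. Integration is fixed-step classical Runge–Kutta at
the kinetic sampling interval (1/960 s), decimated to the kinematic
rate — deterministic by construction. Energy bookkeeping: the damper
removes c·β̇² ≥ 0 W, exactly zero during extension; with the device
torques off and a stationary pivot, total energy is conserved to ~1e-15
relative per swing and the small-amplitude period matches
2π·√(I/(m·g·d)) to 0.01 %.

**Swing initial state.** Late stance imparts (β₀, β̇₀). Because the
damper engages as soon as pre-swing flexion begins, this state is
damping-dependent: a first-order admittance attenuates the zero-damping
velocity by I/(I + c·t_pre) (t_pre = 0.14 s) and the angle by the
square root of that factor (the toe-off angle is partly forced by
trailing-limb geometry). This is the mechanism behind the flexion
plateau at high damping and, downstream, the migration of the
toe-clearance minimum from after to before mid-swing. Defaults
β₀ = 0.60 rad, β̇₀ = 4.6 rad/s give a peak flexion of ~72° at zero
damping falling to ~33° at 1.10 Nm/(rad/s).

**Foot placement (paced landing).** Contact occurs at
max(nominal swing end, pace_offset + w·t_ext, t_ext + margin), where
t_ext is the time the knee first re-extends below 5° after peak
flexion (pace_offset 0.50 s, w 0.2, margin 0.04 s), rounded to the
kinematic frame grid. This models users pacing the landing near their
habitual swing duration while still waiting for the knee to extend:
low damping (slow re-extension) prolongs prosthetic swing, shrinking
symmetry; high damping lets the habitual pace dominate. A purely
additive wait after extension was rejected: it makes the timing of
maximum knee extension a constant fraction of swing across all
conditions, which contradicts the device behaviour being modelled.

**Markers and landing realization.** Markers (hip joint center, knee,
ankle, heel, toe, metatarsal head per limb) are placed from segment
geometry each frame; foot markers move rigidly with the shank during
swing. The ankle's terminal descent is shaped as a C¹ cubic Hermite
from the raw swing state into a constant-slope glide (0.09–0.10 m/s)
ending in a corner exactly at the contact instant, then pinned at
standing ankle height through early stance; a minimum-clearance
step-over (22 mm) guarantees the descent through the detector's height
band happens at glide speed rather than in a slow skim. The glide
slope is about twice the detector's vertical-velocity threshold, so the
zero-phase 6 Hz filter places the criterion crossing at the corner:
noise-free detection is accurate to ±1 frame by construction, and
stays within ±2 frames (95th percentile) at 0.5 mm marker noise. The
vertical mismatch absorbed by the landing is applied to the whole limb
(a pelvic-obliquity-like shift), preserving limb rigidity and hence
every length-based measure.

**Everything else.** Hip centers advance at constant speed with a
2-per-stride vertical sinusoid (12 mm amplitude, minima near the foot
contacts); thigh angles are stride-periodic sinusoids (amplitude
0.35 rad) with peak flexion at 40 % of the stride after foot off; the
sound knee follows a skewed two-bump profile (peak ~60° past
mid-swing, so late-swing clearance stays high). Vertical GRFs are
raised-cosine-edged plateaus scaled to 1.1 body weight, sampled at
960 Hz; the analytic 5 N crossing of each unloading ramp is the
ground-truth foot-off time. Hip hike and circumduction are swing-gated
offsets of the prosthetic limb (flat-top windows; the hike releases
through terminal swing and rides on top of the landing solution, so the
foot still lands at standing height). Marker noise is Gaussian,
isotropic, i.i.d. at 0.5 mm, one independent seeded substream per
marker. Identical configs and seeds reproduce trials bit-exactly.

**Study conditions.** The default damping sweep is the coefficient set
of the prototype's interchangeable rotary dampers for the reference
participant: 0, 0.37, 0.56, 0.80, 1.10 Nm/(rad/s), five strides
averaged per condition, walking speed 1.24 m/s, stride period 1.1 s,
segment lengths for a ~1.66 m adult (thigh and shank 0.43 m, foot
0.21 m, marker radius 9.5 mm), body mass 68.7 kg. Under these
conditions the full noisy pipeline reproduces every expected trend
direction, including the sign change of TC_MIN_t − MSWt from positive
at zero damping to negative at the highest setting, robustly across
seeds.

## What the generator does and does not emulate

It emulates: two-limb periodic gait, a physically integrated swing knee
whose response to damping has the right signs and plausible magnitudes,
stance force profiles sufficient for kinetic event detection, optical
marker noise, rigid-foot swing kinematics, and optional proximal
compensations. It does not emulate: soft-tissue artifact, within-trial
stride-to-stride biological variability (strides differ only through
marker noise), double-support mechanics, 3-D pelvis/trunk dynamics,
foot deformation under load, or force-plate crosstalk. Passing tests
therefore demonstrate that the pipeline recovers what this model
encodes — event times, rigid-body landmarks, profile extrema and their
trends — not that it is robust to every artifact of real capture data.

## Numerical choices and degenerate inputs

- Stride durations are frame-quantized; swing-time symmetry differences
  between neighbouring high-damping conditions can be a fraction of a
  frame, so symmetry is evaluated as an overall decreasing trend toward
  50 % rather than per-step strict monotonicity.
- Butterworth padding: even reflection, 12 samples; series shorter than
  3× that are refused rather than filtered badly.
- Rigid transforms use SVD with a determinant correction, refusing
  collinear triads; a swing window with > 10 % gap frames is an
  "untrackable swing" error rather than an extrapolation.
- Coulomb friction uses a tanh(β̇/0.02) smoothing so fixed-step RK4 does
  not chatter at the extension stop.
- Divergent integrations (|β| > π) raise an error naming the
  configuration invalid instead of producing markers.
- The extension bumper's parameters are chosen for numerical stability
  and plausible overshoot (≲ 4° at the fastest extension), not measured
  from hardware; the real device's bumper is uncharacterized.

## Problem sizes

Default trials simulate 6 strides (~7.7 s at 120 Hz); validation uses
3-stride trials, 100-trial Monte-Carlo batches for noise percentiles,
200 random poses for the sensitivity oracle, and 1000 random small
datasets for the nested-R² property. These sizes make the whole
verification suite run in well under a minute each while leaving the
percentile estimates stable to the asserted tolerances.

## Known limitations

- ELL_MIN saturates as damping suppresses knee flexion (the limb is
  nearly straight for most of swing), so high-damping differences are
  millimetres; with very small flexion the hip-to-toe distance is
  dominated by the terminal-extension pose, exactly as the in-vivo
  plateau suggests.
- The behavioural foot-placement rule is a model, not an observation;
  its three parameters move swing-duration and timing trends together
  and cannot be identified separately from the data the generator
  produces.
- The compensation metrics quantify prescribed offsets faithfully but
  say nothing about how a real user would deploy them.
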