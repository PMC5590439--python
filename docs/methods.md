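# Methods

## Model

`microsma` implements a three-dimensional phenomenological constitutive
model for NiTi shape-memory alloy built on microplane theory, evaluated at
a single material point under prescribed stress and temperature. The
macroscopic stress tensor σ is projected onto planes of every orientation
through the point. On a plane with unit normal **n** the traction σ·**n**
splits into a normal part σ_N = **n**·σ·**n** (projection tensor
N = **n**⊗**n**) and a resolved shear of magnitude σ_T along the in-plane
unit direction **t** (projection tensor T = (**n**⊗**t** + **t**⊗**n**)/2).
Macroscopic strain is recovered from the per-plane responses by the
complementary-virtual-work identity, which turns into integrals over the
unit sphere with the normalisation (3/4π)∫·dφ.

The strain splits additively, ε = ε^e + ε^tr:

* **Elastic part.**
  ε^e = −(ν/E(ξ)) tr(σ) I + ((1+ν)/E(ξ)) · (3/4π)∫ (σ_N N + σ_T T) dφ.
  The integrand collapses algebraically to sym(**n** ⊗ σ·**n**), a
  second-degree polynomial in **n**, so the integral equals σ exactly for
  any quadrature with exact second moments and the elastic response is
  isotropic Hooke behaviour with the mixture modulus
  E(ξ) = E_a + ξ (E_m − E_a).

* **Transformation part.**
  ε^tr = ε\* ξ · (3/4π)∫ T dφ, where ξ ∈ [0,1] is the martensite volume
  fraction and ε\* the maximum recoverable axial strain. Because each T is
  traceless, transformation is volume-preserving. Under uniaxial tension
  the continuum integral equals diag(−½, −½, 1): full transformation
  produces axial strain ε\* with isochoric lateral contraction.

* **Kinetics.** ξ evolves with cosine-shaped transformation kinetics in
  the Brinson (1993) form, driven by the von Mises effective stress σ̄
  (which reduces to √(σ² + 3τ²) for combined tension–torsion) and
  temperature. Forward transformation is active while σ̄ is non-decreasing
  inside the band [σ_s^cr + C_M(T − M_s), σ_f^cr + C_M(T − M_s)]; reverse
  transformation requires T > A_s and is active while σ̄ is non-increasing
  (or T rising at fixed σ̄) inside [C_A(T − A_f), C_A(T − A_s)]. Both
  cosine arguments are clamped to [0, π], which yields the saturation
  values (ξ = 1 above the forward finish, ξ = 0 below the reverse band at
  T ≥ A_f) and continuity at band entry.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| E_a, E_m | austenite / martensite modulus | 26 300 / 63 000 | MPa |
| M_f, M_s | martensite finish / start temperature | 9 / 18.4 | °C |
| A_s, A_f | austenite start / finish temperature | 29.3 / 37 | °C |
| C_M, C_A | forward / reverse Clausius–Clapeyron slope | 8 / 13.8 | MPa/°C |
| σ_s^cr, σ_f^cr | forward band start / finish at M_s | 100 / 170 | MPa |
| ε\* | maximum recoverable axial strain | 0.067 | – |
| ν | Poisson ratio | 0.33 | – |

The default set prints E_a < E_m (austenite softer than martensite),
which is the opposite of the usual NiTi convention; it is kept exactly as
calibrated and both moduli are plain config fields, so a user who believes
the labels are swapped can exchange them. ν is not part of the
calibration; 0.33 is a typical polycrystalline NiTi value, and every
result records the ν actually used. All temperatures are °C throughout.

## Numerical choices

**Sphere quadrature.** Production integrals use a 42-point symmetric
Gaussian rule of the Bazant–Oh family: 21 hemisphere directions (3 along
the axes, 6 edge bisectors, 12 of the form (a, ±b, ±b) and permutations)
plus their antipodes. Published tables of this rule are truncated to
~10 significant digits; the packaged table instead solves the defining
moment conditions (exactness through polynomial degree 7) to full machine
precision, so all second- and fourth-order tensor moments are reproduced
to 1e−15. Weights are normalised to Σw = 1 over the sphere, making the
(3/4π)∫·dφ ↔ 3Σw·f correspondence explicit. A Gauss–Legendre ×
midpoint-azimuth product grid (`dense_grid`, default 64×128) serves as a
brute-force oracle.

**Calibration of the transformation direction.** The unit shear field
T(**n**, σ) is not polynomial in **n** (it carries |·| and square-root
kinks where the resolved shear vanishes), so no small-point rule
integrates it exactly: the 42-point rule gives
3Σw |n₃|√(1−n₃²) = 0.94502 instead of the continuum value 1, and its
deviation from the dense-grid oracle on random triaxial stress states
reaches ~15 % in relative Frobenius norm. Left raw, this bias would make
full uniaxial transformation produce 0.945·ε\* instead of ε\*, breaking
the defining meaning of the calibration parameter. The discrete
transformation-direction tensor is therefore scaled by the scheme's
uniaxial calibration constant c = 1/(3Σw |n₃|√(1−n₃²)), computed once per
quadrature system, so the uniaxial continuum limit diag(−½, −½, 1) is
reproduced exactly. The calibration is a pure scale factor: it cannot
remove the state-dependent part of the quadrature error under strongly
multiaxial stress, which remains a known accuracy limit of the 42-point
rule (the dense grid at 64×128 resolves the same integrand to ~3e−4).

**Degenerate shear.** When the resolved shear magnitude is below
1e−9·max(|σ|, 1 MPa) the shear direction is undefined and its
contribution genuinely vanishes; **t** and T are set to zero.

**Zero-stress transformation direction.** At exactly zero stress with
residual martensite (stress-free thermal recovery) the direction tensor
is undefined; the driver freezes it from the last non-zero-stress step,
which keeps the recovery path continuous.

**Event bookkeeping.** The loading direction is the sign of Δσ̄ between
consecutive steps; a tie (Δσ̄ = 0) is neutral unless T rises, which counts
as reverse driving (this is what drives stress-free thermal recovery).
ξ₀ is frozen when an event first activates and re-frozen on every mode
switch; within an event ξ is kept monotone (non-decreasing forward,
non-increasing reverse). Re-entering the forward band mid-band after a
partial unload re-anchors the cosine at the current ξ, which is
event-local and can differ from the value a never-interrupted loading
would give at the same σ̄ — inherent to cosine kinetics of this family and
irrelevant to the monotone load–unload programs studied here.

**Mixture modulus convention.** E(ξ) inside the elastic strain uses the
post-update ξ of the current step (quasi-static consistency; alternative
conventions differ at order Δσ̄).

**Discretisation.** 200 interpolation steps per load segment by default.
The kinetics are driven by the current (σ̄, T) state rather than by
increments, so results converge fast in step count; doubling the steps
moves final strains by far less than 1e−4 on all shipped scenarios. The
test suite and the acceptance script use 100–200 steps per segment, small
enough that the whole suite runs in seconds.

## Load programs and the cross-section surrogate

The shipped scenarios mirror implant-scale studies: load–unload tension
above A_f (pseudoelasticity), proportional tension–torsion above A_f and
between M_s and A_s (shape-memory effect), stress-free heating recovery,
and one-factor-at-a-time sweeps of force, torque or temperature.
Applied force F (N) and torque M (N·mm) become material-point stresses
through a reference cross-section surrogate: σ = F/area,
τ = M·shear_factor. The defaults (area 0.25 mm², shear factor 1.28 mm⁻³)
are chosen so the combined amplitude 50 N + 75 N·mm at 38 °C drives σ̄
just past the forward onset at that temperature; they stand in for a real
device geometry, whose stress concentration cannot be reduced to a single
cross-section, and preserve the transformation regimes rather than any
field magnitudes. Combined loads are ramped proportionally; sweeps run as
independent paths from fresh austenite.

Because the model is evaluated at one material point, quantities named
after finite-element field reports (peak von Mises stress, maximum
principal strain) are the point-wise values along the load path, not
maxima over a structure. Passing tests therefore demonstrate the
constitutive behaviour — hysteresis, closure, recovery, onset, trends —
not the stress redistribution of any particular implant geometry.

## Known limitations

* Only stress-induced (detwinned) martensite is tracked; the model is
  restricted to T ≥ M_s and has no twinned-martensite branch.
* Quasi-static and isothermal per step: no rate effects, latent-heat
  self-heating or cyclic degradation.
* No tension–compression asymmetry; the effective stress is symmetric in
  sign.
* Stress-driven only: strain-controlled loading would need an inverse
  solve that is deliberately not provided.
* The 42-point rule's accuracy on the transformation-direction integral
  under strongly multiaxial stress is limited as quantified above; the
  dense grid is available (`quadrature.scheme = "dense_grid"`) when that
  matters more than speed.
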