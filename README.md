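# microsma

A material-point simulator for NiTi (Nitinol) shape-memory alloy based on
microplane theory. It reproduces the two behaviours that make NiTi the
material of choice for self-expanding biomedical implants:

* **Pseudoelasticity** — above the austenite-finish temperature A_f,
  stress-induced martensite reverts on unloading, giving a closed
  stress–strain hysteresis loop with zero residual strain.
* **Shape-memory effect (SME)** — between M_s and A_s, stress-induced
  martensite persists after unloading; the residual strain is recovered
  by heating above A_f.

The intended users are engineers and researchers who need the
constitutive response of an SMA device material under combined
tension–torsion–temperature programs — hysteresis loops, residual
strains, transformation onsets, parameter sweeps — without running a
finite-element model.

## Model

Macroscopic stress σ is projected onto microplanes with unit normals
**n** covering the unit sphere. With N = **n**⊗**n**,
σ_N = N : σ, and T = (**n**⊗**t** + **t**⊗**n**)/2 built from the
in-plane traction direction **t**, the strain is assembled as
ε = ε^e + ε^tr with

    ε^e  = −(ν/E(ξ)) tr(σ) I + ((1+ν)/E(ξ)) · (3/4π) ∫ (σ_N N + σ_T T) dφ
    ε^tr = ε* · ξ(σ̄, T) · (3/4π) ∫ T dφ

where E(ξ) = E_a + ξ(E_m − E_a) is the mixture modulus and
σ̄ = √(σ² + 3τ²) the von Mises effective stress that drives the
martensite volume fraction ξ through cosine-shaped (Brinson-type)
transformation kinetics with hysteresis memory. Sphere integrals are
evaluated with a 42-point symmetric Gaussian rule (Bazant–Oh family);
see `docs/methods.md` for the quadrature and calibration details.

## Worked example

Sweep the tensile force at fixed torque (75 N·mm) and temperature
(38 °C), the combined-loading study:

```sh
microsma --log-level WARNING sweep --name tension_torsion \
    --temp 38 --torque 75 --force 30 --force 40 --force 50 --out sweep.csv
```

prints

```
 force_N  torque_Nmm  temperature_C  peak_vm_MPa  max_principal_strain  residual_strain  loop_area_MPa
    30.0        75.0           38.0   205.056090              0.007253              0.0   1.782428e-16
    40.0        75.0           38.0   230.755282              0.008357              0.0  -1.214306e-17
    50.0        75.0           38.0   260.092291              0.009863              0.0   6.539692e-02
```

Reading the rows: with the default cross-section surrogate the 30 N and
40 N cases stay below the forward transformation onset at 38 °C
(σ̄ = 256.8 MPa), so they respond elastically — zero residual strain and
loop area at round-off level. At 50 N the effective stress just crosses
the onset (260.1 MPa peak von Mises), a small amount of martensite forms
and reverts on unloading, and the hysteresis loop opens
(loop area 0.065 MPa of dissipated work per unit volume). Because 38 °C
is above A_f = 37 °C the loop still closes: residual strain is zero.

Other entry points: `microsma run config.json` executes a full JSON/YAML
config (a packaged example lives at `src/microsma/data/default_config.json`),
`microsma scenario` runs one named load case, and `microsma validate`
runs the built-in oracle suite (quadrature identities, uniaxial closed
form, loop closure, SME recovery). The same functionality is available
as a library:

```python
import microsma as m

params = m.default_niti()
system = m.build_microplane_system()
path = m.LoadPath(segments=[
    (m.StressPoint.uniaxial(550.0, 60.0), 200),   # load to 550 MPa at 60 degC
    (m.StressPoint.uniaxial(0.0, 60.0), 200),     # unload
])
result = m.run_path(path, params, system)
print(result.steps[-1].eps_total)                 # ~0: pseudoelastic closure
```

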