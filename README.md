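# luxfer

Enzymology-style characterization of inducible genetic-device transfer
functions, with the LuxR/3OC6HSL quorum-sensing system as the worked
example.

## The problem

Synthetic-biology devices are routinely characterized by fitting a Hill
curve to their dose–response (transfer function). The fit describes the
data but carries no mechanism: change one part of the device — say the
ribosome-binding site (RBS) driving the receptor — and the fitted
parameters tell you nothing about what the new curve will look like.

`luxfer` implements the alternative: an equilibrium-binding model of the
device, in the style of Michaelis–Menten enzymology, whose parameters are
explicit functions of the tunable parts. For a device in which a receptor
R dimerizes (R₂, with dimerization constant K₀), the dimer binds one
inducer molecule L (Q = R₂·L, association constant K₁), and either the
free dimer (K₂) or the ligand-bound dimer (K₃) occupies the promoter, the
steady-state reporter output is the three-parameter hyperbola

    G*(L) = a₁ (a₂ + L) / (a₃ + L)

with basal output G₀ = a₁a₂/a₃, maximal output G_m = a₁ and turning point
L₀.₅ = a₃ − 2a₂. Writing the total dimer pool as r′·ϕ, linear in the
normalized RBS strength ϕ, the coefficients become closed-form functions
of ϕ:

    a₁ = V₀ (1 + ε_L K₃r′ϕ) / (1 + K₃r′ϕ)
    a₂ = K₁⁻¹ (1 + ε_R K₂r′ϕ) / (1 + ε_L K₃r′ϕ)
    a₃ = K₁⁻¹ (1 + K₂r′ϕ) / (1 + K₃r′ϕ)

where V₀ is the naked-promoter leak and ε_R, ε_L are the transcription
rates of the two occupied promoter states relative to the naked one. In
the leak-free limit this reduces to a Michaelis–Menten form with apparent
parameters G_m^app(ϕ) = V·ϕ/((K₃r′)⁻¹ + ϕ) and
K^app(ϕ) = K₁⁻¹/(1 + K₃r′ϕ): a stronger receptor RBS raises the
amplitude saturably and lowers the half-maximal inducer concentration as
ϕ⁻¹. A free-exponent Hill fit of any such device must return n = 1 — the
model explains the noncooperativity observed for Lux-type receptors
activated by a single lactone molecule.

## What is in the package

- `luxfer.equilibrium_model` — the closed forms above, a numerical
  mass-action equilibrium solver with exact conservation (an independent
  oracle for the closed forms), and the mRNA/protein kinetics under
  quasi-equilibrium binding.
- `luxfer.steady_state` — plate-reader processing: per-cell output
  Θ = (f_S − f_B)/(OD_S − OD_B), per-time normalization, the moving-window
  coefficient-of-variation statistic S, its across-condition spread α,
  and the data-driven steady-state acquisition time.
- `luxfer.fitting` — bounded trust-region least squares for the Hill
  form and the leaky hyperbola, plus a joint fit of one shared mechanistic
  parameter set across constructs differing only in ϕ.
- `luxfer.synthetic_data` — a virtual plate reader reproducing the
  characterization design (zero + 8 inducer levels spanning 10⁻¹⁰–10⁻⁴ M,
  readings every 10 min for 14 h, 6 replicates, strong/medium/weak RBS
  constructs) with an invertible signal model and exported ground truth.
- `luxfer.io` / `luxfer.cli` — delimited-text formats, unit-checked YAML
  configuration, and the `luxfer` command
  (`simulate`, `theta`, `steady-state`, `fit-hill`, `fit-leaky`,
  `fit-mechanistic`, `predict`, `run-all`).

## Worked example

Simulate the characterization of the medium-RBS construct (ϕ = 0.3),
process it through the Θ/steady-state pipeline, and fit both forms:

```python
from luxfer import (ExperimentDesign, simulate_plate, compute_theta,
                    steady_state_report, fit_hill, fit_leaky)
from luxfer.steady_state import transfer_curve_at

design = ExperimentDesign(constructs=[("medium", 0.3)], seed=42)
run = simulate_plate(design)
tm = compute_theta(run.plates["medium"])
report = steady_state_report(tm, on_unsettled="endpoint")
tc = transfer_curve_at(tm, 840.0, construct="medium", phi=0.3)
hill, leaky = fit_hill(tc), fit_leaky(tc)
```

Output (seed 42):

```
acquisition time: 50 min (alpha threshold 0.4)
Hill:  a=722  b=3.91e+04  K05=2.39e-08 M  n=1.08  r2=0.998
Leaky: a1=4e+04  a2=2.83e-10 M  a3=2.36e-08 M  r2=0.998
       G0=479  L05=2.3e-08 M
```

The Hill exponent comes out ≈ 1 (the device is noncooperative by
construction), K₀.₅ matches the hyperbola's affinity constant a₃, and the
leaky fit recovers the generator's true parameters
(a₁ = 4.0×10⁴, a₂ = 4.0×10⁻¹⁰ M, a₃ = 2.6×10⁻⁸ M) to within the noise of
a single six-replicate experiment. The early acquisition time reflects
that the *normalized* transfer curve stabilizes long before the raw
signal saturates: all conditions share the same expression kinetics.

The same pipeline from the shell:

```sh
luxfer run-all --config examples/run.yaml --out results/
```

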