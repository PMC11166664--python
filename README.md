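# sacflow

Finite-element simulation of blood-based gold/silver hybrid-nanofluid flow
and heat transport in an artery carrying a **ruptured sidewall aneurysm**.

When an aneurysmal sac on an artery wall ruptures at its apex, blood leaks
through the orifice and the pressure and velocity fields around the sac
reorganize.  One proposed intervention disperses gold and silver
nanoparticles in the blood, which stiffens the effective suspension
(raising μ) and raises its thermal conductivity.  `sacflow` provides a
tested, reusable desk-scale model of this setting for computational
hemodynamics work: a 2D cut of a straight vessel (0.7 m × 0.09 m) with a
circular-arc sac and an apex orifice, transient incompressible Navier–Stokes
flow, and one-way coupled heat transport — everything verified against
closed-form limits.

## Model

Effective suspension properties at volume fractions φ₁ (Au), φ₂ (Ag):

- ρ_hnf = (1−φ₂)[(1−φ₁)ρ_f + φ₁ρ_s1] + φ₂ρ_s2 (likewise (ρC_p)_hnf),
- μ_hnf = μ_f /[(1−φ₁)^2.5 (1−φ₂)^2.5]  (two-step Brinkman),
- k_hnf by the Maxwell dilute-sphere law applied twice (Au into blood, then
  Ag into the intermediate nanofluid).

Flow: ρ_hnf(∂v/∂t + v·∇v) = ∇·[−pI + μ_hnf(∇v+∇vᵀ)], ∇·v = 0, with no-slip
walls, inlet speed v₀, traction outlets −p̄n (p̄ = 13,000 Pa at the outlet,
12,990 Pa at the orifice) with backflow suppression.  Heat:
(ρC_p)_hnf(∂T/∂t + v·∇T) = k_hnf∇²T + μ_hnf Φ with insulated borders and a
310 K inlet.  Discretization: Taylor–Hood P2/P1 triangles, BDF2 in time,
Newton-augmented Picard per step; P1 + SUPG temperature.  An axisymmetric
r–z mode (with the 1/r metric terms) serves straight-tube verification.

## Worked example

```python
from sacflow import builtin_scenarios, run_scenario, compare_extremes

report = run_scenario(builtin_scenarios()["paper_rupture"])
print(report.mesh_stats["n_elements"])          # 1775
print(report.extremes_domain.frame.to_string(index=False))
```

```
  t    v_max  v_min        p_max        p_min      T_max  T_min
0.0 0.000000    0.0 13000.000000 13000.000000 310.000000  310.0
0.4 0.205685    0.0 13021.276436 12984.474522 310.000002  310.0
0.8 0.149106    0.0 13013.631433 12986.848179 310.000001  310.0
1.2 0.144265    0.0 13011.432541 12988.268125 310.000002  310.0
2.4 0.133606    0.0 13011.024672 12988.663898 310.000003  310.0
```

Reading the table: speed peaks in the jet through the rupture orifice during
the impulsive start (0.21 m/s at 0.4 s) and relaxes as the flow organizes;
the pressure field stays pinned between the orifice (12,990 Pa) and outlet
(13,000 Pa) levels plus dynamic excursions of a few tens of pascal; viscous
heating at these scales is ~10⁻⁶ K, so the temperature field remains at the
310 K inlet level throughout — matching the near-constant reported
temperature contours.  `compare_extremes(report.extremes_line)` reports
signed relative deviations of the midline extremes from the bundled
reference table (velocity maxima agree within 0.3–9% at the default,
package-chosen inflow calibration).

A CLI wraps the same pipeline:

```bash
sacflow run --scenario paper_rupture --outdir out/   # VTK + CSV + logs
sacflow verify                                        # closed-form checks
sacflow compare                                       # deviations vs reference
sacflow mesh-only --out vessel.msh
```

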