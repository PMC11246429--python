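# nmrbind

Quantitative NMR-titration analysis of binding between long intrinsically
disordered regions (IDRs) and folded partner proteins.

Disordered adaptor proteins — the clathrin-associated sorting proteins of
endocytosis are the motivating case — bind their folded partners through
many weak short linear motifs (DLL/DLF, DPF, FxDxF) and, occasionally,
through extended multi-residue sites with far higher affinity.  NMR makes
these interactions visible residue by residue: peaks shift, broaden and gain
relaxation as each site samples its bound state.  `nmrbind` turns those
per-residue observables into affinities and kinetics:

* **Chemical-shift perturbations** between titration points,
  CSP = √((Δδ¹H·6.5)² + (Δδ¹⁵N)²), and intensity ratios I/I₀ with explicit
  bookkeeping of peaks broadened beyond detection.
* **Residue-wise K_D from fast-exchange R₁ρ rates.**  Under weak binding the
  rotating-frame rate is linear in the partner concentration,
  R₁ρ = [B]/(K_D+[A])·(R₁ρᴮ−R₁ρᴬ) + R₁ρᴬ, so a weighted linear fit of rates
  against [B] inverts to a per-residue dissociation constant, with
  Monte-Carlo percentile intervals.
* **Global two-state CPMG exchange fitting.**  Constant-time relaxation
  dispersion profiles R₂ᵉᶠᶠ(ν_CPMG) from all dispersing residues and all
  static fields are fit together under two-state exchange (shared k_ex and
  bound population p_B, per-residue |Δω|, per-residue-per-field R₂⁰).  The
  fit kernel is an exact closed-form solution of the two-state CPMG
  propagator, validated to < 0.1 s⁻¹ against explicit Bloch–McConnell
  propagation; K_D, k_on and k_off follow from p_B and the sample
  composition under 1:1 stoichiometry (k_ex = k_on[B]free + k_off).
* **1:1 ITC fitting** (Wiseman isotherm with displaced-volume dilution
  bookkeeping) for the independent calorimetric affinity.
* **Secondary chemical shifts and secondary-structure propensities**
  (SSP ∈ [−1, 1], strand to helix) from Cα/Cβ shifts against a bundled
  random-coil reference.
* **Motif scanning and interaction-window logos:** SLiM patterns, 21-residue
  windows centred on the hydrophobic residue with the highest rate increase,
  ranking by central rate, and position-frequency matrices.
* **Seeded synthetic-data generators** for every input above, with ground
  truth recorded next to the data, so the whole pipeline is testable end to
  end.

## Worked example

Generate a study-scale dispersion experiment (22 residues, 600 and 850 MHz,
14 CPMG frequencies between 31.25 and 1000 Hz at 32 ms constant time,
0.5 s⁻¹ noise) and recover the exchange parameters:

```python
import numpy as np
from nmrbind.synth import gen_dispersion
from nmrbind.cpmg import global_fit

rng = np.random.default_rng(42)
residues = list(range(435, 457))
dw_map = {r: float(rng.uniform(1.0, 4.0)) for r in residues}
table, truth = gen_dispersion(residues, dw_map, k_ex=662.0, p_b=0.089,
                              fields_mhz=(600.0, 850.0), noise_sd=0.5, seed=42)
fit = global_fit(table, seed=42)
print(f"k_ex = {fit.k_ex:.0f} +/- {fit.k_ex_error:.0f} s-1")
print(f"p_B  = {100*fit.p_b:.2f} +/- {100*fit.p_b_error:.2f} %")
binding = fit.derive_binding(a_total=100.0, b_total=10.0)
print(f"K_D  = {binding.kd:.1f} uM   k_off = {binding.k_off:.0f} s-1   "
      f"k_on = {binding.k_on_per_molar:.2e} M-1 s-1")
```

prints

```
k_ex = 663 +/- 4 s-1
p_B  = 8.88 +/- 0.03 %
K_D  = 11.4 uM   k_off = 605 s-1   k_on = 5.28e+07 M-1 s-1
```

k_ex and p_B are the shared two-state exchange rate and bound population;
the derived K_D is the 1:1 dissociation constant implied by p_B at 100 µM
observed protein and 10 µM partner, and k_off = (1−p_B)·k_ex is the
complex lifetime⁻¹.  Recovery is within noise of the generating truth
(662 s⁻¹, 8.9 %).

The same workflow is available from the shell:

```bash
nmrbind simulate --config config.yaml --out data/
nmrbind fit cpmg --data data/ --config config.yaml --out results/
nmrbind report results/
```

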