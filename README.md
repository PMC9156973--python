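# polopulse

Models and a measurement pipeline for the centriolar Polo/PLK1 activity
pulse that initiates mitotic centrosome maturation.

In syncytial *Drosophila* embryos, mother centrioles recruit a
pericentriolar-material (PCM) scaffold of Spd-2 and Cnn before each mitosis.
Centrosomal Polo kinase rises and falls *first*, Spd-2 pulses after it, and
the Cnn scaffold keeps growing and plateaus even as Polo and Spd-2 decline
before nuclear envelope breakdown. `polopulse` is for quantitative cell
biologists and modellers who want to simulate, perturb and measure these
dynamics:

- **Scaffold-assembly model** — a well-mixed mass-action network in which a
  centriolar active-Polo drive converts receptor-bound Spd-2 into a weak
  scaffold S\*, stabilised by cytoplasmic Polo and Cnn into S̄ (1:1:1),
  which catalytically converts Cnn into its own scaffold C\*:
  S + RS ⇌ R̄S →(P\*) S\* ⇌ S̄ → S\* + C\*, with size-dependent C\*
  disassembly at per-unit rate k_dephos_C + γ_C·C\*. Observed totals:
  total Polo = drive + S̄, total Spd-2 = S\* + S̄, total Cnn = S̄ + C\*.
- **Pulse generator** — a delayed negative feedback loop at the centriole:
  an inactive Polo receptor (Ana1-like) is activated (k_R_on, the handle of
  the cell-cycle oscillator), loads cytoplasmic Polo (R̄P), and is then
  inactivated by the locally active Polo it created, at rate
  k_inh·R̄P·(R̄P + S̄), sequestering its bound Polo until a mitotic reset.
  Coupling R̄P(t) into the scaffold model as drive reproduces the imposed-
  pulse dynamics.
- **In-silico genetics** — the two-cycle simulation protocol, half-dose
  backgrounds (halve S_tot or the receptor pool RP_tot),
  recruitment-mutant analogues, a 2-fold robustness scan of all 13 reaction
  rates, and a 0.5–2× parameter sweep of wild-type vs half-dose Polo-pulse
  metrics.
- **Track pipeline** — pulse features (initial/maximum intensity, growth
  period and rate = (max − initial)/period), piecewise-linear Cnn
  growth-curve selection (linear / plateau / decrease, AICc), old-mother vs
  new-mother pairing, growth-period vs S-phase-length correlation (Pearson,
  regression, Henze–Zirkler normality check), and single-exponential FRAP
  recovery fits I(t) = b + A(1 − e^(−kt)) with Welch-ANOVA cross-cycle
  comparisons.
- **Synthetic data** — seeded generators for embryo track cohorts, OM/NM
  pairs and FRAP series with known ground truth, so every pipeline stage is
  testable end to end.

## Worked example

Compare the centrosomal Polo pulse in a wild-type and an Ana1 half-dose
embryo over the second of two modelled nuclear cycles:

```python
from polopulse import default_parameters, halve_pool, polo_metrics, run_two_cycle

p = default_parameters()
wt = polo_metrics(run_two_cycle(p, mode="coupled"))
half = polo_metrics(run_two_cycle(halve_pool(p, "ana1"), mode="coupled"))
print({k: round(v, 3) for k, v in wt.items()})
print({k: round(v, 3) for k, v in half.items()})
```

prints

```
{'peak_amount': 0.448, 'peak_time': 2.0, 'final_amount': 0.141}
{'peak_amount': 0.358, 'peak_time': 3.0, 'final_amount': 0.169}
```

Halving the centriolar Polo receptor pool lowers the pulse peak (0.358 vs
0.448 a.u.) and delays it (3.0 vs 2.0 min into the cycle) — fewer receptors
recruit Polo more slowly — but because those receptors are also inactivated
more slowly, the half-dose centrosome ends S-phase holding *more* Polo
(0.169 vs 0.141 a.u., a ratio of 1.20). The same counter-intuitive
directionality holds at every point of the 0.5–2× sweep of all 13 reaction
rates (`polopulse.dose_sweep`).

The same analyses are scriptable from the shell:

```sh
polopulse twocycle --mode coupled --out cycle2.tsv
polopulse halfdose --component ana1 --out halfdose.tsv
polopulse synth --kind cohort --n 15 --seed 1 --out cohort.tsv
polopulse features cohort.tsv --out features.tsv
```

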