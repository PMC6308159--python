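# ecfctox

Donor-variability analysis of cytotoxic concentration-response in clonal
endothelial colony-forming cells (ECFCs).

Cord-blood ECFC clones offer a cell-based way to ask whether people differ
in their sensitivity to environmental toxicants: clones from several donors
are exposed in 384-well viability assays to paired toxic/nontoxic chemicals
(CdCl₂/ZnCl₂, NaAsO₂/Na₂HAsO₄, TBT/SnCl₂, menadione/phytonadione) over
two-fold serial dilutions, in duplicate wells, on repeated days. The
scientific question is one of variance attribution: how much of the
variation in inhibitory concentrations is between donors (biology of
interest), between clones of the same donor, and between days (technical
noise)? This package implements that full analysis as a tested pipeline,
together with a synthetic-data generator that emulates the study design
with known ground truth, so every stage is verifiable without raw plate
data.

## The model

Viability is analyzed on the transformed concentration scale
t = log₂(1 + μM). Each clone × chemical × day profile
x_j = y(t_j) + ε_j, j = 1…J, is fit with the monotone functional model

    y(t) = 100 / (1 + ∫₀ᵗ exp(Σₖ cₖ bₖ(s)) ds)

where b₁…b_K are K = 20 cubic B-spline basis functions. The positive
integrand makes y decrease strictly from 100 toward 0 by construction. The
coefficients minimize the penalized sum of squared errors

    PENSSE(y|x) = Σⱼ {x_j − y(t_j)}² + λ·PEN(y),
    PEN(y) = ∫ {Σₖ cₖ bₖ″(t)}² dt,   λ = 0.01,

by Newton–Raphson with a backtracking line search. Inhibitory
concentrations invert the fitted curve on a 300-point grid over [0, T]
(T = 1.02 × the top tested concentration) by linear interpolation, with
ICxx = 2^t̂ − 1 μM at viability 100 − xx.

Two inferential layers sit on top:

- **Day-to-day reproducibility** — a functional ANOVA
  Y_ij(t) = μ(t) + α_i(t) + β_j(t) + ε_ij(t) (toxicant i, day j,
  α₁ = β₁ = 0), fit pointwise by least squares; the global day effect is
  the max over t > 0 of |β̂_j(t)|/SE(t), calibrated by permuting days
  within each toxicant (B = 1,000).
- **Variance partition** — per chemical and IC level, the per-day IC
  values are decomposed into between-donor, between-clone-within-donor and
  within-clone (day-to-day) sums of squares by the sequential nested
  linear-model decomposition, reported as percent of total.

## Worked example

The package bundles the study's published per-clone IC summaries
(`ecfctox.datasets`). Recomputing the cross-clone toxicity ranking
(`python analysis/07_reference_summaries.py`) prints:

```
cross-clone IC10 ranking (mean ± SD over 8 clones, uM):
  TBT         0.31 ± 0.11
  NaAsO2      2.40 ± 1.16
  CdCl2       6.65 ± 1.85
  Menadione  11.55 ± 5.03
menadione donor share by IC level: IC10: 43.3%, IC20: 50.6%, ... IC80: 74.6%, IC90: 71.7%
```

TBT is the most potent chemical (a 10% viability loss already at ~0.3 μM)
and menadione the least, but menadione is the one chemical whose variance
partition is dominated by the **between-donor** share (43% at IC10, rising
above 70% at deep effect levels) — the signature of genuine
donor-to-donor differences in sensitivity rather than technical noise.

Running the same machinery end-to-end on a synthetic study
(`python analysis/01_simulate_study.py` … `06_day_effect_fanova.py`)
generates 4,224 wells, normalizes them into 192 profiles, fits 192 curves
(all converged), and prints, for example:

```
cross-clone IC10 mean ± SD (uM), toxic chemicals:
  CdCl2        5.67 ± 1.07 (n = 8 clones)
  NaAsO2       1.93 ± 0.24 (n = 8 clones)
  TBT          0.22 ± 0.06 (n = 8 clones)
  Menadione    9.71 ± 1.25 (n = 8 clones)
nontoxic counterparts with a defined IC: 11 of 864 chemical/level/day cells
```

consistent with the generator's ground truth (IC50 locations at 15, 7,
1.7 and 17 μM with donor/clone/day shifts) and with the design intent that
nontoxic counterparts essentially never reach a 10% viability loss.

A CLI mirrors the stages: `ecfctox simulate | normalize | fit | ic |
varpart | fanova | report | run`.

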