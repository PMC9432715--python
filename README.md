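# cryptcomp

Niche competition in colonic crypts as a model of age-specific cancer
incidence.

`cryptcomp` is for biostatisticians and modellers of multistage
carcinogenesis who want a minimal, fully testable pipeline from a
stem-cell-level stochastic model to registry-scale incidence curves.  It
implements a Moran-process model of the earliest phase of the
adenoma–adenocarcinoma sequence, lifts it to tissue-level survival and
hazard, calibrates its single free parameter against age-specific incidence
tables, and ships a synthetic-data generator so that every stage can be
validated without access to a cancer registry.

## The model

A colonic crypt niche holds a fixed number *N* of stem cells (a Moran
process: every replacement keeps the population size constant).  Replacement
events occur at rate λ per stem cell per year; at each event a dividing
cell's daughter replaces a competitor — any other cell (well-mixed limit)
or a ring neighbour (one-dimensional limit).  During division a wild-type
daughter mutates to a benign tumor cell with probability *u*, and a benign
daughter to a malignant cell with probability *v*.  Two absorbing outcomes
exist per crypt:

- **adenoma** — benign cells fixate (clonal conversion), probability
  *P*<sub>a</sub>(*t*) by age *t*; the adenoma later progresses to an
  adenocarcinoma with probability γ (*sequential* pathway);
- **carcinoma** — a malignant daughter arises before fixation and, with its
  strong proliferative advantage, takes the niche immediately
  (*stochastic tunneling*), probability *P*<sub>c</sub>(*t*).

With *K* independent crypts in the colon, the probability of remaining
cancer-free and the age-specific incidence rate (hazard) are

    S(t) = (1 − P_c(t) − γ P_a(t))^K ,   R(t) = − d/dt ln S(t) ,

and R(t) splits into tunneling and sequential parts,
−d/dt ln(1 − P_c)^K and −d/dt ln(1 − γP_a)^K, whose crossover age marks the
switch from de-novo-dominated early incidence to polyp-dominated incidence.
Five parameters (N, K, u, v, γ) are fixed from physiological measurements;
only the effective replacement rate λ is fitted to incidence data by
χ² minimization.

## Worked example

```python
import numpy as np
from cryptcomp import (
    build_generator, default_time_grid, exemplary_tissue,
    lifetime_fractions, solve_absorption, survival_and_hazard,
)

tissue = exemplary_tissue("colon")   # N=8, K=2e7, u=7.13e-6, v=1.75e-6,
                                     # gamma=9.4%, lambda=0.016 /y
curves = solve_absorption(build_generator(tissue.niche), default_time_grid())
hz = survival_and_hazard(curves, tissue)        # rates per 100,000 person-years
seq, benign = lifetime_fractions(curves, tissue, T=85.0)

print(f"R(42.5) = {np.interp(42.5, hz.t, hz.R):.1f} per 100,000 person-years")
print(f"R(82.5) = {np.interp(82.5, hz.t, hz.R):.1f} per 100,000 person-years")
print(f"pathway crossover at {hz.crossover_age:.1f} years")
print(f"sequential-pathway fraction at 85 y: {100*seq:.1f}%")
print(f"benign-tumor fraction at 85 y:       {100*benign:.1f}%")
```

prints

```
R(42.5) = 13.1 per 100,000 person-years
R(82.5) = 260.6 per 100,000 person-years
pathway crossover at 29.7 years
sequential-pathway fraction at 85 y: 96.1%
benign-tumor fraction at 85 y:       99.6%
```

i.e. at this parameter set the model predicts colon-cancer incidence rising
by a factor ~20 between ages 42.5 and 82.5, tunneling progression dominating
before age ~30, and — over a lifetime — 96% of cancers arising through a
precursor adenoma while >99% of all tumors remain benign, consistent with
clinical estimates (>95% and >99%).

Fitting and scanning work on any table in the documented CSV schema
(`cancer_site,age_lo,age_hi,count,person_years,rate_per_100k`); a synthetic
SEER-like table can stand in:

```sh
cryptcomp generate --preset colon --noise poisson --seed 1 -o synth.csv
cryptcomp fit --preset colon --data synth.csv
cryptcomp scan --preset colon --data synth.csv      # 891-fit ensemble
cryptcomp decompose --preset colon -o hazard.tsv
```

Users with a real registry extract (e.g. SEER 2013–2017 colon rates) apply
the screening adjustment before fitting:
`cryptcomp fit --data seer_colon.csv --adjust-factor 1.3333`
(rates above age 55 increased by 4/3 to compensate for incidence removed by
colonoscopy screening).  Reference fitted rates for such extracts are
λ ≈ 0.016 /y (colon exemplar; ensemble 0.024±0.01), 0.014 (gastric) and
0.05 (rectum).

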