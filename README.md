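# trackevent

Track-event / RAMN cell-survival models and nanodosimetric
track-structure scoring.

`trackevent` is a Python package for radiobiological modellers working
on the link between particle track structure and cell survival. It
implements, as tested reusable components, the machinery of the
track-event family of survival models: closed-form dose–response
functions, the exact compound-Poisson statistics of lethal/sublethal
event counts, impact-parameter (annulus) fluence averaging of
ionization-cluster probabilities, two-pass FCC Wigner–Seitz lattice
scoring of ionization clusters in track point clouds, and the
conversion of ionization clusters to DNA double-strand-break (DSB)
statistics. Seeded synthetic generators of correlated track-like point
clouds and an uncorrelated ionization gas make every stage testable
without external simulation data.

## The model in brief

A cell is hit by a Poisson number of tracks with mean `n_t(D)`; each
track independently produces a nonlethal, sublethal or lethal event
with probabilities `p0`, `p1`, `p2+`. Survival requires no lethal
event and at most one sublethal event, giving

    S = (1 + n_t p1) exp(-n_t (p1 + p2+)) = (1 + qD) exp(-(p+q)D)

with `p = n_t p2+/D` and `q = n_t p1/D`. The RAMN parameterisation
replaces per-cell with per-cluster-volume probabilities
(`S = (1 + N n_t p_SL) exp(-N n_t (p_SL + p_CL))`); repair variants
rescue cells with exactly one (potentially) lethal event or exactly two
sublethal events with probability `R`:

    S = (1 + qD + R [p'D + (qD)^2 / 2]) exp(-(p+q)D)

and a threshold variant repairs all damage with probability `R`
whenever more than one DSB is present (`S' = S0 + R(1 - S0)`). The
event probabilities themselves derive from nanodosimetry: fluence
averages over the impact parameter of conditional ionization-cluster
probabilities, scored on BIV-sized (2–3 nm) and CV-sized (7.5–18 nm)
Wigner–Seitz cells of an FCC lattice, with the cluster-to-DSB
conversion `P(DSB|IC) = (1/F2) Σ_{k≥2} F_k / 2^(k-1)` for cumulative
cluster-size probabilities `F_k`. See `docs/methods.md` for the full
account of models, parameters and numerical choices.

## Worked example

```python
from trackevent import (
    SurvivalParameters, survival_basic, survival_repair_consistent,
    EventProbabilities, poisson_mixture, survival_from_track_probs,
    parametric_f2_profile, annulus_grid, annulus_contributions,
)

# survival at 2 Gy for p = 0.05 /Gy (lethal), q = 0.9 /Gy (sublethal)
p = SurvivalParameters(p=0.05, q=0.9, dose=2.0, repair=0.4)
print(survival_basic(p))              # 0.4187921338233781
print(survival_repair_consistent(p))  # 0.521695343848551

# the same survival read off the multi-event count distribution:
# P(0,0) + P(1,0) for Poisson(2) tracks with p1 = 0.2, p2+ = 0.05
d = poisson_mixture(2.0, EventProbabilities(p1=0.2, p2plus=0.05))
print(d.masses[0, 0] + d.masses[1, 0])          # 0.8491429235974897
print(survival_from_track_probs(2.0, 0.2, 0.05))  # 0.8491429235976867

# how much of the cluster probability comes from non-traversing tracks:
# a plateau + power-law impact-parameter profile on 40 annuli of 1.5 nm
prof = parametric_f2_profile(0.1, 1.5, 1.2, 60.0)
rel, cum = annulus_contributions(prof, annulus_grid(1.5, 40))
print(rel[0], cum[9])  # 0.0216, 0.3082
```

The first two numbers show repair lifting 2 Gy survival from 0.419 to
0.522. The count-distribution read-off agrees with the closed form to
ten decimals — the survival formula is exactly the mass of the
"at most one sublethal, no lethal" cells of the compound-Poisson
distribution. The annulus decomposition shows that for a slowly
decaying profile only ~2% of the total cluster probability comes from
tracks traversing the target; the first ten annuli together carry only
~31%, so truncating the impact parameter too early badly
underestimates the fluence average.

A command-line interface covers the standard runs, e.g.

    trackevent simulate-tracks --model dense --n 50 --seed 1 --out tracks.tsv
    trackevent score --tracks tracks.tsv --dbiv 2.0 --dcv 12 --roi 250 --out single.tsv
    trackevent survival-curve --model basic --params params.yaml --doses 0:10:0.5
    trackevent run --config run.yaml

All tables are headered TSV; `run` writes pmf tables, independence
ratios, Poisson references, a survival read-off and a JSON manifest
that makes reruns bit-identical.

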