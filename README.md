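# maskflow

A semi-analytical flow-network model of the face–mask interface. The
space between a rectangular cloth mask (9 in × 5.4 in, tuck-in ratio τ)
and the face is represented as a network of variable-height channels
with a solid bottom wall (the face) and a Darcy-porous top wall (the
fabric), fed by a central high-pressure cavity. Each channel is reduced
to a second-order ODE for its flux amplitude with a Kármán–Pohlhausen
momentum-integral closure; the network iteration equalises the cavity
pressure across all channels while matching the breathing flux.

The model quantifies, for exhale (outward protection) and inhale (inward
protection):

- peripheral leakage `Q_g` and its nose/chin/cheek decomposition,
- through-mask flux `Q_m = Q_m,cav + Q_m,c` (cavity + channel tops),
- per-channel exit-jet velocities `U_jet = Q_g,i / (W_i K_i(exit))`,
- the effect of fabric air resistance `c_k`, nose clips (exit minor-loss
  `k_L` on the nose channels), and cavity size/placement perturbations.

Because real deployed-mask gap fields are not publicly available, a
seeded synthetic generator produces smooth per-channel gap profiles
constrained to the documented regional ranges (nose 1.5–6 mm, chin
0.3–0.5 mm, cheek 0.7–1.2 mm), with a facial shape coefficient
α ∈ [−1.2, 1.2] emphasising one feature (nose, chin, cheeks, zygomatic
arch). Measured profiles can be supplied as CSV instead.

## Layout

```
src/maskflow/
  geometry.py    mask outline, elliptical cavity, channel skeleton
  gaps.py        synthetic gap-profile generator + CSV I/O
  channel.py     single-channel solver (collocation) + FD reference oracle
  network.py     cavity-coupled network iteration
  config.py      YAML scenario configuration
  metrics.py     decompositions, sweeps, sensitivity, jet tables
  benchmarks.py  headline experiments (jet ensembles, sensitivity)
  cli.py         click CLI
tests/           pytest suite (unit, property, oracle and acceptance tests)
scripts/acceptance.py   recomputes the headline numbers, writes JSON
```

## CLI

```bash
maskflow run                          # default scenario, JSON + CSV output
maskflow run --config scenario.yaml --seed 3 --out-dir out/
maskflow generate-gaps --out-dir out/            # synthetic gap CSV
maskflow sweep-ck --config scenario.yaml         # c_k ∈ {100,500,1000}
maskflow sweep-clip --kl 1 --kl 10 --kl 100 --kl 1000
maskflow sensitivity                             # ±7.5% area, ±5 mm shift
maskflow jet-profile                             # per-channel exit jets
maskflow validate --seed 2                       # solver-vs-oracle report
```

A scenario YAML looks like:

```yaml
label: example
seed: 1
mask: {L1_in: 9, L2_in: 5.4, tuck_ratio: 0.5}
cavity: {y_offset_mm: 0, area_scale: 0.0}
layout: {n_nose: 16, n_chin: 16, n_cheek_per_side: 8, symmetry: true}
face: {feature: nose, alpha: 1.2, seed: 1}
fabric: {ck: 500}
breath: {Q_lps: 0.5, direction: exhale}
clip: {kL: 0.0, region: nose}
edge_loss: {kL_exhale: 0.0, kL_inhale: 0.5}
solver: {eps: 1.0e-6, step_a: 0.3, max_iter: 500}
```

## Model notes

- All quantities SI; gauge pressures (ambient = 0).
- The pressure–flux coupling at the fabric is kept exactly
  Darcy-consistent: `p(x) = c_k v_n(x)` with
  `v_n = −U·(K0/Lc)·d[Δh(1+f)]/dx` from continuity.
- Exhale channels match the cavity *stagnation* pressure
  (`p(0) + (6/5)·ρU²/2`); inhale channels are integrated from the
  peripheral inlet, where the sudden-contraction loss
  `(k_L/2)·ρ(U(1+f))²` applies.
- Channel heights are clamped at a 10 µm floor; aspect ratios
  `K0/Lc > 0.2` trigger a thin-gap warning.
- The steady model (`St = 0`) uses a fixed breathing flux of 0.5 L/s.
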