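# tegotae

Decentralized interlimb coordination for hexapedal walking, built on the
*Tegotae* principle: each leg's controller scores the consistency between
its motor intention and the ground reaction it actually feels, and climbs
that score's gradient.  Six phase oscillators — one per leg, with **no**
neural coupling between them — coordinate purely through the mechanical
distribution of vertical ground reaction forces, and self-organize the
gait patterns insects show: tetrapod walking, the speed-driven
tetrapod-to-tripod transition, load compensation, and quadruped trot /
L-S walk after middle-leg amputation.

The package is aimed at researchers in locomotor neuromechanics and
legged robotics who want a desk-scale, fully reproducible testbed for
force-feedback interlimb coordination: the physical robot is replaced by
a quasi-static rigid-body contact surrogate, and everything — controller,
body, gait analysis, multi-trial experiments — is seeded and
deterministic.

## Model

Per leg `i`, with phase `phi_i` (swing for `phi < pi`, stance for
`phi >= pi`) and vertical ground reaction forces `N` in newtons:

    dphi_i/dt = omega + f_i
    f_i = -sigma1 * N_i * cos(phi_i)
          + sigma2 * (1/n_L) * sum_{j in L(i)} k_j * N_j * cos(phi_i)

`L(i)` is the neighbor set (ipsilateral adjacent ranks + contralateral
same rank, `n_L = 2` or `3`), and `k_j` is `k_a`, `k_p` or `k_c` for an
anterior, posterior or contralateral neighbor.  `f_i` is the exact
gradient of the Tegotae function
`T_i = sigma1 * (-sin phi_i) N_i + sigma2 * sin phi_i * (1/n_L) sum k_j N_j`:
the first term holds a loaded leg in stance, the second invites a leg to
swing while its neighbors carry the body.  Defaults follow the original
robot experiments (`sigma1 = 0.2`, `sigma2 = 1.2`, `k_a = 0.7`,
`k_p = 0.1`, `k_c = 0.2`, amplitudes `A = 15`, `B = 20`, `B' = 5` deg,
2.4 kg body).  See `docs/methods.md` for the contact model and the gait
classifier rules.

## Worked example

Run one 50 s slow-walk trial (omega = 2 rad/s) from random initial
phases:

```bash
tegotae simulate steady_walk --trial 0 --seed 1
```

```json
{
  "label": "tetrapod",
  "sub_label": null,
  "mean_duty": 0.5153,
  "touchdown_order": ["L1", "L3", "R2", "R1", "L2", "R3"],
  "note": "",
  "duty_per_leg": {
    "L1": 0.5725, "L2": 0.3978, "L3": 0.5551,
    "R1": 0.5697, "R2": 0.399,  "R3": 0.5563
  },
  "duty_per_rank": {"fore": 0.5711, "middle": 0.3984, "hind": 0.5557},
  "convergence_time_s": 0.0,
  "fall_fraction": 0.0199
}
```

The trial converges to a **tetrapod** gait: reading the cyclic touchdown
order per side gives hind -> middle -> fore (L3, L2, L1 and R3, R2, R1),
the insect walking order, with diagonal leg pairs stepping together.
`duty_per_leg` is the stance fraction of each leg over the final six
cycles, `convergence_time_s` the first time from which the window label
never changes (0 = converged within the first analysis window), and
`fall_fraction` the fraction of control steps in which no equilibrium
support existed (here only the very first moments, before the random
initial phases sort themselves out).

Other entry points:

```bash
tegotae experiment speed_transition --seed 1   # 10 trials + summary JSON
tegotae analyze forces.csv                     # gait report for a force CSV
tegotae reproduce-paper --seed 1 --out results # all five experiments
```

or from Python:

```python
from tegotae import make_scenario, run_experiment
summary = run_experiment(make_scenario("speed_transition", seed=1))
print(summary.transition_fraction)   # fraction tetrapod -> tripod
```

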