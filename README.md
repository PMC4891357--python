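# ucmreach

Uncontrolled-manifold (UCM) analysis of joint-angle coordination in
tool-extended reaching.

## The problem

When a person points at a target — with the index finger, or with a rod
taped to it — the arm has more joint angles (nine, from the shoulder to
the finger base) than the task needs to fix the tip's 3-D position.  Many
joint configurations place the tip at the same spot; they form the
*uncontrolled manifold* in joint space.  Across repeated reaches, the UCM
method asks whether trial-to-trial joint-angle variability lies mostly
*along* that manifold (it then does not disturb the tip: goal-equivalent)
or *orthogonal* to it (it does: non-goal-equivalent).

With `C` the 9×9 across-trials covariance of the joint angles at a
movement instant and `J` the 3×9 Jacobian of tip position at the mean
configuration:

    NGEV = trace( orth(Jᵀ)ᵀ · C · orth(Jᵀ) ) / d,       d = 3
    GEV  = trace( null(J)ᵀ  · C · null(J)  ) / (n − d),  n = 9
    V_Ratio = GEV / NGEV

`null(J)` (9×6) spans the manifold's tangent space, `orth(Jᵀ)` (9×3) its
orthogonal complement; each variance is per subspace dimension (rad²).
`log(V_Ratio) > 0` means the tip position is stabilised by joint-angle
covariation.  Because the raw quantities are strongly right-skewed, the
log-transformed values are used downstream.

The package is aimed at motor-control researchers who want to run this
analysis on trial ensembles of joint-angle and tip trajectories
(delimited-text tables), or to validate the whole chain on synthetic data
with known ground truth.  It provides:

- `arm_model` — forward kinematics and finite-difference Jacobian of the
  9-DOF arm-plus-rod chain, and SVD subspace bases;
- `ucm` — the GEV/NGEV/V_Ratio decomposition, with an independent
  per-trial projection oracle;
- `kinematics` — the endpoint battery: movement bounds (25 mm/s speed and
  10 mm radius criteria), peak velocity, acceleration/deceleration times,
  horizontal/vertical path curvature, absolute/variable error, and
  time-normalisation to 100 points;
- `synthetic` — a generator emulating the 8-condition study design
  (rod 0/10/20/30 cm × participant displaced or not, 25 trials, 100 Hz,
  30 cm reaches) with controllable goal-equivalent / non-goal-equivalent
  joint noise;
- `pipeline` + a thin `ucmreach` CLI — end-to-end orchestration and
  summary tables.

## Worked example

```python
import numpy as np
from ucmreach import (VariabilityModel, analyze_ensemble,
                      generate_condition_dataset, study_design)

condition = study_design()[0]          # index finger, not displaced
ensemble = generate_condition_dataset(condition,
                                      model=VariabilityModel(seed=5))
result = analyze_ensemble(ensemble)
u = result.ucm
print(result.n_analyzed, result.n_failed)
print(f"{result.absolute_error:.1f} {u.v_ratio_log:.2f} {u.stabilized}")
```

prints

```
20 5
5.9 3.08 True
```

Of the 25 simulated trials, 20 passed the movement-bounds criteria (the 5
others landed outside the 10 mm target radius and are logged, not silently
dropped).  The mean endpoint error is 5.9 mm, and at the 100 % movement
instant `log(V_Ratio) = 3.08 > 0`: joint-angle variability is concentrated
along the manifold, i.e. the fingertip position is stabilised — the
expected signature, since the generator injected a 4:1 std ratio
(2° goal-equivalent vs 0.5° orthogonal per dimension).

The same run from the shell:

```sh
ucmreach run config.yaml --out results/
```

where `config.yaml` holds the geometry (segment lengths in mm), the noise
model and a seed; `results/` then contains per-condition JSON, the
error/kinematics summary tables, the GEV/NGEV-by-condition table and a
log of any detection failures.  `examples/` has one narrative script per
capability.

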