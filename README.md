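# pivotflow

Models and analysis tools for how a moving observer perceives object motion
and depth from optic flow.

## The problem

When the eyes rotate to track something, the whole retinal image moves.
The classic account says the brain compensates by subtracting an
eye-velocity signal — a coordinate transformation (CT) that recovers
world-relative object motion, `w_obj = w_ret + w_eye`. But that only works
when the eye *purely rotates*. As soon as the eye also translates (walking
past a scene while fixating a landmark), the flow produced by the eye
movement becomes depth-dependent, and the same retinal motion instead
carries depth information through the motion-parallax (MP) ratio
`d' = w_ret / w_eye` (depth normalized by viewing distance).

Both computations are limiting cases of one linear relation once the
*rotation pivot* of the optic flow field is made explicit. With `p'` the
pivot distance normalized by viewing distance (`p' = 0`: pure rotation,
"R"; `p' = 1`: translation + counter-rotation about fixation, "R+T"):

    w_obj = w_ret + (1 - (1 + d') p') * w_eye

An observer who infers `p'` from the background flow should therefore
*switch* between adding eye velocity to retinal motion (R) and dividing
retinal motion by eye velocity (R+T). The package implements this account
end to end, for researchers in visual psychophysics and computational
neuroscience:

* `pivotflow.geometry` — the equation engine, Gaussian stimulus velocity
  profiles, and a perspective-projection optic-flow simulator;
* `pivotflow.observer` — the perceptual model: pursuit-slip correction,
  weighted CT (`a_ret`, `a_eye` weights with flow-parsing-style gains) and
  the MP depth percept with an explicit "ambiguous" state;
* `pivotflow.behavior` — fitting: circular-error minimization for
  direction reports, cumulative-Gaussian psychometric MLE for near/far
  reports, pursuit-gain estimation from eye traces, Wilcoxon /
  Hodges-Lehmann / Mann-Whitney / permutation group statistics;
* `pivotflow.synth` — synthetic observers, cohorts, eye traces, and
  Poisson model neurons with the statistical structure the analyses assume;
* `pivotflow.rnn` — a 64-unit continuous-time recurrent network trained
  (NumPy backprop-through-time + Adam) to output world motion and depth
  from retinal motion plus two background-dot flows, with joint
  velocity-tuning probes and the Fourier tuning-shift metric;
* `pivotflow.mt` — the ten-parameter joint retinal/eye velocity tuning
  model of MT-like neurons with Poisson maximum-likelihood fitting;
* `pivotflow.pipeline` / the `pivotflow` CLI — seeded, manifest-tracked
  multi-stage runs over text artifacts (CSV/JSON/YAML).

## Worked example

Simulate a depth-discrimination session for one synthetic observer who
parses half of the horizontal retinal motion as parallax, then fit
psychometric functions per geometry and eye direction:

```python
import numpy as np
from pivotflow import (
    ExperimentDesign, SyntheticObserverSpec, generate_trials, fit_psychometric,
)
from pivotflow.observer import GeometryCondition, EyeCondition, ObserverParams

params = {
    (g, e): ObserverParams(g_ret=0.5, g_eye=1.0, a_ret=0.5, a_eye=0.0)
    for g in GeometryCondition for e in EyeCondition
}
observer = SyntheticObserverSpec(params=params, depth_noise_sigma=0.3,
                                 depth_prior_bias=0.8, seed=0)
design = ExperimentDesign.exp2(reps=20)   # -90..90 deg in 15 deg steps

trials = generate_trials(design, observer)
sub = trials[trials.eye_condition == "Fixation"]
for (geometry, eye_dir), grp in sub.groupby(["geometry", "eye_dir"]):
    if geometry == "none":
        continue
    fit = fit_psychometric(grp.retinal_dir_deg.astype(float),
                           (grp.depth_report == "far").astype(float))
    print(f"{geometry:>3} eye {eye_dir:+.0f}: "
          f"slope {fit.slope:+.4f} /deg, midpoint {fit.mean_m:+6.1f} deg")
```

Output:

```
  R eye -1: slope +0.0015 /deg, midpoint +270.0 deg
  R eye +1: slope -0.0013 /deg, midpoint -244.0 deg
 RT eye -1: slope -0.0045 /deg, midpoint   +0.2 deg
 RT eye +1: slope +0.0045 /deg, midpoint  -24.7 deg
```

In the pure-rotation geometry the flow carries no depth information: the
reports are dominated by the observer's near bias, so the fitted slopes
are near zero and the midpoints run off the stimulus range (a flat curve
has no meaningful midpoint). In the fixation-pivot geometry the observer
shows a three-fold steeper psychometric function near the veridical
midpoint whose slope *inverts with eye direction* — the signature of depth
computed as the ratio of retinal to eye velocity.

The same stages are scriptable from the shell:

```bash
pivotflow synth-behavior --experiment Exp1 --n-observers 10 --seed 1 --out run/
pivotflow fit-behavior --trials run/trials.csv --out run/
pivotflow simulate-flow --geometry RT --pprime 1.0 --seed 1 --out run/
pivotflow train-rnn --epochs 5000 --seed 1 --out run/
```

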