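# gazeassist

Quantitative analysis of a physical therapist's gaze and of the assisted
person's movement during supported sit-to-stand transfers.

When a therapist helps someone stand up from a chair, two streams of
evidence describe the interaction: **where the therapist looks** (recorded
with a wearable eye tracker at 50 Hz and summarized over body-part areas
of interest) and **how the assisted person moves** (optical motion capture
at 100 Hz plus six force plates at 1,000 Hz). `gazeassist` implements the
full processing chain for both streams and a synthetic-trial generator
with known ground truth, so every stage is testable without any recording.

The package is aimed at researchers in rehabilitation biomechanics and
movement science who want a reproducible, scriptable version of this
analysis — or a controlled test bed for parts of it (I-VT fixation
filtering, AOI dwell metrics, seat-off detection, whole-body COM
estimation).

## What it computes

**Gaze.** Fixations are detected with a velocity-threshold (I-VT) filter
(default 30 deg/s, minimum duration 60 ms). Six areas of interest — head,
neck, upper trunk, hip, knee, foot — are geometric height bands anchored to
the collaborator's marker landmarks, so they track the body frame by
frame. Four metrics are computed per AOI over the support period (first
stand-up onset to hand release after the fifth cycle): total duration of
fixation (% of the period), number of fixations, mean fixation time per
visit, and latency to first fixation.

**Kinematics.** The body is a 10-segment rigid-link model (trunk with
head, pelvis, and left/right upper limb, thigh, shank, foot). Occluded
ASIS markers are reconstructed as virtual markers from a sacral jig
calibrated in a static standing pose. The whole-body center of mass is the
mass-fraction-weighted sum of segment COMs,

    COM = Σᵢ mᵢ · (pᵢ + cᵢ (dᵢ − pᵢ)),

with de Leva-adjusted mass fractions mᵢ and longitudinal COM positions cᵢ
between the proximal (pᵢ) and distal (dᵢ) landmarks. Per stand/sit cycle
the pipeline extracts:

- **deepest trunk flexion** — the maximum of the trunk's Cardan x-rotation
  (forward lean positive);
- **seat-off** — the instant the summed vertical force on the two plates
  under the chair reaches 0 N;
- **COM velocity** — forward COM displacement from seat-off to maximum
  ankle dorsiflexion, divided by the elapsed time;
- **COM–BOS distance** — the signed forward distance from the rearmost
  heel marker (the trailing edge of the base of support) to the COM at
  seat-off (negative = COM behind the heels).

**Statistics.** Gaze metrics: two-factor mixed-design ANOVA (experience ×
AOI; dfs (1, N−2) and (5, 5(N−2))), simple main effects with a pooled
error term, Bonferroni-adjusted pairwise comparisons. Kinematic indices:
two-sample pooled-variance t tests on trial-level observations.

## Worked example

```python
import gazeassist as ga
from gazeassist import synthetic_data as sd, stats_report as sr

cfg = sd.CohortConfig(seed=42)            # 7 experts + 17 novices, 5 trials each
gaze, kin = ga.run_cohort(sd.iter_trials(cfg))

for idx in ("deepest_trunk_flexion_deg", "com_velocity_ms", "com_bos_distance_m"):
    r = sr.trial_t_test(kin, idx)
    print(f"{idx}: expert {r.mean_1:.3f} ({r.sd_1:.3f})  "
          f"novice {r.mean_2:.3f} ({r.sd_2:.3f})  t({r.df}) = {r.t:.2f}, p = {r.p:.2g}")
```

prints (exact output at seed 42):

```
deepest_trunk_flexion_deg: expert 42.010 (1.209)  novice 38.128 (3.594)  t(118) = 6.23, p = 7.3e-09
com_velocity_ms: expert 0.446 (0.024)  novice 0.492 (0.064)  t(118) = -4.10, p = 7.5e-05
com_bos_distance_m: expert -0.023 (0.002)  novice -0.046 (0.035)  t(118) = 3.95, p = 0.00013
```

Read: expert-assisted trials show deeper trunk flexion (~42° vs ~38°), a
slower forward COM (~0.45 vs ~0.49 m/s) and a COM closer to the base of
support at seat-off (−0.023 vs −0.046 m) — the generator's configured
group conditions, recovered through the entire measurement pipeline. The
mixed ANOVA on head-AOI dwell for the same cohort gives a head simple main
effect of F(1, 132) = 17.2, p < .001 (expert 10.8% vs novice 2.9%).

## Command line

```bash
gaze-assist synth --config cohort.yaml --out data/ --seed 42   # write trial bundles
gaze-assist run   --data data/ --out results/                  # full pipeline
gaze-assist stats --data results/ --out report/                # ANOVA + t tests
```

Trial bundles are plain text: `markers.csv`, `static.csv` (calibration
pose), `grf.csv`, `gaze.tsv`, `meta.yaml`. `synth-cohort` is an alias for
`gaze-assist synth`. Real C3D motion-capture files can be ingested with
`gazeassist.read_c3d` (optional `ezc3d` dependency).

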