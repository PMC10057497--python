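# golfswing

Analysis pipeline for sex differences in golf-swing trunk kinematics, built
for motion-capture data of junior players. From raw 3-D marker trajectories
(pelvis, thorax, and club markers at 200 Hz) it computes:

* **Discrete swing parameters** per trial — maximal thorax rotation
  (Tmax), maximal pelvis rotation (Pmax), the X-factor
  (Xfac = θ_thorax − θ_pelvis at the top of the backswing), the X-factor
  stretch (SXfac = max over the downswing of the thorax–pelvis separation
  minus Xfac), and golf-club velocity (GCV), the peak club-head-marker
  speed just before impact.
* **Pelvis–thorax coupling** — the continuous relative phase
  CRP(t) = φ_pelvis(t) − φ_thorax(t), with each φ the unwrapped phase of
  the centered Hilbert analytic signal, aligned around maximal pelvis
  rotation and time-normalized to 200 samples.
* **Group inference** — one-way ANOVA with partial eta squared
  (η²ₚ = SS_b/(SS_b+SS_w)), Pearson correlations with exact two-tailed
  significance (t = r√(n−2)/√(1−r²)), a Shapiro–Wilk normality screen, and
  one-dimensional statistical parametric mapping (SPM): a pointwise
  two-sample t field over the 200 CRP nodes tested against the
  random-field-theory threshold u solving

      E[EC(u)] = P(T_df > u) + (Q−1)/FWHM · √(4 ln 2)/(2π) · (1 + u²/df)^−(df−1)/2 = α,

  with a seeded max-|t| permutation threshold as nonparametric
  cross-check.

Swing events are defined from the club-head marker alone: the start of the
swing (speed reaches 0.2 m/s moving away from the target), the top of the
backswing (minimum club speed at the backswing–downswing transition), and
impact (peak acceleration magnitude as the club decelerates on ball
contact).

A synthetic swing generator (`golfswing.synthetic`) produces cohorts with
analytically known ground truth — raised-cosine rotation profiles,
sex-specific amplitude presets, a configurable pelvis-onset lag encoding
the thorax-led male backswing, and seeded marker noise — so every stage of
the pipeline is testable without any data download.

## Worked example

```bash
golfswing simulate --females 8 --males 6 --trials 10 --seed 42 --out demo/data
golfswing analyze  --input demo/data --out demo/results
golfswing report   --results demo/results
```

The report (excerpt) for that seed:

```
| Parameter | Sex | n | Mean | SD |
| pmax_deg | F | 8 | 44.15 | 5.35 |
| pmax_deg | M | 6 | 35.17 | 7.36 |
| gcv_mps  | F | 8 | 23.85 | 1.78 |
| gcv_mps  | M | 6 | 27.73 | 1.90 |

| Parameter | F | p | eta_p^2 | df |
| pmax_deg | 7.05 | 0.0210 | 0.370 | (1, 12) |
| gcv_mps | 15.33 | 0.0021 | 0.561 | (1, 12) |

Two-sample SPM on per-player mean CRP curves (n = 8 F vs 6 M, df = 12):
critical |t*| = 4.657 at alpha = 0.05, residual FWHM = 7.3 nodes.
Suprathreshold clusters:
- nodes 0-51 (backswing side)
```

Read: girls rotate the pelvis further (Pmax 44.2° vs 35.2°, p = 0.021,
η²ₚ = 0.37) while boys swing faster (GCV 27.7 vs 23.8 m/s, p = 0.002,
η²ₚ = 0.56), and the pelvis–thorax coupling differs significantly only on
the backswing side of the align node (node 99 = maximal pelvis rotation) —
the boys' backswing is thorax-led, so their CRP runs more negative than
the girls' until the transition.

`analyze` writes `parameters.csv` (one row per trial), `crp_curves.csv`
(200 nodes per trial), `spm.json`, `stats.json`, and `config.yaml`; every
option of the run is embedded in the artifacts, and reruns with the same
config and seed are byte-identical.

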