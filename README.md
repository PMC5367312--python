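# gazeclust

Cluster-mass permutation analysis, subject-bootstrap confidence bands and
ground-truth simulation for visual-world eye-tracking experiments.

## The problem

In referential communication, a negated instruction such as "not the
jellyfish" rules out one object but leaves the listener a choice between an
*unmentioned* alternative and a *critical* alternative whose naming history
varies by condition: never named (one speaker–one precedent, `OS1P`), named
by the live speaker (one speaker–two precedents, `OS2P`), or named by a
different, remote speaker (two speakers–two precedents, `TS2P`).  Gaze to
the displayed alternatives, sampled at 500 Hz over the 2.5 s following the
expression, indexes the interpretation as it unfolds; the scientific
question is *when* two influences emerge: an early effect of the linguistic
precedent itself, and a later effect of whether that precedent is part of
common ground with the current speaker.

Analyzing such data means testing a time series of repeated-measures
contrasts without bin-by-bin multiple-comparison problems.  `gazeclust`
implements the resampling machinery this calls for, plus a synthetic-data
generator with known ground truth so every stage can be validated.

## The method

Per trial, gaze samples are binned into 50 ms frames and reduced, per
analysis unit *i* (subject or item), condition *k* and frame *f*, to the
empirical-logit preference for the unmentioned over the critical
alternative

    eta_ikf = log( (c_u + 1/2) / (c_c + 1/2) ),

with counts pooled over the unit's trials.  For a contrast with weights
**w** (sum zero over the conditions `OS1P, OS2P, TS2P`), each unit's score
is s_if = Σ_k w_k · eta_ikf, and each frame gets a one-sample t statistic
t_f = mean(s)/se(s) with df = n − 1.  Maximal runs of consecutive frames
that are individually significant (two-tailed α = 0.05) in the same
direction form *clusters*, each summarized by its mass Σ t_f.  The null
distribution of the maximum |mass| is built by relabelling the three
condition series within each unit by an independent uniformly random
permutation and re-running the entire pipeline; a cluster's p-value is
(b + 1)/(n + 1), where b counts null maxima ≥ its |mass|.  The analysis is
run once over subjects and once over items, giving the (p1, p2) pair per
contrast.  The two built-in contrasts are

* `linguistic`: (−1, ½, ½) — the two-precedent average vs. one precedent;
* `common_ground`: (0, 1, −1) — OS2P vs. TS2P.

Confidence bands for the mean curves are pointwise percentile bootstrap
over resampled subjects; selection rates are tabulated per condition and
compared between conditions with a subject-level sign-flip randomization
test.

The generator emulates the full design — 24 subjects, 18 items rotated
through the three conditions via three lists, gamma-renewal fixation
sequences, logistic-ramp preference curves per condition with subject/item
random midpoint shifts — so that the qualitative target pattern (an early
linguistic effect at ~900 ms, a later common-ground effect at ~1600 ms) is
recoverable with known truth.

## Worked example

```python
import gazeclust as gc

params = gc.SyntheticParams(seed=7)
design = gc.generate_design(24, 18, 3)
gaze = gc.generate_gaze(design, params, seed=7)
sel = gc.generate_selections(design, params, seed=8)

cfg = gc.AnalysisConfig(n_permutations=1000, seed=7, window_ms=(0.0, 2500.0))
report = gc.run_full_analysis(gaze, cfg)
for name in ("linguistic", "common_ground"):
    p1, p2 = report.p_pair(name)
    r = report.report_for(name, "subject")
    print(f"{name}: p1={p1:.3f} p2={p2:.3f} onset={r.onset_ms()} ms")

print(gc.rate_table(sel))
res = gc.rate_randomization_test(sel, "OS2P", "OS1P", n_permutations=9999, seed=7)
print(f"OS2P vs OS1P: diff={res.statistic:.3f}, p={res.p_value:.4f}")
```

prints

```
linguistic: p1=0.001 p2=0.001 onset=900.0 ms
common_ground: p1=0.040 p2=0.016 onset=2300.0 ms
           unmentioned  critical  negated  n_trials
condition
OS1P              45.8      54.2      0.0       144
OS2P              85.4      10.4      4.2       144
TS2P              61.1      38.2      0.7       144
OS2P vs OS1P: diff=0.396, p=0.0001
```

The linguistic contrast is significant by subjects and items from 900 ms to
the end of the window; the common-ground contrast reaches significance only
late in the window, i.e. the two-precedent preference emerges before the
common-ground modulation.  The selection table shows the unmentioned
alternative chosen far more often in `OS2P` (85.4%) than in `OS1P` (45.8%),
and the randomization test confirms the difference.

The same pipeline is available from a shell:

```sh
gazeclust simulate --out-dir sim
gazeclust analyze --gaze sim/gaze.csv --selections sim/selections.csv --out-dir out
gazeclust calibrate --n-runs 50 --mode both --out-dir cal
```

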