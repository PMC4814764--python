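# attune

Anisotropic categorical cross-recurrence analysis of two coupled, coded
behavioral streams (gestures and speech), with Monte Carlo permutation
inference and a synthetic-cohort generator so the entire chain runs
without any external data.

Given per-child tables of timed, leveled behavioral episodes, the
pipeline:

1. **Rasterizes** events into 1 Hz skill-level series (levels 0–7, 0 = no
   event) and maps them onto three complexity tiers (1–3 sensorimotor,
   4–6 representational, 7 abstract).
2. Builds the **cross-recurrence plot (CRP)**: gesture seconds on the
   rows, speech seconds on the columns, a cell marked with the shared
   tier whenever both streams display the same tier.
3. Computes **anisotropic CRQA measures** — recurrence rate (RR),
   laminarity (LAM), trapping time (TT) and maximum line length (MaxL),
   separately for vertical and horizontal line structures — globally and
   per tier, plus relative-difference asymmetry scores
   (`V-H_LAM = LAM_V − LAM_H`, `V-H_TT = (TT_V − TT_H)/(TT_V + TT_H)`,
   and likewise for MaxL).
4. Computes the **LOS profile** (per-diagonal recurrence rate within ±60 s
   of the line of synchrony) and its measures %Sync, RR_peak, τ_peak and
   Q_LOS, with an episode-shuffle permutation test for RR_peak.
5. Runs **permutation statistics** over a cohort: one-sample, two-group
   and paired mean-difference tests, Cohen's d, permutation Pearson
   correlations, and an inter-rater agreement test.
6. Simulates **synthetic cohorts** with controllable gesture–speech
   lead/lag, tier occupancy, dwell-time asymmetry and mismatch noise, and
   covariates linked to the imposed ground truth.

## Command line

```bash
# simulate a cohort of event/metadata CSVs
attune simulate --out data/ --n-children 12 --seed 7

# analyze it end to end (per-child, tier, stats and correlation reports)
attune analyze --events data/ --meta data/metadata.csv --out out/ \
    --seed 1 --perms 1000 --window 60 --min-line 2

# one child, printed to stdout
attune crqa --events data/c01.csv --child c01
```

`attune analyze` writes `per_child.csv`, `tier_S.csv`, `tier_R.csv`
(each with KG / grade-1 / overall mean rows), `group_stats.json`,
`correlations.csv`, per-child LOS profiles under `profiles/` and CRP
matrices under `crp/`, plus the effective `config.yaml`.

Event CSV dialect: header `child_id,stream,start_s,end_s,category,level`
with `stream ∈ {gesture, speech}` and an empty `level` for unleveled
events. Metadata:
`child_id,grade,age_months,math_score,language_score,avg_past_score`.

## Python API

```python
import attune

events, metas, truths = attune.generate_cohort(12, {"lag_speech_s": (0, 20)}, seed=1)
report = attune.analyze_cohort(events, {m.child_id: m for m in metas},
                               attune.AnalysisConfig(n_perm=1000, seed=1))
attune.write_report(report, "out/")
```

## Conventions

- Time bins are half-open `[t, t+1)`; an event claims a bin iff it
  overlaps it by ≥ 0.5 s (exact ties go to the later-starting event).
- LAM/TT count lines of length ≥ 2; MaxL counts runs of any length ≥ 1.
- Tier-restricted %RR and LAM are normalized by the full plot's
  recurrent-point count, so tier values sum to the global ones.
- LOS profile delays: τ = speech time − gesture time; τ > 0 means
  gestures lead. RR_τ is normalized per diagonal; Q_LOS uses raw counts
  in the window, excluding τ = 0.
- All permutation p-values use the add-one correction
  `(1 + hits)/(1 + n_perm)` and are bit-reproducible given a seed.
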