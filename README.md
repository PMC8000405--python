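# pmscore

`pmscore` rates how deeply a healthcare delivery organization has integrated
**personalized medicine (PM)** into clinical care. It is written for health
services researchers and health-system strategists who field rubric-based
surveys of PM adoption and need a reproducible scoring engine, a synthetic
cohort simulator for method development, and landscape analytics for the
resulting cohorts.

## The rubric

Each of five clinical areas — oncology, prenatal/neonatal screening,
pharmacogenomics/chronic disease, rare/undiagnosed disease, healthy patient
screening — is scored against eight criteria, each worth at most one point:

| # | criterion | rule |
|---|-----------|------|
| 1–3 | testing guidance, leadership, internal funding | discrete tier: 1/3, 2/3 or 1 point |
| 4 | utilization of data | 1/3 point per satisfied statement (standard of care, off-label/trial matching, experimental research) |
| 5 | data sharing | 1/4 point per satisfied statement (individual physicians, multidisciplinary team, across departments, external organizations) |
| 6–8 | genomic, other-omics, non-laboratory data collection | baseline 1/9, 2/9 or 1/3 by most advanced technique, × consistency multiplier 1/2/3 (some/most/all physicians order) |

An area's total `S ∈ [0, 8]` maps to an integration level: `S ≤ 3 → 1`,
`3 < S ≤ 4 → 2`, `4 < S ≤ 5 → 3`, `5 < S ≤ 6 → 4`, `S > 6 → 5`. The
organizational composite is the mean of the levels of the three
longest-running areas, padded with Level 0 when fewer than three exist,
rounded to the nearest integer (ties are arithmetically impossible);
an organization reporting no PM activity at all is Level 0.

Points are computed as exact rational fractions, so boundary totals like
3.0 never drift across a level threshold.

## Worked example

```python
import pmscore as pm

area = pm.AreaResponse(
    area="oncology", duration_years=8,
    testing_guidance="tier2", leadership="tier2", internal_funding="tier1",
    utilization={"standard_of_care": True, "off_label_or_trial_matching": True},
    sharing={"individual_physicians_only": True,
             "multidisciplinary_team_within_department": True},
    genomic={"tier": "tier2", "consistency": "most"},       # panels, most physicians
    other_omics={"tier": "tier1", "consistency": "some"},
    non_laboratory={"tier": "tier2", "consistency": "all"},
)
score = pm.score_area(area)
for crit, pts in score.criterion_points.items():
    print(f"{crit:20s} {float(pts):.3f}  ({pts})")
print("total", float(score.total), "level", score.level)
```

prints

```
testing_guidance     0.667  (2/3)
leadership           0.667  (2/3)
internal_funding     0.333  (1/3)
utilization          0.667  (2/3)
sharing              0.500  (1/2)
genomic              0.444  (4/9)
other_omics          0.111  (1/9)
non_laboratory       0.667  (2/3)
total 4.055555555555555 level 3
```

The genomic criterion shows the two-step rule: multigene panels set a 2/9
baseline, and ordering by *most* physicians doubles it to 4/9. The total
4.06 falls in the `(4, 5]` bin, so this oncology program rates Level 3.
Adding a younger, minimal pharmacogenomics program (Level 1) gives the
organization the padded level triple `(3, 1, 0)`, mean 4/3, composite
**Level 1** — the padding deliberately penalizes narrow PM adoption.

## Command line

```bash
pmscore simulate --n 153 --seed 7 --output cohort.csv   # synthetic survey cohort
pmscore score    --input cohort.csv --output scores.csv # per-area points + composites
pmscore report   --input cohort.csv --output report.json --tables tables/
```

`simulate` draws organizations from a mixture of documented archetypes
(physician-driven, department-led, enterprise-pioneer) with survey-derived
metadata distributions; `report` computes level distributions (overall and
stratified), criterion-by-level cross-tabs, per-area utilization and
genomic-technique summaries, and Spearman (or Pearson) correlations between
criterion points and area levels.

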