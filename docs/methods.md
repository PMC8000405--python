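# Methods

## The measurement model

`pmscore` implements a capability-maturity rubric for personalized-medicine
(PM) integration. The unit of measurement is a *PM program*: one clinical
area (of five) within one organization. Eight criteria each contribute at
most one point and are weighted equally, so a program's score lies in
[0, 8]. Three scoring mechanisms are used:

1. **Discrete criteria** (testing guidance and data accessibility,
   leadership, internal funding): the single tier that best describes the
   organization earns 1/3, 2/3 or 1 point. A `none` tier — the criterion is
   unmet at any described level — earns 0. The rubric's printed form lists
   only the three positive tiers; the explicit zero state is required to
   represent programs that, e.g., order no testing at all.
2. **Breadth criteria** (data utilization, data sharing): independent
   checklist statements worth 1/3 and 1/4 point each. The sharing
   checklist is scored literally even though its first statement ("data
   only utilized by individual physicians") reads as logically exclusive of
   the broader-sharing statements; a strictly literal reading caps an
   organization that no longer restricts data to individual physicians at
   3/4 unless the first statement is understood cumulatively. We implement
   the printed checklist and surface the tension here rather than resolve it.
3. **Breadth-and-consistency criteria** (genomic, other-omics and
   non-laboratory data collection): the most advanced technique employed
   sets a baseline of 1/9, 2/9 or 1/3 point, multiplied by 1, 2 or 3
   according to whether some, most or all physicians order that data type.
   One consistency value is stored per criterion — the consistency of the
   most advanced technique — because that is the only value the score uses.
   `tier = none` and `consistency = none` imply each other and score 0.

All points are exact `fractions.Fraction` values. Totals are therefore
compared to level boundaries exactly; floats supplied by callers are
rounded to 9 decimals first so that representation noise around a boundary
(e.g. nine accumulated thirds) cannot flip a level.

## Level assignment

The rubric prints only the endpoints: a total of three or less is Level 1
and more than six is Level 5. The interior boundaries are the unique
equal-width completion of those endpoints — right-closed unit bins
(3, 4], (4, 5], (5, 6] for Levels 2–4 — so a total exactly on a boundary
takes the lower level, consistent with "three or less". `assign_level` is a
non-decreasing step function of the total with image {1, …, 5}.

## Composite aggregation

The organizational composite averages the levels of the three clinical
areas with the longest program durations (duration ties broken by the fixed
canonical area order, oncology first), padding with Level 0 when fewer than
three areas exist, and rounds to the nearest integer. The mean of three
integers has fractional part 0, 1/3 or 2/3, so rounding ties cannot occur;
half-up rounding is declared for completeness. Two boundary conventions:

* zero reported areas ⇒ composite Level 0 (self-reported "no PM");
* at least one program ⇒ composite at least Level 1. Without this floor, a
  single Level-1 area would give mean 1/3 and round to 0, conflating an
  organization that *does* practice PM with one that reports none at all.
  The floor binds only in that corner (single area at Level 1).

## Synthetic cohorts

The generator emulates a survey cohort whose microdata are unavailable. Its
generative primitive is the *archetype* — a response profile, not a level
target — so integration levels emerge from sampled answers the way they do
in real cohorts, where organizations at the same level differ widely in how
they got there. Three defaults ship: `physician_driven` (champion-led,
low tiers, little sharing; lands almost entirely at composite Level 1),
`department_led` (mid tiers, internal sharing; mostly Level 2), and
`enterprise_pioneer` (C-suite-backed, broadly sequenced; mostly Level 4–5).
The default mixture weights them equally.

Parameters of note (units, default, rationale):

* **metadata distributions** — practice type 53/34/13%, affiliation
  30/29/41%, urban/suburban/rural 85/13/2%, region 32/28/24/16%,
  hospital-count bins 35/34/20/7/3% over 1 / 2–5 / 6–10 / 11–25 / 26+:
  the respondent demographics of the 153-organization US survey the rubric
  was originally fielded on.
* **area counts** — per-archetype categorical over 1–5 areas; breadth grows
  with maturity. The equal-weight mixture expects ≈2.9 areas per
  organization, matching the reported ratio of PM programs to respondents
  (433/153 ≈ 2.8).
* **durations** — lognormal years (medians 3/5/8 by archetype, σ = 0.5);
  continuous, so duration ties are measure-zero unless `quantize_durations`
  is set, which rounds to a step and deliberately exercises the canonical
  tie-break.
* **level0_fraction** — probability of a zero-area organization; default 0
  because the original survey screened out organizations without PM
  initiatives.
* **area_effect** ∈ [0, 1] — optional within-organization coupling: with
  that probability a criterion draw reuses an organization-level uniform
  (a common random number), correlating answers across areas while leaving
  every marginal distribution unchanged. Default 0; no published estimate
  of cross-area correlation exists to calibrate it.

All sampling flows through a single seeded `numpy.random.Generator`; a
cohort is a pure function of its spec. What passing tests on synthetic data
do **not** show: real survey cohorts have respondent-role biases,
self-report inflation and instrument-level question wording effects that no
archetype mixture reproduces; the generator validates the machinery, not
the field's empirical distribution.

## Landscape analytics

Distributions, cross-tabs and summaries are straightforward counting;
conventions worth stating:

* Organization-level criterion cross-tabs use *any-area-matches* semantics
  (the organization exhibits a variant if any of its programs does);
  program-level cross-tabs are exposed separately.
* Level-0 organizations appear in composite-level distributions but have no
  programs, so per-area analytics exclude them by construction.
* The genomic summary reports, per technique tier, the consistency
  distribution of programs whose *most advanced* tier it is, with a `none`
  row for all other programs — an approximation of instrument-level
  technique-by-technique tables, since the scored schema stores one
  (tier, consistency) pair per criterion.
* The correlation between criterion points and area level defaults to
  Spearman's rank coefficient because the level is ordinal; Pearson is
  available via `method="pearson"`. The choice is an interpretation, not a
  printed rule. Cells with fewer than 3 programs or zero variance are
  reported as missing (NaN/`null`), never as 0.

## Problem sizes and numerical checks

The test suite verifies engine-vs-oracle equivalence on 100 000 sampled
response combinations (the full discrete response space, ≈8×10⁶
combinations, is enumerable but unnecessary), monotonicity on 10 000
upgrade pairs, all 216 composite level triples exhaustively, mixture
recovery at n = 1000 within 3 binomial standard errors, and correlation
behavior at n = 2000 under a constructed null. Statistical assertions use
fixed seeds and ≥3-standard-error tolerances.

## Known limitations

* The rubric's interior level boundaries and the composite Level-1 floor
  are documented conventions, not printed rules.
* The sharing checklist ambiguity above can understate broadly-sharing
  organizations by 1/4 point.
* The synthetic generator is not calibrated to any published aggregate
  results — doing so from aggregates alone would be circular for testing —
  so its emergent level distribution is plausible, not authoritative.
* Wide-format survey ingestion, Excel/REDCap inputs, significance testing
  between strata, and plotting are out of scope.
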