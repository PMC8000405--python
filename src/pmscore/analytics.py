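"""Cohort-level landscape analytics for scored survey cohorts.

Given a scored cohort (:func:`pmscore.scoring.score_cohort`), this module
computes the reporting surfaces of a PM-integration landscape analysis:

* composite-level distributions, overall and stratified by organization
  metadata;
* per-clinical-area program-level distributions;
* criterion cross-tabs — for each composite level, the share of
  organizations exhibiting a given criterion variant (an organization
  matches when any of its areas does; a program-level variant is exposed
  as well);
* per-area summaries of data utilization flags and of genomic-technique ×
  ordering-consistency cells;
* criterion-points vs area-level correlations per clinical area.

Level is ordinal, so the default correlation coefficient is Spearman's
rank correlation; Pearson is available behind the ``method`` argument.
Zero-variance or under-sized cells are reported as missing (NaN), never
silently as zero. All analytics are deterministic given the scored cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .rubric import (
    ClinicalArea,
    ConsistencyLevel,
    DataTier,
    DiscreteTier,
    OrgResponse,
    CRITERIA,
    DATA_CRITERIA,
    DISCRETE_CRITERIA,
    SHARING_FLAGS,
    UTILIZATION_FLAGS,
)
from .scoring import ScoredOrg

__all__ = [
    "ConfigurationError",
    "LandscapeReport",
    "level_distribution",
    "count_programs",
    "criterion_crosstab",
    "area_summaries",
    "correlate_criteria_with_level",
    "build_report",
]

GROUPABLE_FIELDS = ("affiliation", "practice_type", "demographic", "region")

LEVELS = tuple(range(6))  # composite levels 0..5
AREA_LEVELS = tuple(range(1, 6))  # per-area levels 1..5

class ConfigurationError(ValueError):
    """Unknown grouping field, criterion or variant."""


def _strata(field: str) -> list[str]:
    from . import rubric

    enum = {
        "affiliation": rubric.Affiliation,
        "practice_type": rubric.PracticeType,
        "demographic": rubric.Demographic,
        "region": rubric.Region,
    }[field]
    return [m.value for m in enum]


def level_distribution(
    scored: list[ScoredOrg], group_by: Optional[str] = None
) -> pd.DataFrame:
    """Share of organizations at each composite level 0-5.

    Returns a tidy frame with columns ``group, level, count, share``; with
    ``group_by=None`` the single group is ``"overall"``. Strata with no
    organizations are retained with count 0 and share NaN.
    """
    if not scored:
        raise ValueError("level_distribution requires a non-empty scored cohort")
    if group_by is not None and group_by not in GROUPABLE_FIELDS:
        raise ConfigurationError(
            f"unknown group_by field {group_by!r}; expected one of {GROUPABLE_FIELDS}"
        )
    rows = []
    if group_by is None:
        groups = {"overall": scored}
    else:
        groups = {name: [] for name in _strata(group_by)}
        for s in scored:
            groups[getattr(s.org, group_by).value].append(s)
    for name, members in groups.items():
        counts = {lvl: 0 for lvl in LEVELS}
        for s in members:
            counts[s.composite.composite_level] += 1
        n = len(members)
        for lvl in LEVELS:
            rows.append(
                {
                    "group": name,
                    "level": lvl,
                    "count": counts[lvl],
                    "share": counts[lvl] / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def count_programs(cohort: Iterable[OrgResponse | ScoredOrg]) -> int:
    """Total number of PM programs (area responses) in the cohort."""
    total = 0
    for rec in cohort:
        org = rec.org if isinstance(rec, ScoredOrg) else rec
        total += len(org.areas)
    return total


def _variants(criterion: str) -> tuple[str, ...]:
    if criterion in DISCRETE_CRITERIA:
        return tuple(t.value for t in DiscreteTier)
    if criterion == "utilization":
        return UTILIZATION_FLAGS
    if criterion == "sharing":
        return SHARING_FLAGS
    if criterion in DATA_CRITERIA:
        return tuple(t.value for t in DataTier)
    raise ConfigurationError(f"unknown criterion {criterion!r}")


def _area_matches(area, criterion: str, variant: str) -> bool:
    if criterion in DISCRETE_CRITERIA:
        if variant not in {t.value for t in DiscreteTier}:
            raise ConfigurationError(f"unknown variant {variant!r} for {criterion!r}")
        return getattr(area, criterion).value == variant
    if criterion == "utilization":
        if variant not in UTILIZATION_FLAGS:
            raise ConfigurationError(f"unknown variant {variant!r} for {criterion!r}")
        return bool(getattr(area.utilization, variant))
    if criterion == "sharing":
        if variant not in SHARING_FLAGS:
            raise ConfigurationError(f"unknown variant {variant!r} for {criterion!r}")
        return bool(getattr(area.sharing, variant))
    if criterion in DATA_CRITERIA:
        if variant not in {t.value for t in DataTier}:
            raise ConfigurationError(f"unknown variant {variant!r} for {criterion!r}")
        return getattr(area, criterion).tier.value == variant
    raise ConfigurationError(f"unknown criterion {criterion!r}")


def criterion_crosstab(
    scored: list[ScoredOrg], criterion: str, variant: str, unit: str = "organization"
) -> pd.DataFrame:
    """Share of units exhibiting ``variant`` of ``criterion`` at each level.

    With ``unit="organization"`` (default) an organization counts as
    matching when *any* of its areas matches, and the level axis is the
    composite level 0-5. With ``unit="program"`` each area response is a
    unit and the axis is the area level 1-5. Empty levels are retained with
    count 0 and share NaN.
    """
    _variants(criterion)  # criterion existence check
    rows = []
    if unit == "organization":
        axis = LEVELS
        buckets: dict[int, list] = {lvl: [] for lvl in axis}
        for s in scored:
            match = any(_area_matches(a, criterion, variant) for a in s.org.areas)
            buckets[s.composite.composite_level].append(match)
    elif unit == "program":
        axis = AREA_LEVELS
        buckets = {lvl: [] for lvl in axis}
        for s in scored:
            for area, sc in zip(s.org.areas, s.area_scores):
                buckets[sc.level].append(_area_matches(area, criterion, variant))
    else:
        raise ConfigurationError(f"unknown unit {unit!r}; expected organization or program")
    for lvl in axis:
        matches = buckets[lvl]
        n = len(matches)
        rows.append(
            {
                "level": lvl,
                "n": n,
                "count": int(sum(matches)),
                "share": sum(matches) / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _program_frame(scored: list[ScoredOrg]) -> pd.DataFrame:
    """One row per scored program with responses, points and level."""
    rows = []
    for s in scored:
        for area, sc in zip(s.org.areas, s.area_scores):
            row = {
                "org_id": s.org.org_id,
                "area": area.area.value,
                "level": sc.level,
                "total": float(sc.total),
            }
            for crit in CRITERIA:
                row[f"points_{crit}"] = float(sc.criterion_points[crit])
            for f in UTILIZATION_FLAGS:
                row[f"util_{f}"] = bool(getattr(area.utilization, f))
            for crit in DATA_CRITERIA:
                resp = getattr(area, crit)
                row[f"{crit}_tier"] = resp.tier.value
                row[f"{crit}_consistency"] = resp.consistency.value
            rows.append(row)
    return pd.DataFrame(rows)


def area_summaries(scored: list[ScoredOrg]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Utilization-flag shares and genomic technique × consistency shares per area.

    The utilization summary gives, per clinical area, the share of programs
    with each utilization flag set. The genomic summary mirrors a
    technique-by-consistency table: for each genomic tier, the share of
    programs in the area ordering at that tier with each consistency, with a
    ``none`` row for programs whose most advanced technique is a different
    tier (or none at all) — so each technique block sums to 1 per area.
    Areas with no programs are reported as NaN columns.
    """
    frame = _program_frame(scored)
    area_codes = [a.value for a in ClinicalArea]

    util = pd.DataFrame(index=list(UTILIZATION_FLAGS), columns=area_codes, dtype=float)
    cons_order = [
        ConsistencyLevel.ALL.value,
        ConsistencyLevel.MOST.value,
        ConsistencyLevel.SOME.value,
        ConsistencyLevel.NONE.value,
    ]
    tiers = [DataTier.TIER1.value, DataTier.TIER2.value, DataTier.TIER3.value]
    genomic = pd.DataFrame(
        index=pd.MultiIndex.from_product([tiers, cons_order], names=["technique", "consistency"]),
        columns=area_codes,
        dtype=float,
    )
    for code in area_codes:
        sub = frame[frame["area"] == code] if len(frame) else frame
        n = len(sub)
        if n == 0:
            continue
        for f in UTILIZATION_FLAGS:
            util.loc[f, code] = sub[f"util_{f}"].mean()
        for tier in tiers:
            at_tier = sub[sub["genomic_tier"] == tier]
            for cons in cons_order[:3]:
                genomic.loc[(tier, cons), code] = len(
                    at_tier[at_tier["genomic_consistency"] == cons]
                ) / n
            genomic.loc[(tier, ConsistencyLevel.NONE.value), code] = (n - len(at_tier)) / n
    return util, genomic


def correlate_criteria_with_level(
    scored: list[ScoredOrg], method: str = "spearman"
) -> pd.DataFrame:
    """Correlation of each criterion's points with the area level, per area.

    Rows are the eight criteria, columns the five clinical areas. Cells are
    NaN when an area has fewer than 3 programs or the criterion's points
    (or the levels) have zero variance — correlation is undefined there,
    and NaN is an explicit not-available marker, not a zero.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    frame = _program_frame(scored)
    area_codes = [a.value for a in ClinicalArea]
    out = pd.DataFrame(index=list(CRITERIA), columns=area_codes, dtype=float)
    for code in area_codes:
        sub = frame[frame["area"] == code] if len(frame) else frame
        if len(sub) < 3:
            continue
        y = sub["level"].to_numpy(dtype=float)
        for crit in CRITERIA:
            x = sub[f"points_{crit}"].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if method == "spearman":
                r = stats.spearmanr(x, y).statistic
            else:
                r = stats.pearsonr(x, y).statistic
            out.loc[crit, code] = float(r)
    return out


def _area_level_distribution(scored: list[ScoredOrg]) -> pd.DataFrame:
    """Share of programs at each area level 1-5, per clinical area."""
    frame = _program_frame(scored)
    area_codes = [a.value for a in ClinicalArea]
    out = pd.DataFrame(index=list(AREA_LEVELS), columns=area_codes, dtype=float)
    for code in area_codes:
        sub = frame[frame["area"] == code] if len(frame) else frame
        n = len(sub)
        if n == 0:
            continue
        for lvl in AREA_LEVELS:
            out.loc[lvl, code] = (sub["level"] == lvl).sum() / n
    return out


@dataclass
class LandscapeReport:
    """Bundle of every landscape table computed from one scored cohort."""

    n_orgs: int
    n_programs: int
    overall_level_distribution: pd.DataFrame
    stratified_distributions: dict[str, pd.DataFrame]
    area_level_distribution: pd.DataFrame
    criterion_crosstabs: dict[str, dict[str, pd.DataFrame]]
    utilization_summary: pd.DataFrame
    genomic_summary: pd.DataFrame
    correlation_matrix: pd.DataFrame
    correlation_method: str

    def to_dict(self) -> dict:
        def df(d: pd.DataFrame, orient: str = "records"):
            clean = d.replace({np.nan: None})
            if orient == "records":
                return clean.to_dict(orient="records")
            # index/column tables: nested mapping with string keys
            return {
                str(col): {str(ix): clean.loc[ix, col] for ix in clean.index}
                for col in clean.columns
            }

        return {
            "n_orgs": self.n_orgs,
            "n_programs": self.n_programs,
            "overall_level_distribution": df(self.overall_level_distribution),
            "stratified_distributions": {
                k: df(v) for k, v in self.stratified_distributions.items()
            },
            "area_level_distribution": df(self.area_level_distribution, orient="table"),
            "criterion_crosstabs": {
                crit: {variant: df(tab) for variant, tab in variants.items()}
                for crit, variants in self.criterion_crosstabs.items()
            },
            "utilization_summary": df(self.utilization_summary, orient="table"),
            "genomic_summary": df(
                self.genomic_summary.set_axis(
                    [f"{t}/{c}" for t, c in self.genomic_summary.index], axis=0
                ),
                orient="table",
            ),
            "correlation_matrix": df(self.correlation_matrix, orient="table"),
            "correlation_method": self.correlation_method,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")


def build_report(scored: list[ScoredOrg], correlation_method: str = "spearman") -> LandscapeReport:
    """Compute the full landscape report for a scored cohort."""
    crosstabs: dict[str, dict[str, pd.DataFrame]] = {}
    for crit in CRITERIA:
        crosstabs[crit] = {
            variant: criterion_crosstab(scored, crit, variant) for variant in _variants(crit)
        }
    util, genomic = area_summaries(scored)
    return LandscapeReport(
        n_orgs=len(scored),
        n_programs=count_programs(scored),
        overall_level_distribution=level_distribution(scored),
        stratified_distributions={
            f: level_distribution(scored, group_by=f) for f in GROUPABLE_FIELDS
        },
        area_level_distribution=_area_level_distribution(scored),
        criterion_crosstabs=crosstabs,
        utilization_summary=util,
        genomic_summary=genomic,
        correlation_matrix=correlate_criteria_with_level(scored, method=correlation_method),
        correlation_method=correlation_method,
    )
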