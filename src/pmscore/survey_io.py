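"""Read, validate and write survey cohorts and score outputs.

Two cohort dialects are supported:

* ``csv`` — long layout, one row per (organization, clinical area) with the
  organization metadata repeated on every row. An organization with no PM
  areas appears as a single row whose area fields are blank. RFC-4180,
  UTF-8, header row required.
* ``json`` — one top-level array of organization objects mirroring
  :class:`pmscore.rubric.OrgResponse`.

Enumeration tokens are case-insensitive on read and canonical lowercase on
write. Unknown CSV columns are carried through on the ``extras`` field and
restored on write. Validation failures are aggregated into a single report
naming every offending (organization, area, field); nothing is silently
coerced.
"""

from __future__ import annotations

import csv
import json
from fractions import Fraction
from pathlib import Path

from pydantic import ValidationError

from .rubric import OrgResponse, UTILIZATION_FLAGS, SHARING_FLAGS
from .scoring import ScoredOrg, CRITERIA

__all__ = [
    "CohortFormatError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_scores",
    "infer_format",
    "ORG_COLUMNS",
    "AREA_COLUMNS",
]


class CohortFormatError(ValueError):
    """The file does not parse in the declared dialect (bad header, bad row)."""


class CohortValidationError(ValueError):
    """One or more records violate the rubric schema.

    ``errors`` lists every offence as "org=<id> area=<code> field=<name>: <why>".
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} validation error(s):\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


ORG_COLUMNS = (
    "org_id",
    "practice_type",
    "affiliation",
    "demographic",
    "region",
    "n_hospitals",
    "respondent_role",
)

_FLAG_COLUMNS = tuple(f"util_{f}" for f in UTILIZATION_FLAGS) + tuple(
    f"share_{f}" for f in SHARING_FLAGS
)

AREA_COLUMNS = (
    "area",
    "duration_years",
    "testing_guidance",
    "leadership",
    "internal_funding",
    *_FLAG_COLUMNS,
    "genomic_tier",
    "genomic_consistency",
    "other_omics_tier",
    "other_omics_consistency",
    "non_laboratory_tier",
    "non_laboratory_consistency",
)

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f", ""}


def infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in {".csv", ".txt", ""}:
        return "csv"
    raise CohortFormatError(f"cannot infer cohort format from suffix {suffix!r}")


def _parse_bool(token: str, where: str, errors: list[str]) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    errors.append(f"{where}: unrecognized boolean token {token!r}")
    return False


def _row_to_area_dict(
    row: dict[str, str], extras_cols: list[str], where: str, errors: list[str]
) -> dict:
    def tok(col: str, default: str) -> str:
        v = (row.get(col) or "").strip()
        return v.lower() if v else default

    area: dict = {
        "area": tok("area", ""),
        "duration_years": (row.get("duration_years") or "0").strip() or "0",
        "testing_guidance": tok("testing_guidance", "none"),
        "leadership": tok("leadership", "none"),
        "internal_funding": tok("internal_funding", "none"),
        "utilization": {
            f: _parse_bool(row.get(f"util_{f}") or "", f"{where} field=util_{f}", errors)
            for f in UTILIZATION_FLAGS
        },
        "sharing": {
            f: _parse_bool(row.get(f"share_{f}") or "", f"{where} field=share_{f}", errors)
            for f in SHARING_FLAGS
        },
        "extras": {c: row[c] for c in extras_cols if (row.get(c) or "") != ""},
    }
    for crit in ("genomic", "other_omics", "non_laboratory"):
        area[crit] = {
            "tier": tok(f"{crit}_tier", "none"),
            "consistency": tok(f"{crit}_consistency", "none"),
        }
    return area


def read_cohort(path: str | Path, format: str | None = None) -> list[OrgResponse]:
    """Read and validate a survey cohort file.

    Raises :class:`CohortFormatError` on parse failure (with line numbers)
    and :class:`CohortValidationError` with an aggregated per-field report
    when any record violates the rubric schema.
    """
    path = Path(path)
    fmt = format or infer_format(path)
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path)
    raise CohortFormatError(f"unknown cohort format {fmt!r}")


def _read_json(path: Path) -> list[OrgResponse]:
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise CohortFormatError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    if not isinstance(payload, list):
        raise CohortFormatError(f"{path}: expected a top-level array of organizations")
    records: list[OrgResponse] = []
    errors: list[str] = []
    for i, obj in enumerate(payload):
        org_id = obj.get("org_id", f"<record {i}>") if isinstance(obj, dict) else f"<record {i}>"
        try:
            records.append(OrgResponse.model_validate(obj))
        except ValidationError as e:
            for err in e.errors():
                loc = ".".join(str(p) for p in err["loc"])
                errors.append(f"org={org_id} field={loc}: {err['msg']}")
    if errors:
        raise CohortValidationError(errors)
    return records


def _read_csv(path: Path) -> list[OrgResponse]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFormatError(f"{path}: empty file, header row required")
        header = [h.strip() for h in reader.fieldnames]
        missing = [c for c in ORG_COLUMNS + AREA_COLUMNS if c not in header]
        if missing:
            raise CohortFormatError(f"{path}: missing required columns: {', '.join(missing)}")
        extras_cols = [c for c in header if c not in ORG_COLUMNS + AREA_COLUMNS]

        errors: list[str] = []
        # org_id -> (metadata dict, first line, list of (line, area dict))
        orgs: dict[str, dict] = {}
        for row in reader:
            line = reader.line_num
            org_id = (row.get("org_id") or "").strip()
            if not org_id:
                errors.append(f"line {line}: blank org_id")
                continue
            meta = {c: (row.get(c) or "").strip() for c in ORG_COLUMNS}
            meta = {k: (v.lower() if k not in ("org_id", "respondent_role") else v) for k, v in meta.items()}
            entry = orgs.setdefault(org_id, {"meta": meta, "line": line, "area_rows": []})
            if entry["meta"] != meta:
                errors.append(
                    f"org={org_id} line {line}: metadata differs from line {entry['line']}"
                )
            area_token = (row.get("area") or "").strip()
            if area_token:
                where = f"org={org_id} area={area_token.lower()} line {line}"
                entry["area_rows"].append((line, _row_to_area_dict(row, extras_cols, where, errors)))
            else:
                # zero-area marker row; keep row-level extras on the org
                entry.setdefault("org_extras", {}).update(
                    {c: row[c] for c in extras_cols if (row.get(c) or "") != ""}
                )
                entry["had_blank_row"] = True

        records: list[OrgResponse] = []
        for org_id, entry in orgs.items():
            if entry.get("had_blank_row") and entry["area_rows"]:
                errors.append(
                    f"org={org_id}: mixes a blank (no-area) row with area rows"
                )
                continue
            seen: set[str] = set()
            areas = []
            for line, area in entry["area_rows"]:
                code = area["area"]
                if code in seen:
                    errors.append(f"org={org_id} area={code} line {line}: duplicate (org, area) row")
                    continue
                seen.add(code)
                areas.append(area)
            meta = entry["meta"]
            payload = {
                "org_id": org_id,
                "practice_type": meta["practice_type"],
                "affiliation": meta["affiliation"],
                "demographic": meta["demographic"],
                "region": meta["region"],
                "n_hospitals": meta["n_hospitals"] or "1",
                "respondent_role": meta["respondent_role"],
                "areas": areas,
                "extras": entry.get("org_extras", {}),
            }
            try:
                records.append(OrgResponse.model_validate(payload))
            except ValidationError as e:
                for err in e.errors():
                    loc = list(err["loc"])
                    area_note = ""
                    if loc and loc[0] == "areas" and len(loc) > 1 and isinstance(loc[1], int):
                        idx = loc[1]
                        if idx < len(areas):
                            area_note = f" area={areas[idx]['area']}"
                        loc = loc[2:]
                    field = ".".join(str(p) for p in loc) or "record"
                    errors.append(f"org={org_id}{area_note} field={field}: {err['msg']}")
    if errors:
        raise CohortValidationError(errors)
    return records


def _area_to_row(org: OrgResponse, area) -> dict[str, str]:
    row = {
        "org_id": org.org_id,
        "practice_type": org.practice_type.value,
        "affiliation": org.affiliation.value,
        "demographic": org.demographic.value,
        "region": org.region.value,
        "n_hospitals": str(org.n_hospitals),
        "respondent_role": org.respondent_role,
        "area": area.area.value,
        "duration_years": repr(float(area.duration_years)),
        "testing_guidance": area.testing_guidance.value,
        "leadership": area.leadership.value,
        "internal_funding": area.internal_funding.value,
    }
    for f in UTILIZATION_FLAGS:
        row[f"util_{f}"] = str(getattr(area.utilization, f)).lower()
    for f in SHARING_FLAGS:
        row[f"share_{f}"] = str(getattr(area.sharing, f)).lower()
    for crit in ("genomic", "other_omics", "non_laboratory"):
        resp = getattr(area, crit)
        row[f"{crit}_tier"] = resp.tier.value
        row[f"{crit}_consistency"] = resp.consistency.value
    row.update(area.extras)
    return row


def write_cohort(records: list[OrgResponse], path: str | Path, format: str | None = None) -> None:
    """Write a cohort in the canonical dialect (lowercase tokens)."""
    path = Path(path)
    fmt = format or infer_format(path)
    if fmt == "json":
        payload = [org.model_dump(mode="json") for org in records]
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return
    if fmt != "csv":
        raise CohortFormatError(f"unknown cohort format {fmt!r}")

    extras_cols: list[str] = []
    for org in records:
        for a in org.areas:
            for k in a.extras:
                if k not in extras_cols:
                    extras_cols.append(k)
        for k in org.extras:
            if k not in extras_cols:
                extras_cols.append(k)
    header = list(ORG_COLUMNS + AREA_COLUMNS) + extras_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=header, restval="")
        writer.writeheader()
        for org in records:
            if not org.areas:
                row = {
                    "org_id": org.org_id,
                    "practice_type": org.practice_type.value,
                    "affiliation": org.affiliation.value,
                    "demographic": org.demographic.value,
                    "region": org.region.value,
                    "n_hospitals": str(org.n_hospitals),
                    "respondent_role": org.respondent_role,
                }
                row.update(org.extras)
                writer.writerow(row)
            for area in org.areas:
                writer.writerow(_area_to_row(org, area))


def _fmt(x: Fraction | float) -> str:
    return f"{float(x):.6f}"


SCORE_COLUMNS = (
    "org_id",
    "record_type",
    "area",
    "duration_years",
    *CRITERIA,
    "total",
    "level",
    "padded_level_1",
    "padded_level_2",
    "padded_level_3",
    "mean_level",
    "composite_level",
)


def write_scores(scored: list[ScoredOrg], path: str | Path, format: str | None = None) -> None:
    """Write score output: one row per scored area plus one composite row per org.

    Area rows carry the eight criterion points (decimals, 6 places), the
    summed total and the area level; organization rows carry the padded
    level triple, the mean and the rounded composite level.
    """
    if not scored:
        raise ValueError("no assessments to write")
    path = Path(path)
    fmt = format or infer_format(path)
    if fmt == "json":
        payload = []
        for s in scored:
            durations = {a.area: a.duration_years for a in s.org.areas}
            payload.append(
                {
                    "org_id": s.org.org_id,
                    "areas": [
                        {
                            "area": sc.area.value,
                            "duration_years": durations[sc.area],
                            "criterion_points": {k: _fmt(v) for k, v in sc.criterion_points.items()},
                            "total": _fmt(sc.total),
                            "level": sc.level,
                        }
                        for sc in s.area_scores
                    ],
                    "composite": {
                        "selected_areas": [
                            {"area": a.value, "level": lvl, "duration_years": dur}
                            for a, lvl, dur in s.composite.selected_areas
                        ],
                        "padded_levels": list(s.composite.padded_levels),
                        "mean_level": _fmt(s.composite.mean_level),
                        "composite_level": s.composite.composite_level,
                    },
                }
            )
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return
    if fmt != "csv":
        raise CohortFormatError(f"unknown score format {fmt!r}")

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(SCORE_COLUMNS), restval="")
        writer.writeheader()
        for s in scored:
            durations = {a.area: a.duration_years for a in s.org.areas}
            for sc in s.area_scores:
                row = {
                    "org_id": s.org.org_id,
                    "record_type": "area",
                    "area": sc.area.value,
                    "duration_years": repr(float(durations[sc.area])),
                    "total": _fmt(sc.total),
                    "level": str(sc.level),
                }
                for crit, pts in sc.criterion_points.items():
                    row[crit] = _fmt(pts)
                writer.writerow(row)
            comp = s.composite
            writer.writerow(
                {
                    "org_id": s.org.org_id,
                    "record_type": "organization",
                    "padded_level_1": str(comp.padded_levels[0]),
                    "padded_level_2": str(comp.padded_levels[1]),
                    "padded_level_3": str(comp.padded_levels[2]),
                    "mean_level": _fmt(comp.mean_level),
                    "composite_level": str(comp.composite_level),
                }
            )
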