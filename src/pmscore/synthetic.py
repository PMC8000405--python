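"""Reproducible synthetic survey cohorts with controllable maturity structure.

The real survey microdata behind the rubric are not public, so this module
generates cohorts that emulate their structure: each organization is drawn
from a mixture of *archetypes* — generative response profiles, not level
targets — so that integration levels emerge from the response patterns the
way they do in real cohorts, where no single organizational archetype sits
at any given level.

Three default archetypes ship with the package:

* ``physician_driven`` — PM carried by individual clinician champions;
  low tiers, little sharing, inconsistent ordering (typical Level 1-2).
* ``department_led`` — department-level programs with moderate funding and
  internal sharing (typical Level 2-3).
* ``enterprise_pioneer`` — C-suite-backed, broadly sequenced, externally
  sharing institutions (typical Level 4-5).

Organization metadata (practice type, affiliation, demographic, region,
hospital count) defaults to the published respondent demographics of the
153-organization US survey the rubric was fielded on: practice type
53/34/13%, affiliation 30/29/41%, demographic 85/13/2% urban/suburban/rural,
region 32/28/24/16%, hospital-count bins 35/34/20/7/3%.

All randomness flows through one ``numpy.random.Generator`` seeded from the
spec: a cohort is a pure function of its :class:`CohortSpec`.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .rubric import (
    Affiliation,
    AreaResponse,
    ClinicalArea,
    ConsistencyLevel,
    DataCollectionResponse,
    DataTier,
    Demographic,
    DiscreteTier,
    OrgResponse,
    PracticeType,
    Region,
    SHARING_FLAGS,
    UTILIZATION_FLAGS,
    canonical_area_order,
)

__all__ = [
    "Archetype",
    "CohortSpec",
    "default_archetypes",
    "sample_org",
    "generate_cohort",
    "spec_from_config",
]

_PROB_TOL = 1e-9

# Published respondent demographics used as metadata sampling defaults.
DEFAULT_PRACTICE_TYPE = {
    PracticeType.HEALTH_SYSTEM: 0.53,
    PracticeType.INDEPENDENT_HOSPITAL: 0.34,
    PracticeType.INTEGRATED_DELIVERY_NETWORK: 0.13,
}
DEFAULT_AFFILIATION = {
    Affiliation.ACADEMIC: 0.30,
    Affiliation.COMMUNITY_TEACHING: 0.29,
    Affiliation.COMMUNITY_NONTEACHING: 0.41,
}
DEFAULT_DEMOGRAPHIC = {
    Demographic.URBAN: 0.85,
    Demographic.SUBURBAN: 0.13,
    Demographic.RURAL: 0.02,
}
DEFAULT_REGION = {
    Region.SOUTH: 0.32,
    Region.NORTHEAST: 0.28,
    Region.MIDWEST: 0.24,
    Region.WEST: 0.16,
}
# (low, high, probability) bins for the number of hospitals in the system.
DEFAULT_HOSPITAL_BINS = ((1, 1, 0.35), (2, 5, 0.34), (6, 10, 0.20), (11, 25, 0.07), (26, 40, 0.03))

_TIERS = (DataTier.NONE, DataTier.TIER1, DataTier.TIER2, DataTier.TIER3)
_DISCRETE = (DiscreteTier.NONE, DiscreteTier.TIER1, DiscreteTier.TIER2, DiscreteTier.TIER3)
_CONSISTENCY = (ConsistencyLevel.SOME, ConsistencyLevel.MOST, ConsistencyLevel.ALL)


def _check_simplex(probs: Sequence[float], what: str) -> None:
    if any(p < 0 or p > 1 for p in probs):
        raise ValueError(f"{what}: probabilities must be in [0, 1]")
    if abs(sum(probs) - 1.0) > _PROB_TOL:
        raise ValueError(f"{what}: probabilities sum to {sum(probs)}, expected 1")


class Archetype(BaseModel):
    """A generative response profile for one kind of organization.

    ``discrete_probs`` and ``data_tier_probs`` are 4-vectors over
    (none, tier1, tier2, tier3); ``consistency_probs`` is a 3-vector over
    (some, most, all), conditional on a positive tier; flag probabilities
    are independent Bernoulli rates; ``area_count_probs`` is a 5-vector over
    1..5 active clinical areas; durations are lognormal in years.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    discrete_probs: dict[str, tuple[float, float, float, float]]
    utilization_probs: dict[str, float]
    sharing_probs: dict[str, float]
    data_tier_probs: dict[str, tuple[float, float, float, float]]
    consistency_probs: tuple[float, float, float]
    area_count_probs: tuple[float, float, float, float, float]
    duration_log_mean: float = Field(default=math.log(5.0))
    duration_log_sd: float = Field(default=0.5, ge=0)

    @model_validator(mode="after")
    def _validate_probs(self) -> "Archetype":
        for key in ("testing_guidance", "leadership", "internal_funding"):
            if key not in self.discrete_probs:
                raise ValueError(f"archetype {self.name!r}: missing discrete_probs[{key!r}]")
            _check_simplex(self.discrete_probs[key], f"discrete_probs[{key}]")
        for key in ("genomic", "other_omics", "non_laboratory"):
            if key not in self.data_tier_probs:
                raise ValueError(f"archetype {self.name!r}: missing data_tier_probs[{key!r}]")
            _check_simplex(self.data_tier_probs[key], f"data_tier_probs[{key}]")
        for flag in UTILIZATION_FLAGS:
            p = self.utilization_probs.get(flag)
            if p is None or not 0 <= p <= 1:
                raise ValueError(f"archetype {self.name!r}: bad utilization_probs[{flag!r}]")
        for flag in SHARING_FLAGS:
            p = self.sharing_probs.get(flag)
            if p is None or not 0 <= p <= 1:
                raise ValueError(f"archetype {self.name!r}: bad sharing_probs[{flag!r}]")
        _check_simplex(self.consistency_probs, "consistency_probs")
        _check_simplex(self.area_count_probs, "area_count_probs")
        return self


def default_archetypes() -> list[Archetype]:
    """The three documented default archetypes."""
    return [
        Archetype(
            name="physician_driven",
            discrete_probs={
                "testing_guidance": (0.15, 0.60, 0.20, 0.05),
                "leadership": (0.10, 0.70, 0.15, 0.05),
                "internal_funding": (0.25, 0.55, 0.15, 0.05),
            },
            utilization_probs={
                "standard_of_care": 0.60,
                "off_label_or_trial_matching": 0.25,
                "experimental_research": 0.15,
            },
            sharing_probs={
                "individual_physicians_only": 0.80,
                "multidisciplinary_team_within_department": 0.30,
                "across_departments": 0.10,
                "external_organizations": 0.05,
            },
            data_tier_probs={
                "genomic": (0.20, 0.50, 0.25, 0.05),
                "other_omics": (0.60, 0.30, 0.08, 0.02),
                "non_laboratory": (0.35, 0.45, 0.15, 0.05),
            },
            consistency_probs=(0.70, 0.25, 0.05),
            area_count_probs=(0.25, 0.45, 0.20, 0.07, 0.03),
            duration_log_mean=math.log(3.0),
            duration_log_sd=0.5,
        ),
        Archetype(
            name="department_led",
            discrete_probs={
                "testing_guidance": (0.05, 0.30, 0.50, 0.15),
                "leadership": (0.03, 0.27, 0.55, 0.15),
                "internal_funding": (0.10, 0.35, 0.40, 0.15),
            },
            utilization_probs={
                "standard_of_care": 0.80,
                "off_label_or_trial_matching": 0.50,
                "experimental_research": 0.35,
            },
            sharing_probs={
                "individual_physicians_only": 0.90,
                "multidisciplinary_team_within_department": 0.70,
                "across_departments": 0.40,
                "external_organizations": 0.10,
            },
            data_tier_probs={
                "genomic": (0.08, 0.32, 0.40, 0.20),
                "other_omics": (0.40, 0.35, 0.18, 0.07),
                "non_laboratory": (0.15, 0.40, 0.30, 0.15),
            },
            consistency_probs=(0.45, 0.40, 0.15),
            area_count_probs=(0.05, 0.25, 0.50, 0.14, 0.06),
            duration_log_mean=math.log(5.0),
            duration_log_sd=0.5,
        ),
        Archetype(
            name="enterprise_pioneer",
            discrete_probs={
                "testing_guidance": (0.00, 0.05, 0.35, 0.60),
                "leadership": (0.00, 0.05, 0.30, 0.65),
                "internal_funding": (0.02, 0.08, 0.35, 0.55),
            },
            utilization_probs={
                "standard_of_care": 0.95,
                "off_label_or_trial_matching": 0.85,
                "experimental_research": 0.70,
            },
            sharing_probs={
                "individual_physicians_only": 0.95,
                "multidisciplinary_team_within_department": 0.90,
                "across_departments": 0.85,
                "external_organizations": 0.60,
            },
            data_tier_probs={
                "genomic": (0.02, 0.13, 0.35, 0.50),
                "other_omics": (0.10, 0.25, 0.35, 0.30),
                "non_laboratory": (0.05, 0.20, 0.35, 0.40),
            },
            consistency_probs=(0.15, 0.40, 0.45),
            area_count_probs=(0.02, 0.08, 0.35, 0.30, 0.25),
            duration_log_mean=math.log(8.0),
            duration_log_sd=0.5,
        ),
    ]


class CohortSpec(BaseModel):
    """Declarative description of a synthetic cohort.

    ``archetype_mix`` weights align with ``archetypes``; metadata
    distributions default to the published survey demographics;
    ``level0_fraction`` is the probability of a zero-area (Level 0)
    organization — 0 by default, matching a survey frame that screens out
    organizations without PM initiatives. ``area_effect`` in [0, 1] couples
    criterion draws across an organization's clinical areas (0 =
    independent). ``quantize_durations`` rounds durations to a multiple of
    the given step, deliberately creating ties to exercise the canonical
    tie-break.
    """

    model_config = ConfigDict(frozen=True)

    n_orgs: int = Field(ge=1)
    seed: int = 0
    archetypes: list[Archetype] = Field(default_factory=default_archetypes)
    archetype_mix: Optional[tuple[float, ...]] = None
    level0_fraction: float = Field(default=0.0, ge=0, le=1)
    area_effect: float = Field(default=0.0, ge=0, le=1)
    quantize_durations: Optional[float] = Field(default=None, gt=0)
    practice_type_probs: dict[PracticeType, float] = Field(
        default_factory=lambda: dict(DEFAULT_PRACTICE_TYPE)
    )
    affiliation_probs: dict[Affiliation, float] = Field(
        default_factory=lambda: dict(DEFAULT_AFFILIATION)
    )
    demographic_probs: dict[Demographic, float] = Field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHIC)
    )
    region_probs: dict[Region, float] = Field(default_factory=lambda: dict(DEFAULT_REGION))

    @field_validator("archetypes")
    @classmethod
    def _nonempty(cls, v: list[Archetype]) -> list[Archetype]:
        if not v:
            raise ValueError("at least one archetype is required")
        return v

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        mix = self.mixture_weights()
        if len(mix) != len(self.archetypes):
            raise ValueError(
                f"archetype_mix has {len(mix)} weights for {len(self.archetypes)} archetypes"
            )
        _check_simplex(mix, "archetype_mix")
        for name, probs in (
            ("practice_type_probs", self.practice_type_probs),
            ("affiliation_probs", self.affiliation_probs),
            ("demographic_probs", self.demographic_probs),
            ("region_probs", self.region_probs),
        ):
            _check_simplex(list(probs.values()), name)
        return self

    def mixture_weights(self) -> tuple[float, ...]:
        if self.archetype_mix is not None:
            return self.archetype_mix
        k = len(self.archetypes)
        return tuple(1.0 / k for _ in range(k))


def _draw_cat(rng: np.random.Generator, categories: Sequence, probs: Sequence[float], u: float | None = None):
    """Inverse-CDF categorical draw; a supplied uniform enables coupling."""
    if u is None:
        u = rng.random()
    acc = 0.0
    for cat, p in zip(categories, probs):
        acc += p
        if u < acc:
            return cat
    return categories[-1]


def _coupled_uniform(rng: np.random.Generator, u_org: float, rho: float) -> float:
    # With probability rho reuse the org-level uniform (common random number),
    # preserving each marginal while correlating draws across areas.
    if rho > 0 and rng.random() < rho:
        return u_org
    return rng.random()


def _sample_area(
    arch: Archetype,
    area: ClinicalArea,
    duration: float,
    rng: np.random.Generator,
    u_org: float,
    rho: float,
) -> AreaResponse:
    kw: dict = {"area": area, "duration_years": duration}
    for crit in ("testing_guidance", "leadership", "internal_funding"):
        kw[crit] = _draw_cat(rng, _DISCRETE, arch.discrete_probs[crit], _coupled_uniform(rng, u_org, rho))
    kw["utilization"] = {
        f: bool(_coupled_uniform(rng, u_org, rho) < arch.utilization_probs[f]) for f in UTILIZATION_FLAGS
    }
    kw["sharing"] = {
        f: bool(_coupled_uniform(rng, u_org, rho) < arch.sharing_probs[f]) for f in SHARING_FLAGS
    }
    for crit in ("genomic", "other_omics", "non_laboratory"):
        tier = _draw_cat(rng, _TIERS, arch.data_tier_probs[crit], _coupled_uniform(rng, u_org, rho))
        if tier is DataTier.NONE:
            kw[crit] = DataCollectionResponse()
        else:
            cons = _draw_cat(rng, _CONSISTENCY, arch.consistency_probs, _coupled_uniform(rng, u_org, rho))
            kw[crit] = DataCollectionResponse(tier=tier, consistency=cons)
    return AreaResponse(**kw)


def _sample_metadata(spec: CohortSpec, rng: np.random.Generator) -> dict:
    lo, hi, _ = _draw_cat(
        rng,
        DEFAULT_HOSPITAL_BINS,
        [b[2] for b in DEFAULT_HOSPITAL_BINS],
    )
    return {
        "practice_type": _draw_cat(rng, list(spec.practice_type_probs), list(spec.practice_type_probs.values())),
        "affiliation": _draw_cat(rng, list(spec.affiliation_probs), list(spec.affiliation_probs.values())),
        "demographic": _draw_cat(rng, list(spec.demographic_probs), list(spec.demographic_probs.values())),
        "region": _draw_cat(rng, list(spec.region_probs), list(spec.region_probs.values())),
        "n_hospitals": int(rng.integers(lo, hi + 1)),
        "respondent_role": "lab_director",
    }


def sample_org(spec: CohortSpec, rng: np.random.Generator, org_id: str = "org0001") -> OrgResponse:
    """Draw one organization: archetype, metadata, areas, criterion responses."""
    meta = _sample_metadata(spec, rng)
    if rng.random() < spec.level0_fraction:
        return OrgResponse(org_id=org_id, areas=[], **meta)
    arch = _draw_cat(rng, spec.archetypes, spec.mixture_weights())
    n_areas = _draw_cat(rng, (1, 2, 3, 4, 5), arch.area_count_probs)
    order = canonical_area_order()
    chosen_idx = sorted(rng.choice(5, size=n_areas, replace=False).tolist())
    u_org = rng.random()
    areas = []
    for i in chosen_idx:
        duration = float(rng.lognormal(arch.duration_log_mean, arch.duration_log_sd))
        if spec.quantize_durations is not None:
            step = spec.quantize_durations
            duration = round(duration / step) * step
        areas.append(_sample_area(arch, order[i], duration, rng, u_org, spec.area_effect))
    return OrgResponse(org_id=org_id, areas=areas, **meta)


def generate_cohort(spec: CohortSpec) -> list[OrgResponse]:
    """Generate a full cohort, fully determined by the spec (incl. its seed)."""
    rng = np.random.default_rng(spec.seed)
    return [sample_org(spec, rng, org_id=f"org{i + 1:04d}") for i in range(spec.n_orgs)]


def spec_from_config(path, **overrides) -> CohortSpec:
    """Build a CohortSpec from a YAML/JSON config file; omitted keys take defaults.

    ``archetypes`` in the file may be a list of archetype mappings or be
    omitted to use the three shipped defaults. Keyword overrides (e.g.
    ``n_orgs``, ``seed`` from the command line) win over file values.
    """
    raw = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping of CohortSpec fields")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return CohortSpec.model_validate(raw)
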