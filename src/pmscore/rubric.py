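"""Controlled vocabularies and record types for the PM-integration rubric.

Personalized medicine (PM) integration is assessed per clinical area against
eight criteria. Three criteria (testing guidance and data accessibility,
leadership, internal funding) are *discrete*: a single tier describes the
organization. Two criteria (data utilization, data sharing) are *breadth*
checklists of independent statements. Three criteria (genomic, other-omics
and non-laboratory data collection) are *breadth-and-consistency*: the most
advanced collection technique sets a baseline that a physician-ordering
consistency multiplier scales.

This module is the single source of truth for the vocabularies: every other
module imports its enumerations and record types, and every file format uses
the lowercase snake-case member values below as its canonical tokens.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "ClinicalArea",
    "DiscreteTier",
    "DataTier",
    "ConsistencyLevel",
    "PracticeType",
    "Affiliation",
    "Demographic",
    "Region",
    "UtilizationFlags",
    "SharingFlags",
    "DataCollectionResponse",
    "AreaResponse",
    "OrgResponse",
    "canonical_area_order",
    "CRITERIA",
    "DISCRETE_CRITERIA",
    "DATA_CRITERIA",
    "UTILIZATION_FLAGS",
    "SHARING_FLAGS",
]


class _OrderedToken(str, Enum):
    """String enum with declaration-order ranks and case-insensitive lookup."""

    @classmethod
    def _missing_(cls, value: object):
        if isinstance(value, str):
            token = value.strip().lower()
            for member in cls:
                if member.value == token:
                    return member
        return None

    @property
    def rank(self) -> int:
        """Position in declaration order; used for ordered comparisons."""
        return list(type(self)).index(self)


class ClinicalArea(_OrderedToken):
    """The five clinical areas scored independently.

    Declaration order is the canonical order used for deterministic
    tie-breaking when program durations are equal.
    """

    ONCOLOGY = "oncology"
    PRENATAL_NEONATAL_SCREENING = "prenatal_neonatal_screening"
    PHARMACOGENOMICS_CHRONIC_DISEASE = "pharmacogenomics_chronic_disease"
    RARE_UNDIAGNOSED_DISEASE = "rare_undiagnosed_disease"
    HEALTHY_PATIENT_SCREENING = "healthy_patient_screening"


class DiscreteTier(_OrderedToken):
    """Tier of a discrete criterion; ``none`` means the criterion is unmet.

    For testing guidance: tier1 is physician-driven manual ordering, tier2
    recommended pathways with manual EHR entry, tier3 automatic EHR results
    integration. For leadership: individual champions / department-level
    initiatives / C-suite support. For internal funding: <25% / 25-60% / >60%
    funded internally.
    """

    NONE = "none"
    TIER1 = "tier1"
    TIER2 = "tier2"
    TIER3 = "tier3"


class DataTier(_OrderedToken):
    """Most advanced data-collection technique for a data criterion.

    Genomic: disparate biomarkers / multigene hotspot panels / WGS-WES.
    Other omics and non-laboratory: any one / any two / all three of the
    listed data types.
    """

    NONE = "none"
    TIER1 = "tier1"
    TIER2 = "tier2"
    TIER3 = "tier3"


class ConsistencyLevel(_OrderedToken):
    """Breadth of physician ordering for a data criterion."""

    NONE = "none"
    SOME = "some"
    MOST = "most"
    ALL = "all"


class PracticeType(_OrderedToken):
    HEALTH_SYSTEM = "health_system"
    INDEPENDENT_HOSPITAL = "independent_hospital"
    INTEGRATED_DELIVERY_NETWORK = "integrated_delivery_network"


class Affiliation(_OrderedToken):
    ACADEMIC = "academic"
    COMMUNITY_TEACHING = "community_teaching"
    COMMUNITY_NONTEACHING = "community_nonteaching"


class Demographic(_OrderedToken):
    URBAN = "urban"
    SUBURBAN = "suburban"
    RURAL = "rural"


class Region(_OrderedToken):
    SOUTH = "south"
    NORTHEAST = "northeast"
    MIDWEST = "midwest"
    WEST = "west"


#: Canonical names of the eight criteria, in rubric order.
CRITERIA: tuple[str, ...] = (
    "testing_guidance",
    "leadership",
    "internal_funding",
    "utilization",
    "sharing",
    "genomic",
    "other_omics",
    "non_laboratory",
)

DISCRETE_CRITERIA: tuple[str, ...] = ("testing_guidance", "leadership", "internal_funding")
DATA_CRITERIA: tuple[str, ...] = ("genomic", "other_omics", "non_laboratory")

UTILIZATION_FLAGS: tuple[str, ...] = (
    "standard_of_care",
    "off_label_or_trial_matching",
    "experimental_research",
)

SHARING_FLAGS: tuple[str, ...] = (
    "individual_physicians_only",
    "multidisciplinary_team_within_department",
    "across_departments",
    "external_organizations",
)


def canonical_area_order() -> list[ClinicalArea]:
    """The five clinical areas in their fixed canonical order.

    Oncology first; used as the deterministic tie-break when selecting the
    longest-running areas for the composite level.
    """
    return list(ClinicalArea)


class UtilizationFlags(BaseModel):
    """Checklist for the data-utilization criterion (one-third point each)."""

    model_config = ConfigDict(validate_assignment=True)

    standard_of_care: bool = False
    off_label_or_trial_matching: bool = False
    experimental_research: bool = False

    def count(self) -> int:
        return sum(getattr(self, f) for f in UTILIZATION_FLAGS)


class SharingFlags(BaseModel):
    """Checklist for the data-sharing criterion (one-fourth point each).

    The four statements are scored as independent checkboxes as printed in
    the rubric, even though the first ("data only utilized by individual
    physicians") reads as exclusive of the others.
    """

    model_config = ConfigDict(validate_assignment=True)

    individual_physicians_only: bool = False
    multidisciplinary_team_within_department: bool = False
    across_departments: bool = False
    external_organizations: bool = False

    def count(self) -> int:
        return sum(getattr(self, f) for f in SHARING_FLAGS)


class DataCollectionResponse(BaseModel):
    """Tier plus ordering consistency for one data-collection criterion."""

    model_config = ConfigDict(validate_assignment=True)

    tier: DataTier = DataTier.NONE
    consistency: ConsistencyLevel = ConsistencyLevel.NONE

    @model_validator(mode="after")
    def _tier_consistency_paired(self) -> "DataCollectionResponse":
        # tier none <=> consistency none: you cannot order nothing
        # consistently, nor collect something that nobody orders.
        if (self.tier is DataTier.NONE) != (self.consistency is ConsistencyLevel.NONE):
            raise ValueError(
                f"tier={self.tier.value!r} is inconsistent with "
                f"consistency={self.consistency.value!r}: 'none' must pair with 'none'"
            )
        return self


class AreaResponse(BaseModel):
    """Raw survey answers for all eight criteria in one clinical area."""

    model_config = ConfigDict(validate_assignment=True)

    area: ClinicalArea
    duration_years: float = Field(ge=0, description="Years the PM program has run")
    testing_guidance: DiscreteTier = DiscreteTier.NONE
    leadership: DiscreteTier = DiscreteTier.NONE
    internal_funding: DiscreteTier = DiscreteTier.NONE
    utilization: UtilizationFlags = Field(default_factory=UtilizationFlags)
    sharing: SharingFlags = Field(default_factory=SharingFlags)
    genomic: DataCollectionResponse = Field(default_factory=DataCollectionResponse)
    other_omics: DataCollectionResponse = Field(default_factory=DataCollectionResponse)
    non_laboratory: DataCollectionResponse = Field(default_factory=DataCollectionResponse)
    extras: dict[str, str] = Field(default_factory=dict)


class OrgResponse(BaseModel):
    """One organization's survey record: metadata plus 0-5 area responses.

    An empty ``areas`` list encodes a self-reported "no PM approaches"
    organization, which is assigned composite Level 0.
    """

    model_config = ConfigDict(validate_assignment=True)

    org_id: str = Field(min_length=1)
    practice_type: PracticeType
    affiliation: Affiliation
    demographic: Demographic
    region: Region
    n_hospitals: int = Field(default=1, ge=1)
    respondent_role: str = ""
    areas: list[AreaResponse] = Field(default_factory=list)
    extras: dict[str, str] = Field(default_factory=dict)

    @field_validator("areas")
    @classmethod
    def _distinct_areas(cls, areas: list[AreaResponse]) -> list[AreaResponse]:
        if len(areas) > 5:
            raise ValueError(f"an organization has at most 5 areas, got {len(areas)}")
        seen: set[ClinicalArea] = set()
        for a in areas:
            if a.area in seen:
                raise ValueError(f"duplicate clinical area {a.area.value!r}")
            seen.add(a.area)
        return areas
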