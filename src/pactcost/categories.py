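"""Cost categories and analytic perspectives.

A cost-consequence analysis reports costs under named *perspectives*: the
healthcare service perspective (costs falling on the health system), a broader
service perspective (adding education and social care), and a societal
perspective (adding family economic impacts: parental productivity losses and
informal, i.e. unpaid, care). Out-of-pocket family expenses form a ninth
category that is excluded from every built-in perspective and only enters when
a sensitivity analysis explicitly configures it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class CostCategory(str, enum.Enum):
    """Closed enumeration of cost categories; every item maps to exactly one."""

    PACT_DELIVERY = "pact_delivery"
    SPEECH_LANGUAGE_THERAPY = "speech_language_therapy"
    COMMUNITY_HEALTH_SOCIAL = "community_health_social"
    HOSPITAL_HEALTH = "hospital_health"
    EDUCATION_CHILDCARE = "education_childcare"
    SOCIAL_CARE = "social_care"
    PARENTAL_PRODUCTIVITY = "parental_productivity"
    PARENTAL_INFORMAL_CARE = "parental_informal_care"
    OUT_OF_POCKET = "out_of_pocket"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories denominated in hours rather than service events. They are priced
#: by the national average wage (human capital approach) and the market price
#: of a formal caregiver (proxy good approach) respectively, not by an
#: item-level unit-cost entry.
HOURLY_CATEGORIES = frozenset(
    {CostCategory.PARENTAL_PRODUCTIVITY, CostCategory.PARENTAL_INFORMAL_CARE}
)

HEALTHCARE_CATEGORIES = frozenset(
    {
        CostCategory.PACT_DELIVERY,
        CostCategory.SPEECH_LANGUAGE_THERAPY,
        CostCategory.COMMUNITY_HEALTH_SOCIAL,
        CostCategory.HOSPITAL_HEALTH,
    }
)

BROADER_CATEGORIES = HEALTHCARE_CATEGORIES | {
    CostCategory.EDUCATION_CHILDCARE,
    CostCategory.SOCIAL_CARE,
}

SOCIETAL_CATEGORIES = BROADER_CATEGORIES | {
    CostCategory.PARENTAL_PRODUCTIVITY,
    CostCategory.PARENTAL_INFORMAL_CARE,
}


@dataclass(frozen=True)
class PerspectiveSpec:
    """A named set of cost categories aggregated into one incremental cost."""

    name: str
    categories: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", frozenset(self.categories))

    def __contains__(self, category: CostCategory) -> bool:
        return category in self.categories


HEALTHCARE_SERVICE = PerspectiveSpec("healthcare_service", HEALTHCARE_CATEGORIES)
BROADER_SERVICE = PerspectiveSpec("broader_service", BROADER_CATEGORIES)
SOCIETAL = PerspectiveSpec("societal", SOCIETAL_CATEGORIES)

DEFAULT_PERSPECTIVES = {
    p.name: p for p in (HEALTHCARE_SERVICE, BROADER_SERVICE, SOCIETAL)
}

#: Default ordering of the societal categories in waterfall decompositions:
#: intervention delivery first, then health services, then education/social
#: care, then family impacts.
WATERFALL_ORDER = (
    CostCategory.PACT_DELIVERY,
    CostCategory.SPEECH_LANGUAGE_THERAPY,
    CostCategory.COMMUNITY_HEALTH_SOCIAL,
    CostCategory.HOSPITAL_HEALTH,
    CostCategory.EDUCATION_CHILDCARE,
    CostCategory.SOCIAL_CARE,
    CostCategory.PARENTAL_PRODUCTIVITY,
    CostCategory.PARENTAL_INFORMAL_CARE,
)
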