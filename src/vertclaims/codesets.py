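"""Packaged code sets and domain constants.

The shipped HCPCS→BETOS crosswalk is a minimal (~60 code) subset spanning the
seven top-level BETOS groups; a full CMS crosswalk file can be supplied to any
function that accepts a ``crosswalk`` frame.  The revenue-code map covers the
facility revenue centers the generator emits, with operating/recovery-room
codes routed to ``unclassified``.
"""

from __future__ import annotations

import pandas as pd

BETOS_CATEGORIES = (
    "evaluation_management",
    "procedures",
    "imaging",
    "test",
    "durable_medical_equipment",
    "other",
    "unclassified",
)

SETTINGS = ("professional", "outpatient_facility", "inpatient_facility")

OWNERSHIP_TYPES = (
    "physician_owned",
    "local_hospital_owned",
    "multi_hospital_system_owned",
)
HOSPITAL_OWNERSHIP = frozenset(OWNERSHIP_TYPES[1:])

#: Specialties whose clinicians count as primary-care physicians for attribution.
PCP_SPECIALTIES = frozenset(
    {
        "family_practice",
        "general_practice",
        "geriatrics",
        "internal_medicine",
        "pediatrics",
    }
)

EXCLUSION_REASONS = (
    "none",
    "age_out_of_range",
    "not_continuously_enrolled",
    "no_pcp_visits",
    "spend_over_cap",
)

#: Annual spending cap for cohort inclusion, in cents (strictly-greater excluded).
SPEND_CAP_CENTS = 100_000 * 100

COHORT_AGE_MIN = 19
COHORT_AGE_MAX = 64

# Practice-size categories by attributed patients per organization-year.
PRACTICE_SIZE_BOUNDS = (500, 10_000, 15_000)

AGE_BAND_EDGES = (19, 30, 40, 55, 65)  # 19-29, 30-39, 40-54, 55-64
AGE_BAND_LABELS = ("19-29", "30-39", "40-54", "55-64")

HCPCS_TO_BETOS: dict[str, str] = {}

# evaluation & management: office/outpatient visits, preventive visits
for _c in (
    "99202", "99203", "99204", "99205",
    "99211", "99212", "99213", "99214", "99215",
    "99385", "99386", "99395", "99396", "99495",
):
    HCPCS_TO_BETOS[_c] = "evaluation_management"

# procedures (minor + ambulatory surgery)
for _c in (
    "10060", "11042", "17110", "20610", "29881", "43239",
    "45378", "45380", "47562", "49505", "59400", "66984",
):
    HCPCS_TO_BETOS[_c] = "procedures"

# imaging (plain film, CT, MRI, ultrasound, echo, mammography)
for _c in (
    "70450", "70551", "71045", "71046", "71250", "72100", "72148",
    "73721", "74177", "76700", "76805", "93306", "77067", "77063",
):
    HCPCS_TO_BETOS[_c] = "imaging"

# tests (chemistry panels, hematology, micro, venipuncture)
for _c in (
    "80048", "80053", "80061", "82947", "83036", "83721",
    "84443", "85025", "85610", "87086", "36415",
):
    HCPCS_TO_BETOS[_c] = "test"

# durable medical equipment
for _c in ("E0601", "E0110", "E0260", "K0001", "A4253", "L3806"):
    HCPCS_TO_BETOS[_c] = "durable_medical_equipment"

# other (therapy, psych, pulmonary, sleep, retinal photography)
for _c in ("97110", "97140", "92250", "92227", "90837", "94010", "95810"):
    HCPCS_TO_BETOS[_c] = "other"

#: Facility claims without a HCPCS code are classified by revenue center.
#: Operating/recovery room lines land in ``unclassified``.
REVENUE_TO_BETOS: dict[str, str] = {
    "0100": "other",              # all-inclusive room & board
    "0101": "other",
    "0270": "durable_medical_equipment",
    "0300": "test",               # laboratory, general
    "0301": "test",               # laboratory, chemistry
    "0320": "imaging",            # radiology, diagnostic
    "0350": "imaging",            # CT
    "0351": "imaging",
    "0402": "imaging",            # ultrasound
    "0450": "other",              # emergency room
    "0610": "imaging",            # MRI
    "0611": "imaging",
    "0360": "unclassified",       # operating room
    "0370": "unclassified",       # anesthesia/recovery
    "0710": "unclassified",       # recovery room
}

#: Default claims-detectable code sets for the HEDIS-style process measures.
QUALITY_CODES: dict[str, frozenset[str]] = {
    "hba1c": frozenset({"83036"}),
    "ldl": frozenset({"80061", "83721"}),
    "retinal_exam": frozenset({"92250", "92227"}),
    "mammography": frozenset({"77067", "77063"}),
}

QUALITY_MEASURES = ("readmit_30d", "hba1c", "ldl", "retinal_exam", "mammography")

#: CPT↔revenue-code crosswalk for the claims-per-member comparison.  Code sets
#: are disjoint across families (validated in tests).
TEST_FAMILY_CROSSWALK: dict[str, dict[str, frozenset[str]]] = {
    "chemistry": {
        "professional_codes": frozenset({"80048", "80053", "80061", "82947", "83036", "85025"}),
        "outpatient_revenue_codes": frozenset({"0300", "0301"}),
    },
    "xray": {
        "professional_codes": frozenset({"71045", "71046", "72100"}),
        "outpatient_revenue_codes": frozenset({"0320"}),
    },
    "ct": {
        "professional_codes": frozenset({"70450", "71250", "74177"}),
        "outpatient_revenue_codes": frozenset({"0350", "0351"}),
    },
    "mri": {
        "professional_codes": frozenset({"70551", "72148", "73721"}),
        "outpatient_revenue_codes": frozenset({"0610", "0611"}),
    },
    "ultrasound": {
        "professional_codes": frozenset({"76700", "76805", "93306"}),
        "outpatient_revenue_codes": frozenset({"0402"}),
    },
}


def betos_crosswalk_frame() -> pd.DataFrame:
    """The packaged HCPCS→BETOS crosswalk as a two-column frame."""
    return pd.DataFrame(
        sorted(HCPCS_TO_BETOS.items()), columns=["hcpcs", "betos_category"]
    )
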