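"""Clinical-genomic risk labeling: NCCN grouping, Decipher categories and
the Spratt combined score.

The Spratt clinical-genomic score assigns a numeric value 0–3 to the
NCCN risk group (low, favorable intermediate, unfavorable intermediate,
high/very high) and 0–2 to the Decipher category (low < 0.45,
intermediate in [0.45, 0.60), high >= 0.60) and sums them, giving a
six-tier score (0–5) collapsed into three tiers (low / intermediate /
high).  A lesion is **low risk** when either

(i)  NCCN low and Decipher low or intermediate, or
(ii) NCCN low or intermediate (favorable or unfavorable) and Decipher low.

A patient is low risk only if *all* of their lesions are; equivalently
the patient label is the worst (highest three-tier) lesion label.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

from radiorisk.io import ClinicalRecord, T_STAGES


class NccnGroup(IntEnum):
    LOW = 0
    FAVORABLE_INTERMEDIATE = 1
    UNFAVORABLE_INTERMEDIATE = 2
    HIGH_OR_VERY_HIGH = 3


class DecipherCategory(IntEnum):
    LOW = 0
    INTERMEDIATE = 1
    HIGH = 2


class ThreeTier(IntEnum):
    LOW = 0
    INTERMEDIATE = 1
    HIGH = 2


#: Decipher cutoffs; boundaries are half-open: [0, .45) low,
#: [.45, .60) intermediate, [.60, 1] high
DECIPHER_CUTOFFS = (0.45, 0.60)


@dataclass(frozen=True)
class RiskRules:
    """Configurable pieces of the risk mapping.

    ``low_includes_unfavorable`` controls reading of "low-or-intermediate
    NCCN" in the low-risk rule: the default includes both intermediate
    subgroups; the strict variant admits favorable intermediate only.
    ``high_min_numeric`` is the smallest six-tier score labeled high.
    """

    low_includes_unfavorable: bool = True
    high_min_numeric: int = 4


@dataclass(frozen=True)
class RiskLabels:
    nccn_group: NccnGroup
    decipher_category: DecipherCategory
    spratt_numeric: int
    three_tier: ThreeTier
    low_risk: bool


def decipher_category(score: float) -> DecipherCategory:
    """Categorize a Decipher score using the 0.45 / 0.60 cutoffs."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"Decipher score must be in [0, 1], got {score}")
    lo, hi = DECIPHER_CUTOFFS
    if score < lo:
        return DecipherCategory.LOW
    if score < hi:
        return DecipherCategory.INTERMEDIATE
    return DecipherCategory.HIGH


def _t_stage_at_least(t_stage: str, threshold: str) -> bool:
    return T_STAGES.index(t_stage) >= T_STAGES.index(threshold)


def nccn_group(record: ClinicalRecord) -> NccnGroup:
    """NCCN risk group from T stage, grade group and PSA.

    Default rule table: low requires organ-confined <= T2a, grade group
    1 and PSA < 10; high/very-high is triggered by any of T >= T3a,
    grade group >= 4 or PSA > 20; everything else is intermediate,
    split favorable/unfavorable by requiring a single intermediate risk
    factor (T2b–T2c, grade group 2–3, or PSA 10–20), grade group <= 2
    and < 50% positive cores (unknown core counts are treated as < 50%).
    """
    if record.psa is None:
        raise ValueError("nccn_group requires psa (missing field: psa)")
    t, gg, psa = record.t_stage, record.grade_group, float(record.psa)

    if _t_stage_at_least(t, "T3a") or gg >= 4 or psa > 20:
        return NccnGroup.HIGH_OR_VERY_HIGH
    if not _t_stage_at_least(t, "T2b") and gg == 1 and psa < 10:
        return NccnGroup.LOW

    irf_count = sum(
        [
            _t_stage_at_least(t, "T2b"),      # T2b–T2c
            gg in (2, 3),
            10 <= psa <= 20,
        ]
    )
    cores_ok = record.pct_positive_cores is None or record.pct_positive_cores < 0.5
    if irf_count <= 1 and gg <= 2 and cores_ok:
        return NccnGroup.FAVORABLE_INTERMEDIATE
    return NccnGroup.UNFAVORABLE_INTERMEDIATE


def spratt_labels(
    nccn: NccnGroup,
    decipher: DecipherCategory,
    rules: RiskRules | None = None,
) -> RiskLabels:
    """Combine NCCN group and Decipher category into the Spratt labels."""
    rules = rules or RiskRules()
    numeric = int(nccn) + int(decipher)

    nccn_low_or_int = (
        nccn <= NccnGroup.UNFAVORABLE_INTERMEDIATE
        if rules.low_includes_unfavorable
        else nccn <= NccnGroup.FAVORABLE_INTERMEDIATE
    )
    low = (
        (nccn == NccnGroup.LOW and decipher <= DecipherCategory.INTERMEDIATE)
        or (nccn_low_or_int and decipher == DecipherCategory.LOW)
    )
    if low:
        tier = ThreeTier.LOW
    elif numeric >= rules.high_min_numeric:
        tier = ThreeTier.HIGH
    else:
        tier = ThreeTier.INTERMEDIATE
    return RiskLabels(nccn, decipher, numeric, tier, low)


def lesion_labels(
    record: ClinicalRecord,
    decipher_score: float,
    rules: RiskRules | None = None,
) -> RiskLabels:
    """Convenience: labels straight from a clinical record and Decipher score."""
    return spratt_labels(nccn_group(record), decipher_category(decipher_score), rules)


def patient_label(labels: list[RiskLabels]) -> RiskLabels:
    """Patient-level label: the worst (highest three-tier) lesion label.

    The patient is low risk iff every lesion is; this is consistent with
    taking the maximum three-tier label because a lesion is low risk
    exactly when its tier is low.
    """
    if not labels:
        raise ValueError("patient_label requires at least one lesion")
    return max(labels, key=lambda lab: (lab.three_tier, lab.spratt_numeric))
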