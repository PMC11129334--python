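"""Sibling surveillance decision rule for highly heritable embryonal tumors
(retinoblastoma being the prototype).

A proband's negative germline result does not by itself reduce sibling risk
to population level — germline detection can fail, and parental gonadal
mosaicism remains possible. Both residual risks are excluded when *two*
distinct somatic inactivating events are identified in the tumor and shown
to be absent in the proband's blood: the tumor is then sporadic, siblings
carry population risk only, and serial examinations under anesthesia can be
dropped (13 examinations per sibling over the first four years of life).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

GERMLINE_STATUSES = ("positive", "negative", "not_tested")
RECOMMENDATIONS = (
    "population_risk_no_surveillance",
    "surveillance_recommended",
    "genetic_counselling_carrier_testing",
)

#: examinations under anesthesia avoided per sibling released from
#: surveillance during the first four years of life (informational)
EXAMINATIONS_AVOIDED = 13


@dataclass
class SiblingRiskCall:
    germline_status: str
    somatic_biallelic: bool
    hits_absent_in_blood: bool
    recommendation: str
    examinations_avoided: int = 0
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if self.recommendation == "population_risk_no_surveillance" and not (
            self.germline_status == "negative"
            and self.somatic_biallelic
            and self.hits_absent_in_blood
        ):
            raise ValueError(
                "population-risk release requires negative germline, biallelic "
                "somatic inactivation, and blood-confirmed absence"
            )


def call_sibling_risk(
    germline_status: str,
    n_somatic_hits: int,
    blood_checked: bool,
) -> SiblingRiskCall:
    """Convert integrated germline + tumor results into a sibling
    recommendation.

    ``n_somatic_hits`` counts distinct somatic inactivating events in the
    gene (a second mutation, structural variant, or CN-LOH duplicating the
    first hit each count); ``blood_checked`` is True when those events were
    confirmed absent in blood.
    """
    if germline_status not in GERMLINE_STATUSES:
        raise ValueError(f"unknown germline status {germline_status!r}")
    if n_somatic_hits < 0:
        raise ValueError("n_somatic_hits must be >= 0")
    biallelic = n_somatic_hits >= 2

    if germline_status == "positive":
        return SiblingRiskCall(
            germline_status, biallelic, blood_checked,
            "genetic_counselling_carrier_testing",
        )
    if germline_status == "negative" and biallelic and blood_checked:
        return SiblingRiskCall(
            germline_status, True, True,
            "population_risk_no_surveillance",
            examinations_avoided=EXAMINATIONS_AVOIDED,
        )
    warning = None
    if germline_status == "negative" and biallelic and not blood_checked:
        warning = (
            "two somatic hits found but not confirmed absent in blood; "
            "blood check required before releasing siblings from surveillance"
        )
    return SiblingRiskCall(
        germline_status, biallelic, blood_checked,
        "surveillance_recommended", warning=warning,
    )
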