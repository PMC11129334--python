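"""Clinical screening-criteria form: scoring and diagnostic-yield
stratification.

Four criteria are assessed per child at inclusion:

* **family history** — cancer in the family or parental consanguinity;
* **multiple primary** — synchronous or metachronous multiple primary
  malignancies;
* **other features** — at least one non-cancer related feature (coded
  vocabulary: cognitive/behavioral disorder, skin manifestation, congenital
  malformation, intellectual disability / developmental delay, other);
* **malignancy type** — the tumor type itself carries a strong known
  association with predisposition.

A form section that was not completed scores ``missing`` (not
``not_fulfilled``) and drops out of the evaluable denominator, which is why
per-criterion denominators vary across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import binomial_ci

CRITERIA = ("family_history", "multiple_primary", "other_features", "malignancy_type")

DEFAULT_FEATURE_VOCABULARY = frozenset(
    {
        "cognitive_behavioral",
        "skin_manifestation",
        "congenital_malformation",
        "id_dd",  # intellectual disability / developmental delay
        "other",
    }
)

#: tumor types with a strong prior association to germline predisposition
DEFAULT_MALIGNANCY_LIST = frozenset(
    {
        "retinoblastoma",
        "high_grade_astrocytoma",
        "wilms_tumor",
        "renal_tumor",
        "medulloblastoma_shh",
        "pleuropulmonary_blastoma",
        "adrenocortical_carcinoma",
    }
)


@dataclass
class CriteriaRecord:
    """Raw per-patient form content; ``None`` marks a missing section."""

    family_history: Optional[bool]
    multiple_primary: Optional[bool]
    other_features: Optional[tuple[str, ...]]  # coded features; None = missing
    diagnosis: str = "other"
    patient_id: Optional[str] = None


@dataclass
class CriteriaScore:
    status: dict[str, str]  # criterion -> fulfilled | not_fulfilled | missing
    n_fulfilled: int
    n_evaluable: int
    id_dd_flag: bool
    n_other_features: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_fulfilled <= self.n_evaluable <= 4:
            raise ValueError("invalid criterion counts")
        if self.id_dd_flag and self.n_other_features < 1:
            raise ValueError("id_dd_flag requires at least one recorded feature")


def score_criteria(
    r: CriteriaRecord,
    malignancy_list: frozenset = DEFAULT_MALIGNANCY_LIST,
    feature_vocabulary: frozenset = DEFAULT_FEATURE_VOCABULARY,
) -> CriteriaScore:
    """Score one record; unknown feature codes are an error."""
    status: dict[str, str] = {}

    for crit, value in (
        ("family_history", r.family_history),
        ("multiple_primary", r.multiple_primary),
    ):
        if value is None:
            status[crit] = "missing"
        else:
            status[crit] = "fulfilled" if value else "not_fulfilled"

    n_features = 0
    id_dd = False
    if r.other_features is None:
        status["other_features"] = "missing"
    else:
        unknown = [f for f in r.other_features if f not in feature_vocabulary]
        if unknown:
            raise ValueError(f"unknown feature code(s): {unknown}")
        n_features = len(r.other_features)
        id_dd = "id_dd" in r.other_features
        status["other_features"] = "fulfilled" if n_features >= 1 else "not_fulfilled"

    # malignancy type is derivable from the diagnosis, hence never missing
    status["malignancy_type"] = (
        "fulfilled" if r.diagnosis in malignancy_list else "not_fulfilled"
    )

    return CriteriaScore(
        status=status,
        n_fulfilled=sum(1 for s in status.values() if s == "fulfilled"),
        n_evaluable=sum(1 for s in status.values() if s != "missing"),
        id_dd_flag=id_dd,
        n_other_features=n_features,
    )


def stratify_yield(
    n_fulfilled: Sequence[int],
    chicap_diagnosis: Sequence[bool],
    level: float = 0.95,
) -> pd.DataFrame:
    """Diagnostic yield by number of fulfilled criteria (strata 0-4).

    Returns one row per stratum with patient count, number of molecular
    diagnoses, the yield fraction, and its exact binomial CI. Empty strata
    report n=0 with undefined (NaN) yield.
    """
    if len(n_fulfilled) != len(chicap_diagnosis):
        raise ValueError("input lengths differ")
    nf = np.asarray(n_fulfilled)
    dx = np.asarray(chicap_diagnosis, dtype=bool)
    rows = []
    for k in range(5):
        mask = nf == k
        n = int(mask.sum())
        x = int(dx[mask].sum())
        if n > 0:
            lo, hi = binomial_ci(x, n, level)
            y = x / n
        else:
            lo = hi = y = float("nan")
        rows.append(
            {
                "n_criteria": k,
                "n_patients": n,
                "n_chicap": x,
                "yield": y,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)


def feature_prevalence(scores: Sequence[CriteriaScore],
                       records: Optional[Sequence[CriteriaRecord]] = None) -> dict:
    """Non-cancer feature prevalence over patients with an evaluable
    other-features section.

    Returns per-category counts (when records are supplied), the number of
    patients with >=1 and >=2 features, and the evaluable denominator.
    """
    evaluable = [s for s in scores if s.status["other_features"] != "missing"]
    n_eval = len(evaluable)
    out: dict = {
        "n_evaluable": n_eval,
        "n_ge1_feature": sum(1 for s in evaluable if s.n_other_features >= 1),
        "n_ge2_features": sum(1 for s in evaluable if s.n_other_features >= 2),
        "n_id_dd": sum(1 for s in evaluable if s.id_dd_flag),
    }
    out["prop_ge1_feature"] = out["n_ge1_feature"] / n_eval if n_eval else float("nan")
    out["prop_ge2_features"] = out["n_ge2_features"] / n_eval if n_eval else float("nan")
    if records is not None:
        counts: dict[str, int] = {}
        for r in records:
            if r.other_features is None:
                continue
            for f in set(r.other_features):
                counts[f] = counts.get(f, 0) + 1
        out["per_category"] = counts
    return out
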