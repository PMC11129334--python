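"""Germline reporting rules.

Implements the clinical gating applied to classified germline variants:

* panel membership (a variant outside the panel is never reported);
* pathogenicity (only P/LP classifications are reportable — ACMG-style
  classification labels are *inputs*, not computed here);
* genotype consistency with the gene's inheritance model, including the
  autosomal-recessive heterozygote suppression rule and its adult-onset
  dominant exception;
* parental-origin assignment (de novo / maternal / paternal / unknown);
* blood mosaicism flagging from the blood allele fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .panel import Panel, PanelGene

VARIANT_CLASSES = frozenset({"SNV", "INDEL", "SV_DEL", "SV_OTHER"})
ZYGOSITIES = frozenset(
    {"heterozygous", "homozygous", "hemizygous", "compound_het_partner"}
)
CLASSIFICATIONS = frozenset({"P", "LP", "VUS", "LB", "B"})
ORIGINS = frozenset({"de_novo", "maternal", "paternal", "unknown"})

#: default blood allele fraction below which a heterozygous call is
#: flagged as possibly mosaic (configurable; no published numeric rule).
DEFAULT_MOSAIC_AF_THRESHOLD = 0.30


class CompoundHetError(ValueError):
    """A compound_het_partner call without a located partner."""


@dataclass
class GermlineVariantCall:
    """One classified germline variant in one patient."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    gene: Optional[str]
    zygosity: str
    classification: str
    allele_fraction_blood: float = 0.5
    compound_group: Optional[str] = None
    origin: str = "unknown"
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if not 0.0 <= self.allele_fraction_blood <= 1.0:
            raise ValueError(
                f"allele_fraction_blood {self.allele_fraction_blood} outside [0, 1]"
            )
        if self.zygosity == "hemizygous" and self.chrom.lstrip("chr") not in ("X", "Y"):
            raise ValueError("hemizygous calls are only valid on X/Y")
        if self.gene is not None:
            self.gene = self.gene.upper()


@dataclass
class ReportDecision:
    """Outcome of the reporting gate for one germline variant.

    ``reportable`` is true exactly when ``reason`` is REPORTED or
    AR_HET_EXCEPTION. ``notes`` carries soft annotations (assumed phase for
    unphased compound heterozygotes, ambiguous carrier status for female
    X-linked heterozygotes).
    """

    reportable: bool
    reason: str
    mosaic_flag: bool = False
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ok = self.reason in ("REPORTED", "AR_HET_EXCEPTION")
        if self.reportable != ok:
            raise ValueError(
                f"reportable={self.reportable} inconsistent with reason={self.reason}"
            )


def flag_mosaic(
    v: GermlineVariantCall, mosaic_af_threshold: float = DEFAULT_MOSAIC_AF_THRESHOLD
) -> bool:
    """Flag possible blood mosaicism.

    True iff the call is heterozygous and its blood allele fraction falls
    strictly below the threshold (default 0.30). Homozygous/hemizygous calls
    are never flagged: their expected fraction is ~1.
    """
    return (
        v.zygosity == "heterozygous"
        and v.allele_fraction_blood < mosaic_af_threshold
    )


def gate_variant(
    v: GermlineVariantCall,
    g: Optional[PanelGene],
    partners: Sequence[GermlineVariantCall] = (),
    mosaic_af_threshold: float = DEFAULT_MOSAIC_AF_THRESHOLD,
) -> ReportDecision:
    """Decide whether one classified germline variant is reportable.

    ``partners`` are the other calls sharing ``v.compound_group`` in the same
    patient; they are required (and consulted for their P/LP status) only for
    compound_het_partner calls.

    Rules, in order: not in panel → NOT_PANEL; not P/LP → NOT_PLP; then the
    inheritance model decides — AD genes report any qualifying genotype; AR
    genes report homozygotes and in-trans P/LP pairs, and lone heterozygotes
    only via the adult-onset dominant exception; XL genes report hemizygous
    males and heterozygous females (the latter annotated as ambiguous
    carrier-vs-affected).
    """
    mosaic = flag_mosaic(v, mosaic_af_threshold)
    if g is None:
        return ReportDecision(False, "NOT_PANEL", mosaic)
    if v.classification not in ("P", "LP"):
        return ReportDecision(False, "NOT_PLP", mosaic)

    if g.inheritance == "AD":
        if v.zygosity == "compound_het_partner" and not partners:
            raise CompoundHetError(
                f"compound_group {v.compound_group!r}: no partner call found"
            )
        return ReportDecision(True, "REPORTED", mosaic)

    if g.inheritance == "AR":
        if v.zygosity == "homozygous":
            return ReportDecision(True, "REPORTED", mosaic)
        if v.zygosity == "compound_het_partner":
            if not partners:
                raise CompoundHetError(
                    f"compound_group {v.compound_group!r}: no partner call found"
                )
            if any(p.classification in ("P", "LP") for p in partners):
                # unphased pairs are assumed in trans when both alleles are
                # P/LP (clinical convention); the note records that assumption
                return ReportDecision(
                    True, "REPORTED", mosaic, notes=("assumed_in_trans",)
                )
            return ReportDecision(False, "AR_HET_SUPPRESSED", mosaic)
        if v.zygosity == "heterozygous":
            if g.adult_onset_dominant_exception:
                return ReportDecision(True, "AR_HET_EXCEPTION", mosaic)
            return ReportDecision(False, "AR_HET_SUPPRESSED", mosaic)
        return ReportDecision(False, "GENOTYPE_INCONSISTENT", mosaic)

    # XL
    if v.zygosity == "hemizygous":
        return ReportDecision(True, "REPORTED", mosaic)
    if v.zygosity in ("heterozygous", "homozygous"):
        notes = ("carrier_or_affected=ambiguous",) if v.zygosity == "heterozygous" else ()
        return ReportDecision(True, "REPORTED", mosaic, notes=notes)
    return ReportDecision(False, "GENOTYPE_INCONSISTENT", mosaic)


def assign_origin(
    child: GermlineVariantCall,
    mother_has: Optional[bool],
    father_has: Optional[bool],
) -> str:
    """Assign parental origin from parental carrier status.

    ``None`` means the parent was unavailable / untested. De novo requires
    confirmed absence in both parents. When both parents carry a variant the
    child has on one allele, the origin cannot be resolved without phasing;
    maternal is returned as a tie-break with a warning.
    """
    if mother_has is None or father_has is None:
        return "unknown"
    if not mother_has and not father_has:
        return "de_novo"
    if mother_has and father_has:
        warnings.warn(
            f"{child.gene or child.chrom}:{child.pos}: both parents carry the "
            "variant; returning maternal as tie-break",
            stacklevel=2,
        )
        return "maternal"
    return "maternal" if mother_has else "paternal"


def _partners_of(
    v: GermlineVariantCall, calls: Sequence[GermlineVariantCall]
) -> list[GermlineVariantCall]:
    if v.compound_group is None:
        return []
    return [c for c in calls if c is not v and c.compound_group == v.compound_group]


def report_cohort_germline(
    calls_by_patient: Mapping[str, Sequence[GermlineVariantCall]],
    panel: Panel,
    mosaic_af_threshold: float = DEFAULT_MOSAIC_AF_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the reporting gate over a whole cohort.

    Returns ``(findings, patient_status)``: one findings row per reportable
    variant, and one status row per patient with ``positive`` False for
    patients with no reportable variant.
    """
    finding_rows = []
    status_rows = []
    for patient_id, calls in calls_by_patient.items():
        n_reportable = 0
        for v in calls:
            if v.gene is not None:
                g = panel.get(v.gene)
            else:
                # un-annotated call: locate by position
                from .panel import gene_for_position

                try:
                    g = gene_for_position(panel, v.chrom, v.pos)
                except Exception:
                    g = None
                if g is not None:
                    v.gene = g.symbol
            decision = gate_variant(
                v, g, _partners_of(v, calls), mosaic_af_threshold
            )
            if decision.reportable:
                n_reportable += 1
                finding_rows.append(
                    {
                        "patient_id": patient_id,
                        "gene": v.gene,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "variant_class": v.variant_class,
                        "zygosity": v.zygosity,
                        "classification": v.classification,
                        "reason": decision.reason,
                        "origin": v.origin,
                        "mosaic": decision.mosaic_flag,
                        "notes": ";".join(decision.notes),
                    }
                )
        status_rows.append(
            {
                "patient_id": patient_id,
                "positive": n_reportable > 0,
                "n_reportable_variants": n_reportable,
            }
        )
    findings = pd.DataFrame(
        finding_rows,
        columns=[
            "patient_id", "gene", "chrom", "pos", "ref", "alt",
            "variant_class", "zygosity", "classification", "reason",
            "origin", "mosaic", "notes",
        ],
    )
    status = pd.DataFrame(
        status_rows, columns=["patient_id", "positive", "n_reportable_variants"]
    )
    return findings, status
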