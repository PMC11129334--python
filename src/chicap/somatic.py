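"""Paired tumor-normal integration: high-confidence somatic filtering,
SNV-based tumor mutational burden, and second-hit classification.

For a patient with a reported germline variant in a tumor-suppressor gene,
the somatic data are scanned for the event inactivating the remaining
allele. Categories, with the priority order used when several evidence
types co-occur:

1. ``inconclusive`` — too few somatic calls genome-wide to say anything
   (default: an empty call set), typically a non-representative biopsy;
2. ``second_mutation`` — a passing somatic SNV/INDEL inside the same gene;
3. ``structural_variant`` — an SV disrupting the gene, or a copy-number
   loss segment overlapping it;
4. ``cn_loh`` — copy-neutral loss of heterozygosity: the germline allele's
   tumor VAF exceeds 0.70 with no copy-number change over the gene, or a
   copy-neutral segment with deviated B-allele frequency covers the gene;
5. ``none`` — informative data but no second hit found.

Direct sequence evidence outranks structural evidence, which outranks the
allelic-imbalance inference; the order is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .panel import PanelGene, normalize_chrom

SECOND_HIT_CATEGORIES = (
    "second_mutation",
    "cn_loh",
    "structural_variant",
    "none",
    "inconclusive",
)


@dataclass
class SomaticVariantCall:
    """One somatic small variant from a tumor-normal pair."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # SNV | INDEL
    depth_tumor: int
    depth_normal: int
    allele_depth_tumor: int
    allele_fraction_tumor: float
    gene: Optional[str] = None
    trinucleotide_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in ("SNV", "INDEL"):
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.allele_depth_tumor > self.depth_tumor:
            raise ValueError("allele_depth_tumor exceeds depth_tumor")
        if not 0.0 <= self.allele_fraction_tumor <= 1.0:
            raise ValueError("allele_fraction_tumor outside [0, 1]")
        if self.gene is not None:
            self.gene = self.gene.upper()


@dataclass
class CopyNumberSegment:
    chrom: str
    start: int
    end: int
    copy_state: str  # loss | neutral | gain
    baf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.copy_state not in ("loss", "neutral", "gain"):
            raise ValueError(f"unknown copy_state {self.copy_state!r}")
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.baf is not None and not 0.0 <= self.baf <= 1.0:
            raise ValueError("baf outside [0, 1]")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (
            normalize_chrom(self.chrom) == normalize_chrom(chrom)
            and self.start <= end
            and start <= self.end
        )


@dataclass
class StructuralVariantCall:
    type: str  # DEL | DUP | INV | TRA
    chrom: str
    start: int
    end: int
    genes_disrupted: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in ("DEL", "DUP", "INV", "TRA"):
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.type != "TRA" and self.start > self.end:
            raise ValueError("SV start > end")
        self.genes_disrupted = tuple(g.upper() for g in self.genes_disrupted)


@dataclass(frozen=True)
class HighConfidenceFilter:
    """Strict (">") thresholds defining a high-confidence somatic call:
    coverage above 10 in both tumor and normal, alt allele depth in tumor
    above 3, tumor allele fraction above 0.05."""

    min_depth_exclusive: int = 10
    min_allele_depth_exclusive: int = 3
    min_allele_fraction_exclusive: float = 0.05


@dataclass(frozen=True)
class TmbConfig:
    """TMB denominator and hypermutation call.

    ``genome_size_mb`` defaults to the full hg19 assembly length in Mb;
    a non-N effective length may be supplied instead. A tumor is called
    hypermutated when TMB strictly exceeds ``hypermutation_threshold``
    mutations per Mb.
    """

    genome_size_mb: float = 3095.69
    hypermutation_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be > 0")


@dataclass
class TmbResult:
    n_passing_snvs: int
    tmb: float
    hypermutated: bool
    log10_tmb: Optional[float]


@dataclass(frozen=True)
class SecondHitConfig:
    cn_loh_vaf_threshold: float = 0.70
    min_informative_somatic_calls: int = 1
    baf_deviation: float = 0.2
    hc_filter: HighConfidenceFilter = HighConfidenceFilter()
    priority: tuple[str, ...] = ("second_mutation", "structural_variant", "cn_loh")


@dataclass
class SecondHitCall:
    category: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in SECOND_HIT_CATEGORIES:
            raise ValueError(f"unknown second-hit category {self.category!r}")


def pass_high_confidence(
    s: SomaticVariantCall, f: HighConfidenceFilter = HighConfidenceFilter()
) -> bool:
    """All four comparisons are strict (">")."""
    return (
        s.depth_tumor > f.min_depth_exclusive
        and s.depth_normal > f.min_depth_exclusive
        and s.allele_depth_tumor > f.min_allele_depth_exclusive
        and s.allele_fraction_tumor > f.min_allele_fraction_exclusive
    )


def compute_tmb(
    snvs: Iterable[SomaticVariantCall],
    f: HighConfidenceFilter = HighConfidenceFilter(),
    c: TmbConfig = TmbConfig(),
) -> TmbResult:
    """SNV-based tumor mutational burden.

    Counts high-confidence somatic SNVs (INDELs are ignored) and divides by
    the genome size in Mb. ``log10_tmb`` is None for a zero count.
    """
    n = sum(
        1 for s in snvs if s.variant_class == "SNV" and pass_high_confidence(s, f)
    )
    tmb = n / c.genome_size_mb
    return TmbResult(
        n_passing_snvs=n,
        tmb=tmb,
        hypermutated=tmb > c.hypermutation_threshold,
        log10_tmb=math.log10(tmb) if tmb > 0 else None,
    )


def _evidence_present(
    gene: PanelGene,
    tumor_vaf: Optional[float],
    somatic_small: Sequence[SomaticVariantCall],
    cn: Sequence[CopyNumberSegment],
    svs: Sequence[StructuralVariantCall],
    cfg: SecondHitConfig,
) -> dict:
    """Evaluate each evidence channel independently; the classifier then
    applies the priority order."""
    in_gene_hits = [
        s
        for s in somatic_small
        if pass_high_confidence(s, cfg.hc_filter)
        and (
            (s.gene is not None and s.gene == gene.symbol)
            or gene.contains(s.chrom, s.pos)
        )
    ]

    gene_cn = [seg for seg in cn if seg.overlaps(gene.chrom, gene.start, gene.end)]
    loss_over_gene = [seg for seg in gene_cn if seg.copy_state == "loss"]
    sv_hits = [
        sv
        for sv in svs
        if gene.symbol in sv.genes_disrupted
        or (
            sv.type != "TRA"
            and normalize_chrom(sv.chrom) == gene.chrom
            and sv.start <= gene.end
            and gene.start <= sv.end
        )
    ]

    non_neutral_over_gene = [seg for seg in gene_cn if seg.copy_state != "neutral"]
    vaf_cnloh = (
        tumor_vaf is not None
        and tumor_vaf > cfg.cn_loh_vaf_threshold
        and not non_neutral_over_gene
    )
    baf_cnloh = any(
        seg.copy_state == "neutral"
        and seg.baf is not None
        and abs(seg.baf - 0.5) > cfg.baf_deviation
        for seg in gene_cn
    )
    return {
        "second_mutation": bool(in_gene_hits),
        "structural_variant": bool(sv_hits) or bool(loss_over_gene),
        "cn_loh": vaf_cnloh or baf_cnloh,
        "_in_gene_hits": in_gene_hits,
        "_sv_hits": sv_hits,
        "_loss_over_gene": loss_over_gene,
        "_vaf_cnloh": vaf_cnloh,
        "_baf_cnloh": baf_cnloh,
    }


def classify_second_hit(
    gene: PanelGene,
    tumor_vaf_of_germline_allele: Optional[float],
    somatic_small: Sequence[SomaticVariantCall],
    cn: Sequence[CopyNumberSegment],
    svs: Sequence[StructuralVariantCall],
    cfg: SecondHitConfig = SecondHitConfig(),
) -> SecondHitCall:
    """Five-way second-hit classification for one germline finding.

    ``somatic_small`` is the genome-wide somatic small-variant call set of
    the tumor (used both for the informativeness check and for in-gene
    hits). A missing tumor VAF with no BAF-annotated segments skips the
    VAF branch of CN-LOH with a warning.
    """
    if not gene.tumor_suppressor:
        raise ValueError(
            f"{gene.symbol}: second-hit analysis applies to tumor-suppressor genes"
        )
    if len(somatic_small) < cfg.min_informative_somatic_calls:
        return SecondHitCall(
            "inconclusive",
            {"n_somatic_calls": len(somatic_small)},
        )
    if tumor_vaf_of_germline_allele is None and not any(
        seg.baf is not None for seg in cn
    ):
        warnings.warn(
            f"{gene.symbol}: tumor VAF of the germline allele missing and no "
            "BAF data; CN-LOH cannot be assessed",
            stacklevel=2,
        )
    ev = _evidence_present(
        gene, tumor_vaf_of_germline_allele, somatic_small, cn, svs, cfg
    )
    for category in cfg.priority:
        if ev[category]:
            if category == "second_mutation":
                hit = ev["_in_gene_hits"][0]
                detail = {"variant": f"{hit.chrom}:{hit.pos}{hit.ref}>{hit.alt}"}
            elif category == "structural_variant":
                detail = {
                    "n_svs": len(ev["_sv_hits"]),
                    "n_loss_segments": len(ev["_loss_over_gene"]),
                }
            else:
                detail = {
                    "tumor_vaf": tumor_vaf_of_germline_allele,
                    "baf_based": ev["_baf_cnloh"],
                }
            return SecondHitCall(category, detail)
    return SecondHitCall("none", {"tumor_vaf": tumor_vaf_of_germline_allele})
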