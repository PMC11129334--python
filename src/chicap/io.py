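"""File interfaces.

Readers use cyvcf2 for VCF 4.2 (germline single-sample and somatic
tumor-normal paired) and pandas for the tabular formats (copy-number
segments, structural variants, panel, cohort tables). Writers emit minimal
but standard-conformant VCF text so that the synthetic generator's output
round-trips through real-world readers.

Custom tags: germline VCFs carry ``CHICAP_CLASS`` (P/LP/VUS/LB/B) and
optionally ``CMPHET_GROUP``; somatic VCFs carry ``TNC`` (reference-strand
trinucleotide context).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .germline import GermlineVariantCall
from .somatic import CopyNumberSegment, SomaticVariantCall, StructuralVariantCall

_GERMLINE_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CHICAP_CLASS,Number=1,Type=String,Description="Variant classification (P/LP/VUS/LB/B)">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CMPHET_GROUP,Number=1,Type=String,Description="Compound-heterozygote group id">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_SOMATIC_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=TNC,Number=1,Type=String,Description="Reference-strand trinucleotide context">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _contig_lines(chroms: Iterable[str]) -> str:
    seen = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    return "".join(f"##contig=<ID={c}>\n" for c in seen)


def write_germline_vcf(
    calls: Sequence[GermlineVariantCall], path: str | Path, sample: str = "PROBAND"
) -> None:
    lines = []
    for v in calls:
        info = [f"CHICAP_CLASS={v.classification}"]
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.compound_group:
            info.append(f"CMPHET_GROUP={v.compound_group}")
        dp = 40
        if v.zygosity == "homozygous":
            gt, alt_reads = "1/1", round(dp * v.allele_fraction_blood)
        elif v.zygosity == "hemizygous":
            gt, alt_reads = "1", round(dp * v.allele_fraction_blood)
        else:
            gt, alt_reads = "0/1", round(dp * v.allele_fraction_blood)
        ref, alt = v.ref, v.alt
        if v.variant_class == "SV_DEL":
            alt = "<DEL>"
            info.append("SVTYPE=DEL")
            info.append(f"END={v.pos + max(1, len(v.ref)) - 1}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{ref}\t{alt}\t.\tPASS\t{';'.join(info)}"
            f"\tGT:AD:DP\t{gt}:{dp - alt_reads},{alt_reads}:{dp}"
        )
    with open(path, "w") as fh:
        fh.write(_GERMLINE_HEADER)
        fh.write(_contig_lines(v.chrom for v in calls))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_germline_vcf(path: str | Path, patient_id: Optional[str] = None
                      ) -> list[GermlineVariantCall]:
    """Parse a germline VCF into calls.

    Zygosity comes from GT (ploidy-1 genotypes are hemizygous), the blood
    allele fraction from AD/DP, the classification from ``CHICAP_CLASS``
    (default VUS when absent).
    """
    from cyvcf2 import VCF

    calls = []
    vcf = VCF(str(path))
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        if alt == "<DEL>" or (rec.INFO.get("SVTYPE") == "DEL"):
            vclass = "SV_DEL"
            alt_allele = rec.REF  # placeholder allele string for SVs
        elif len(rec.REF) == 1 and len(alt) == 1:
            vclass = "SNV"
            alt_allele = alt
        else:
            vclass = "INDEL"
            alt_allele = alt
        gts = rec.genotypes[0]
        alleles = [a for a in gts[:-1] if a is not None and a >= 0]
        if len(alleles) == 1:
            zyg = "hemizygous"
        elif all(a >= 1 for a in alleles):
            zyg = "homozygous"
        else:
            zyg = "heterozygous"
        group = rec.INFO.get("CMPHET_GROUP")
        if group is not None and zyg == "heterozygous":
            zyg = "compound_het_partner"
        try:
            ad = rec.format("AD")[0]
            dp = int(rec.format("DP")[0][0])
            af = float(ad[1]) / dp if dp > 0 else 0.0
        except Exception:
            af = 0.5
        calls.append(
            GermlineVariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt_allele,
                variant_class=vclass,
                gene=rec.INFO.get("GENE"),
                zygosity=zyg,
                classification=rec.INFO.get("CHICAP_CLASS", "VUS"),
                allele_fraction_blood=min(1.0, af),
                compound_group=group,
                patient_id=patient_id,
            )
        )
    vcf.close()
    return calls


def write_somatic_vcf(
    calls: Sequence[SomaticVariantCall],
    path: str | Path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> None:
    lines = []
    for s in calls:
        info = []
        if s.trinucleotide_context:
            info.append(f"TNC={s.trinucleotide_context}")
        if s.gene:
            info.append(f"GENE={s.gene}")
        ref_reads = s.depth_tumor - s.allele_depth_tumor
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
            f"{';'.join(info) or '.'}\tGT:AD:DP\t"
            f"0/1:{ref_reads},{s.allele_depth_tumor}:{s.depth_tumor}\t"
            f"0/0:{s.depth_normal},0:{s.depth_normal}"
        )
    with open(path, "w") as fh:
        fh.write(_SOMATIC_HEADER)
        fh.write(_contig_lines(s.chrom for s in calls))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{tumor_sample}\t{normal_sample}\n"
        )
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_somatic_vcf(
    path: str | Path, tumor_sample: str = "TUMOR", normal_sample: str = "NORMAL"
) -> list[SomaticVariantCall]:
    """Parse a tumor-normal paired somatic VCF into calls (AD/DP per sample)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        ti, ni = samples.index(tumor_sample), samples.index(normal_sample)
    except ValueError as exc:
        raise ValueError(
            f"samples {tumor_sample}/{normal_sample} not found in {samples}"
        ) from exc
    calls = []
    for rec in vcf:
        alt = rec.ALT[0]
        ad = rec.format("AD")
        dp = rec.format("DP")
        depth_t, depth_n = int(dp[ti][0]), int(dp[ni][0])
        alt_t = int(ad[ti][1])
        calls.append(
            SomaticVariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                variant_class="SNV" if len(rec.REF) == 1 and len(alt) == 1 else "INDEL",
                depth_tumor=depth_t,
                depth_normal=depth_n,
                allele_depth_tumor=alt_t,
                allele_fraction_tumor=alt_t / depth_t if depth_t else 0.0,
                gene=rec.INFO.get("GENE"),
                trinucleotide_context=rec.INFO.get("TNC"),
            )
        )
    vcf.close()
    return calls


# --- tabular formats --------------------------------------------------------

def write_cn_segments(segments: Sequence[CopyNumberSegment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "copy_state": s.copy_state,
             "baf": "" if s.baf is None else s.baf}
            for s in segments
        ],
        columns=["chrom", "start", "end", "copy_state", "baf"],
    ).to_csv(path, sep="\t", index=False)


def read_cn_segments(path: str | Path) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return [
        CopyNumberSegment(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            copy_state=str(r.copy_state),
            baf=None if pd.isna(r.baf) else float(r.baf),
        )
        for r in df.itertuples(index=False)
    ]


def write_svs(svs: Sequence[StructuralVariantCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"type": s.type, "chrom": s.chrom, "start": s.start, "end": s.end,
             "genes": ",".join(s.genes_disrupted)}
            for s in svs
        ],
        columns=["type", "chrom", "start", "end", "genes"],
    ).to_csv(path, sep="\t", index=False)


def read_svs(path: str | Path) -> list[StructuralVariantCall]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out = []
    for r in df.itertuples(index=False):
        genes = () if pd.isna(r.genes) or r.genes == "" else tuple(str(r.genes).split(","))
        out.append(
            StructuralVariantCall(
                type=str(r.type), chrom=str(r.chrom),
                start=int(r.start), end=int(r.end), genes_disrupted=genes,
            )
        )
    return out
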