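import itertools

import pytest

from chicap.germline import (
    CompoundHetError,
    GermlineVariantCall,
    ReportDecision,
    assign_origin,
    flag_mosaic,
    gate_variant,
    report_cohort_germline,
)
from chicap.panel import Panel, PanelGene


def _call(zygosity="heterozygous", classification="LP", gene="GENE1",
          chrom="1", af=0.5, group=None):
    return GermlineVariantCall(
        chrom=chrom, pos=100, ref="C", alt="T", variant_class="SNV",
        gene=gene, zygosity=zygosity, classification=classification,
        allele_fraction_blood=af, compound_group=group,
    )


def _gene(inheritance="AD", exception=False, chrom="1"):
    return PanelGene("GENE1", chrom, 1, 1_000_000, inheritance,
                     adult_onset_dominant_exception=exception)


# --- gating rules -----------------------------------------------------------

def test_ar_lone_heterozygote_suppressed():
    d = gate_variant(_call("heterozygous", "LP"), _gene("AR"))
    assert (d.reportable, d.reason) == (False, "AR_HET_SUPPRESSED")


def test_ar_heterozygote_adult_onset_exception():
    d = gate_variant(_call("heterozygous", "P"), _gene("AR", exception=True))
    assert (d.reportable, d.reason) == (True, "AR_HET_EXCEPTION")


def test_compound_het_pair_both_pathogenic_reportable():
    a = _call("compound_het_partner", "P", group="cg1")
    b = _call("compound_het_partner", "P", group="cg1")
    d = gate_variant(a, _gene("AR"), partners=[b])
    assert d.reportable and d.reason == "REPORTED"
    assert "assumed_in_trans" in d.notes


def test_compound_het_without_partner_raises():
    a = _call("compound_het_partner", "P", group="cg9")
    with pytest.raises(CompoundHetError, match="cg9"):
        gate_variant(a, _gene("AR"))


def test_vus_in_ad_gene_not_reported():
    d = gate_variant(_call("heterozygous", "VUS"), _gene("AD"))
    assert (d.reportable, d.reason) == (False, "NOT_PLP")


def test_off_panel_variant_not_reported():
    d = gate_variant(_call(), None)
    assert (d.reportable, d.reason) == (False, "NOT_PANEL")


def test_xl_hemizygous_male_and_female_carrier():
    g = _gene("XL", chrom="X")
    hemi = _call("hemizygous", "P", chrom="X")
    assert gate_variant(hemi, g).reportable
    het = _call("heterozygous", "P", chrom="X")
    d = gate_variant(het, g)
    assert d.reportable and "carrier_or_affected=ambiguous" in d.notes


def _oracle(classification, zygosity, inheritance, exception, partner_plp):
    """Independent truth table for the reporting gate."""
    if classification not in ("P", "LP"):
        return (False, "NOT_PLP")
    if inheritance == "AD":
        return (True, "REPORTED")
    if inheritance == "AR":
        if zygosity == "homozygous":
            return (True, "REPORTED")
        if zygosity == "compound_het_partner":
            return (True, "REPORTED") if partner_plp else (False, "AR_HET_SUPPRESSED")
        if zygosity == "heterozygous":
            return (True, "AR_HET_EXCEPTION") if exception else (False, "AR_HET_SUPPRESSED")
        return (False, "GENOTYPE_INCONSISTENT")
    # XL
    if zygosity in ("hemizygous", "heterozygous", "homozygous"):
        return (True, "REPORTED")
    return (False, "GENOTYPE_INCONSISTENT")


def test_gate_variant_matches_truth_table_oracle():
    """Exhaustive agreement over classification x zygosity x inheritance x
    exception flag x partner pathogenicity."""
    for classification, zygosity, inheritance, exception, partner_plp in itertools.product(
        ("P", "LP", "VUS", "LB", "B"),
        ("heterozygous", "homozygous", "hemizygous", "compound_het_partner"),
        ("AD", "AR", "XL"),
        (False, True),
        (False, True),
    ):
        if exception and inheritance != "AR":
            continue
        chrom = "X" if zygosity == "hemizygous" or inheritance == "XL" else "1"
        v = _call(zygosity, classification, chrom=chrom,
                  group="cg" if zygosity == "compound_het_partner" else None)
        partners = (
            [_call("compound_het_partner", "P" if partner_plp else "VUS",
                   chrom=chrom, group="cg")]
            if zygosity == "compound_het_partner"
            else []
        )
        got = gate_variant(v, _gene(inheritance, exception, chrom=chrom), partners)
        assert (got.reportable, got.reason) == _oracle(
            classification, zygosity, inheritance, exception, partner_plp
        ), (classification, zygosity, inheritance, exception, partner_plp)


def test_suppressing_exception_flag_never_adds_reportables():
    """Monotonicity: removing the adult-onset exception can only shrink
    the reportable set."""
    for classification in ("P", "LP", "VUS"):
        for zygosity in ("heterozygous", "homozygous"):
            with_flag = gate_variant(
                _call(zygosity, classification), _gene("AR", exception=True)
            ).reportable
            without = gate_variant(
                _call(zygosity, classification), _gene("AR", exception=False)
            ).reportable
            assert without <= with_flag


def test_report_decision_invariant_enforced():
    with pytest.raises(ValueError):
        ReportDecision(reportable=True, reason="NOT_PLP")


# --- mosaicism --------------------------------------------------------------

def test_flag_mosaic_threshold_and_zygosity():
    assert flag_mosaic(_call(af=0.12))
    assert not flag_mosaic(_call(af=0.48))
    assert not flag_mosaic(_call("homozygous", af=0.12))
    assert not flag_mosaic(_call(af=0.30))  # strict less-than


def test_flag_mosaic_monotone_in_allele_fraction():
    flags = [flag_mosaic(_call(af=af)) for af in (0.0, 0.1, 0.29, 0.3, 0.5, 1.0)]
    assert flags == sorted(flags, reverse=True)


# --- parental origin --------------------------------------------------------

@pytest.mark.parametrize(
    "mother,father,expected",
    [
        (False, False, "de_novo"),
        (None, False, "unknown"),
        (False, None, "unknown"),
        (True, False, "maternal"),
        (False, True, "paternal"),
    ],
)
def test_assign_origin(mother, father, expected):
    assert assign_origin(_call(), mother, father) == expected


def test_assign_origin_both_parents_tie_break_warns():
    with pytest.warns(UserWarning, match="both parents"):
        assert assign_origin(_call(), True, True) == "maternal"


# --- cohort reporting -------------------------------------------------------

def test_report_cohort_counts_positive_patients(panel):
    rb1 = panel.get("RB1")
    calls = {}
    for i in range(10):
        pid = f"P{i}"
        if i < 4:  # reportable het P in RB1
            calls[pid] = [
                GermlineVariantCall(
                    chrom=rb1.chrom, pos=rb1.start + 10, ref="C", alt="T",
                    variant_class="SNV", gene="RB1", zygosity="heterozygous",
                    classification="P",
                )
            ]
        elif i < 7:  # VUS only
            calls[pid] = [
                GermlineVariantCall(
                    chrom=rb1.chrom, pos=rb1.start + 10, ref="C", alt="T",
                    variant_class="SNV", gene="RB1", zygosity="heterozygous",
                    classification="VUS",
                )
            ]
        else:
            calls[pid] = []
    findings, status = report_cohort_germline(calls, panel)
    assert len(findings) == 4
    assert status.positive.sum() == 4
    assert len(status) == 10
    assert not status.set_index("patient_id").loc["P9", "positive"]


def test_report_cohort_empty_and_all_vus(panel):
    findings, status = report_cohort_germline({}, panel)
    assert findings.empty and status.empty
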