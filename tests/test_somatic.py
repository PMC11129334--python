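import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from chicap.panel import PanelGene
from chicap.somatic import (
    CopyNumberSegment,
    HighConfidenceFilter,
    SecondHitConfig,
    SomaticVariantCall,
    StructuralVariantCall,
    TmbConfig,
    classify_second_hit,
    compute_tmb,
    pass_high_confidence,
)

GENE = PanelGene("RB1", "13", 48_877_887, 49_056_122, "AD", tumor_suppressor=True)


def _snv(chrom="5", pos=1_000_000, dp_t=100, dp_n=50, ad=40, gene=None,
         variant_class="SNV"):
    return SomaticVariantCall(
        chrom=chrom, pos=pos, ref="C", alt="T", variant_class=variant_class,
        depth_tumor=dp_t, depth_normal=dp_n, allele_depth_tumor=ad,
        allele_fraction_tumor=ad / dp_t, gene=gene,
    )


# --- high-confidence filter -------------------------------------------------

@pytest.mark.parametrize(
    "dp_t,dp_n,ad,af,expected",
    [
        (11, 11, 4, 0.051, True),   # just above every strict bound
        (10, 50, 9, 0.30, False),   # tumor depth at boundary
        (50, 10, 9, 0.30, False),   # normal depth at boundary
        (50, 50, 3, 0.30, False),   # allele depth at boundary
        (100, 50, 5, 0.05, False),  # allele fraction exactly at boundary
    ],
)
def test_pass_high_confidence_strict_boundaries(dp_t, dp_n, ad, af, expected):
    s = SomaticVariantCall(
        chrom="1", pos=1, ref="C", alt="T", variant_class="SNV",
        depth_tumor=dp_t, depth_normal=dp_n, allele_depth_tumor=ad,
        allele_fraction_tumor=af,
    )
    assert pass_high_confidence(s) is expected


@settings(derandomize=True, max_examples=200)
@given(
    dp_t=st.integers(1, 200), dp_n=st.integers(1, 200),
    ad_frac=st.floats(0, 1), bump=st.integers(0, 50),
)
def test_pass_high_confidence_monotone_in_depths(dp_t, dp_n, ad_frac, bump):
    """Increasing any numeric argument never flips pass -> fail."""
    ad = int(dp_t * ad_frac)
    base = SomaticVariantCall(
        chrom="1", pos=1, ref="C", alt="T", variant_class="SNV",
        depth_tumor=dp_t, depth_normal=dp_n, allele_depth_tumor=ad,
        allele_fraction_tumor=ad / dp_t,
    )
    better = SomaticVariantCall(
        chrom="1", pos=1, ref="C", alt="T", variant_class="SNV",
        depth_tumor=dp_t + bump, depth_normal=dp_n + bump,
        allele_depth_tumor=ad + bump,
        allele_fraction_tumor=min(1.0, (ad + bump) / (dp_t + bump) + 1e-6),
    )
    assert pass_high_confidence(base) <= pass_high_confidence(better)


# --- TMB --------------------------------------------------------------------

def test_tmb_arithmetic_and_hypermutation_boundary():
    cfg = TmbConfig(genome_size_mb=1.0, hypermutation_threshold=10.0)
    at = compute_tmb([_snv() for _ in range(10)], c=cfg)
    assert at.tmb == pytest.approx(10.0) and not at.hypermutated
    above = compute_tmb([_snv() for _ in range(11)], c=cfg)
    assert above.tmb == pytest.approx(11.0) and above.hypermutated


def test_tmb_known_value_and_log():
    res = compute_tmb([_snv() for _ in range(100)],
                      c=TmbConfig(genome_size_mb=3095.69))
    assert res.tmb == pytest.approx(100 / 3095.69)
    assert res.log10_tmb == pytest.approx(math.log10(100 / 3095.69))


def test_tmb_excludes_indels_and_failing_calls():
    calls = [_snv(), _snv(variant_class="INDEL"), _snv(dp_t=8, ad=4)]
    assert compute_tmb(calls, c=TmbConfig(genome_size_mb=1.0)).n_passing_snvs == 1


def test_tmb_zero_count_has_no_log():
    res = compute_tmb([], c=TmbConfig(genome_size_mb=1.0))
    assert res.tmb == 0.0 and res.log10_tmb is None and not res.hypermutated


def test_tmb_linearity():
    calls = [_snv(pos=i) for i in range(50)]
    one = compute_tmb(calls, c=TmbConfig(genome_size_mb=3095.69))
    two = compute_tmb(calls + calls, c=TmbConfig(genome_size_mb=3095.69))
    assert two.tmb == pytest.approx(2 * one.tmb)


def test_tmb_rejects_nonpositive_genome():
    with pytest.raises(ValueError):
        TmbConfig(genome_size_mb=0)


# --- second-hit classification ----------------------------------------------

def _in_gene_snv():
    return _snv(chrom=GENE.chrom, pos=GENE.start + 1000, gene="RB1")


def test_cn_loh_from_high_vaf_without_copy_change():
    call = classify_second_hit(GENE, 0.85, [_snv()], [], [])
    assert call.category == "cn_loh"


def test_second_mutation_in_gene():
    call = classify_second_hit(GENE, 0.50, [_snv(), _in_gene_snv()], [], [])
    assert call.category == "second_mutation"


def test_empty_somatic_call_set_is_inconclusive():
    assert classify_second_hit(GENE, None, [], [], []).category == "inconclusive"


def test_vaf_at_threshold_is_none():
    assert classify_second_hit(GENE, 0.69, [_snv()], [], []).category == "none"
    assert classify_second_hit(GENE, 0.70, [_snv()], [], []).category == "none"


def test_high_vaf_with_copy_loss_is_structural_not_cnloh():
    loss = CopyNumberSegment(GENE.chrom, GENE.start - 1, GENE.end + 1, "loss")
    call = classify_second_hit(GENE, 0.9, [_snv()], [loss], [])
    assert call.category == "structural_variant"


def test_baf_based_cnloh_segment():
    seg = CopyNumberSegment(GENE.chrom, GENE.start, GENE.end, "neutral", baf=0.85)
    call = classify_second_hit(GENE, None, [_snv()], [seg], [])
    assert call.category == "cn_loh"


def test_sv_disrupting_gene():
    sv = StructuralVariantCall("DEL", GENE.chrom, GENE.start, GENE.end, ("RB1",))
    assert classify_second_hit(GENE, 0.5, [_snv()], [], [sv]).category == "structural_variant"


def test_non_tumor_suppressor_rejected():
    g = PanelGene("POLE", "12", 1, 100, "AD", tumor_suppressor=False)
    with pytest.raises(ValueError):
        classify_second_hit(g, 0.5, [_snv()], [], [])


def test_missing_vaf_and_baf_warns():
    with pytest.warns(UserWarning, match="CN-LOH"):
        classify_second_hit(GENE, None, [_snv()], [], [])


def test_classifier_matches_priority_oracle():
    """Exhaustive agreement with a brute-force oracle over presence/absence
    of {informative calls, in-gene hit, gene-disrupting SV, high-VAF CN-LOH}
    under the priority order mutation > structural > CN-LOH."""
    cfg = SecondHitConfig()
    for informative, in_gene, sv_present, vaf_high in itertools.product(
        (False, True), repeat=4
    ):
        somatic = []
        if informative:
            somatic.append(_snv())
        if in_gene:
            if not informative:
                continue  # an in-gene call implies an informative call set
            somatic.append(_in_gene_snv())
        svs = (
            [StructuralVariantCall("DEL", GENE.chrom, GENE.start, GENE.end, ("RB1",))]
            if sv_present else []
        )
        vaf = 0.85 if vaf_high else 0.5

        if not informative:
            expected = "inconclusive"
        elif in_gene:
            expected = "second_mutation"
        elif sv_present:
            expected = "structural_variant"
        elif vaf_high:
            expected = "cn_loh"
        else:
            expected = "none"
        got = classify_second_hit(GENE, vaf, somatic, [], svs, cfg)
        assert got.category == expected, (informative, in_gene, sv_present, vaf_high)


def test_raising_cnloh_threshold_never_creates_cnloh():
    """Monotonicity: a stricter VAF threshold can only remove CN-LOH calls."""
    for vaf in (0.55, 0.72, 0.80, 0.95):
        lenient = classify_second_hit(
            GENE, vaf, [_snv()], [], [], SecondHitConfig(cn_loh_vaf_threshold=0.60)
        ).category
        strict = classify_second_hit(
            GENE, vaf, [_snv()], [], [], SecondHitConfig(cn_loh_vaf_threshold=0.90)
        ).category
        if lenient == "none":
            assert strict == "none"
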