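"""Seeded synthetic-data generation.

Everything the pipeline consumes can be generated here: cohort tables with
criteria marginals, paired germline/tumor variant data with implanted
second-hit scenarios, and multinomially sampled 96-channel mutation
catalogs. All generators are pure functions of (config, seed): the same
inputs give byte-identical outputs.

Defaults encode the study conditions of a nationwide pediatric solid-tumor
cohort: 309 children, ~11% carrying a predisposition syndrome (~31% of
those already known at inclusion), criterion marginals of 22% family
history, 3.4% multiple primaries, 30% with at least one non-cancer
feature, and 42% with a predisposition-associated malignancy type; the
second-hit scenario mix follows the observed 8:4:2:3:2 split of second
mutation : CN-LOH : structural variant : inconclusive : none.

The bundled signature matrices are *synthetic* stand-ins: peaked random
probability vectors carrying real signature names (SBS1, SBS44, ...) so
that etiology grouping is exercised, not reproductions of the COSMIC
catalog.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .criteria import (
    DEFAULT_FEATURE_VOCABULARY,
    DEFAULT_MALIGNANCY_LIST,
    CriteriaRecord,
    score_criteria,
)
from .germline import GermlineVariantCall
from .panel import Panel, PanelGene
from .signatures import BASES, CHANNELS_96, SignatureMatrix
from .somatic import (
    CopyNumberSegment,
    SomaticVariantCall,
    StructuralVariantCall,
)
from .stats import PatientRecord

#: chromosomes free of demo-panel genes, used for background somatic noise
_BACKGROUND_CHROMS = ("5", "6", "8", "9", "10", "16", "18", "19", "20", "21")

SCENARIOS = ("second_mutation", "cn_loh", "structural_variant", "inconclusive", "none")


# --- configuration ----------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 0
    n_patients: int = 309
    prevalence_target: float = 0.113
    fraction_known_at_inclusion: float = 11 / 35
    criteria_marginals: dict = field(
        default_factory=lambda: {
            "family_history": 0.22,
            "multiple_primary": 0.034,
            "other_features": 0.30,
            "malignancy_type": 0.42,
        }
    )
    missingness: dict = field(
        default_factory=lambda: {
            "family_history": 19 / 309,
            "multiple_primary": 18 / 309,
            "other_features": 16 / 309,
            "malignancy_type": 0.0,
        }
    )
    #: per-criterion true odds ratios for the logistic enrichment link;
    #: None disables enrichment (status independent of criteria)
    criterion_ors: Optional[dict] = field(
        default_factory=lambda: {
            "family_history": 2.5,
            "multiple_primary": 9.2,
            "other_features": 3.9,
            "malignancy_type": 3.8,
        }
    )
    second_hit_scenario_mix: dict = field(
        default_factory=lambda: {
            "second_mutation": 8 / 19,
            "cn_loh": 4 / 19,
            "structural_variant": 2 / 19,
            "inconclusive": 3 / 19,
            "none": 2 / 19,
        }
    )
    n_background_somatic: int = 40
    cn_loh_vaf_mean: float = 0.85
    cn_loh_vaf_sd: float = 0.04
    retained_vaf_mean: float = 0.50
    retained_vaf_sd: float = 0.04
    normal_mutation_count: int = 3000
    hyper_mutation_count: int = 50000

    def __post_init__(self) -> None:
        for name, p in self.criteria_marginals.items():
            if not 0 <= p <= 1:
                raise ValueError(f"marginal {name}={p} outside [0, 1]")
        if not 0 <= self.prevalence_target <= 1:
            raise ValueError("prevalence_target outside [0, 1]")
        s = sum(self.second_hit_scenario_mix.values())
        if abs(s - 1) > 1e-9:
            raise ValueError(f"scenario mix sums to {s}, expected 1")


# --- cohort -----------------------------------------------------------------

_FEATURE_POOL = (
    ("cognitive_behavioral", 0.35),
    ("skin_manifestation", 0.23),
    ("congenital_malformation", 0.14),
    ("id_dd", 0.10),
    ("other", 0.18),
)


def _draw_features(rng: np.random.Generator, p_ge1: float) -> tuple[str, ...]:
    """0, 1 or 2 distinct features; P(>=1) = p_ge1, with ~30% of feature
    carriers having two (matching the observed >=2 / >=1 ratio)."""
    u = rng.random()
    if u >= p_ge1:
        return ()
    k = 2 if rng.random() < 0.30 else 1
    names = [f for f, _ in _FEATURE_POOL]
    weights = np.array([w for _, w in _FEATURE_POOL])
    picked = rng.choice(len(names), size=k, replace=False, p=weights / weights.sum())
    return tuple(names[i] for i in sorted(picked))


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[PatientRecord], list[CriteriaRecord], dict]:
    """Generate a cohort with the configured criteria marginals and
    prevalence.

    When ``criterion_ors`` is set, disease status follows a logistic link in
    the fulfilled-criterion indicators with those odds ratios; the intercept
    is calibrated on the realized covariates so the expected prevalence
    equals ``prevalence_target``. The returned ground-truth dict records the
    generating parameters for parameter-recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    records: list[CriteriaRecord] = []
    diagnoses = []
    for i in range(n):
        listed = rng.random() < cfg.criteria_marginals["malignancy_type"]
        diagnosis = "retinoblastoma" if listed else "other"
        fh = bool(rng.random() < cfg.criteria_marginals["family_history"])
        mp = bool(rng.random() < cfg.criteria_marginals["multiple_primary"])
        feats = _draw_features(rng, cfg.criteria_marginals["other_features"])
        # missingness applied after the latent draw
        fh_v = None if rng.random() < cfg.missingness["family_history"] else fh
        mp_v = None if rng.random() < cfg.missingness["multiple_primary"] else mp
        feats_v = None if rng.random() < cfg.missingness["other_features"] else feats
        records.append(
            CriteriaRecord(
                family_history=fh_v,
                multiple_primary=mp_v,
                other_features=feats_v,
                diagnosis=diagnosis,
                patient_id=f"SC{i + 1:04d}",
            )
        )
        diagnoses.append(diagnosis)

    scores = [score_criteria(r) for r in records]
    X = np.array(
        [
            [1.0 if s.status[c] == "fulfilled" else 0.0 for c in
             ("family_history", "multiple_primary", "other_features", "malignancy_type")]
            for s in scores
        ]
    )

    truth: dict = {
        "seed": cfg.seed,
        "n_patients": n,
        "prevalence_target": cfg.prevalence_target,
        "criterion_ors": cfg.criterion_ors,
    }
    if cfg.prevalence_target == 0:
        p_i = np.zeros(n)
        truth["intercept"] = None
    elif cfg.criterion_ors is None:
        p_i = np.full(n, cfg.prevalence_target)
        truth["intercept"] = None
    else:
        beta = np.log(
            [
                cfg.criterion_ors["family_history"],
                cfg.criterion_ors["multiple_primary"],
                cfg.criterion_ors["other_features"],
                cfg.criterion_ors["malignancy_type"],
            ]
        )
        eta = X @ beta

        def mean_p(b0: float) -> float:
            return float(np.mean(1 / (1 + np.exp(-(b0 + eta)))))

        b0 = brentq(lambda b: mean_p(b) - cfg.prevalence_target, -30, 30)
        p_i = 1 / (1 + np.exp(-(b0 + eta)))
        truth["intercept"] = b0

    positive = rng.random(n) < p_i
    known = positive & (rng.random(n) < cfg.fraction_known_at_inclusion)

    patients = []
    for i in range(n):
        patients.append(
            PatientRecord(
                id=records[i].patient_id,
                age_years=float(np.floor(rng.uniform(0, 18))),
                sex="male" if rng.random() < 0.55 else "female",
                tumor_group="CNS" if rng.random() < 0.40 else "extracranial",
                chicap_diagnosis=bool(positive[i]),
                known_at_inclusion=bool(known[i]),
                criteria=scores[i],
            )
        )
    truth["n_positive"] = int(positive.sum())
    truth["n_known_at_inclusion"] = int(known.sum())
    return patients, records, truth


# --- paired germline/tumor data --------------------------------------------

@dataclass
class PairedTumorData:
    """One patient's implanted germline finding plus engineered tumor data."""

    patient_id: str
    scenario: str
    gene: str
    germline_call: GermlineVariantCall
    tumor_vaf_of_germline: Optional[float]
    somatic_calls: list[SomaticVariantCall]
    cn_segments: list[CopyNumberSegment]
    svs: list[StructuralVariantCall]


def _random_context(rng: np.random.Generator, ref: str) -> str:
    return rng.choice(BASES) + ref + rng.choice(BASES)


def _background_snv(rng: np.random.Generator) -> SomaticVariantCall:
    chrom = str(rng.choice(_BACKGROUND_CHROMS))
    ref = str(rng.choice(BASES))
    alt = str(rng.choice([b for b in BASES if b != ref]))
    dp_t = int(rng.integers(60, 121))
    af = float(np.clip(rng.normal(0.35, 0.10), 0.10, 0.90))
    ad = max(4, round(dp_t * af))
    return SomaticVariantCall(
        chrom=chrom,
        pos=int(rng.integers(1_000_000, 100_000_000)),
        ref=ref,
        alt=alt,
        variant_class="SNV",
        depth_tumor=dp_t,
        depth_normal=int(rng.integers(30, 61)),
        allele_depth_tumor=min(ad, dp_t),
        allele_fraction_tumor=min(ad, dp_t) / dp_t,
        trinucleotide_context=_random_context(rng, ref),
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-9, hi))


def generate_paired_variants(
    patient_id: str,
    scenario: str,
    panel: Panel,
    rng: np.random.Generator,
    cfg: SimulationConfig = SimulationConfig(),
    gene: Optional[str] = None,
) -> PairedTumorData:
    """Emit a reportable germline P variant in a tumor-suppressor gene plus
    tumor data engineered so the second-hit classifier returns exactly the
    requested scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if gene is not None:
        g = panel.get(gene)
        if g is None or not g.tumor_suppressor:
            raise ValueError(f"{gene}: not a tumor-suppressor panel gene")
    else:
        candidates = sorted(
            (x for x in panel if x.tumor_suppressor and x.inheritance == "AD"),
            key=lambda x: x.symbol,
        )
        g = candidates[int(rng.integers(len(candidates)))]

    mid = (g.start + g.end) // 2
    germ = GermlineVariantCall(
        chrom=g.chrom,
        pos=mid,
        ref="C",
        alt="T",
        variant_class="SNV",
        gene=g.symbol,
        zygosity="heterozygous",
        classification="P",
        allele_fraction_blood=float(np.clip(rng.normal(0.48, 0.03), 0.35, 0.60)),
        patient_id=patient_id,
    )

    somatic: list[SomaticVariantCall] = []
    cn: list[CopyNumberSegment] = []
    svs: list[StructuralVariantCall] = []
    vaf: Optional[float]

    if scenario == "inconclusive":
        vaf = None
    else:
        somatic = [_background_snv(rng) for _ in range(cfg.n_background_somatic)]
        if scenario == "second_mutation":
            vaf = _truncated_normal(
                rng, cfg.retained_vaf_mean, cfg.retained_vaf_sd, 0.30, 0.70
            )
            dp_t = int(rng.integers(60, 121))
            ad = round(dp_t * 0.42)
            somatic.append(
                SomaticVariantCall(
                    chrom=g.chrom,
                    pos=int(rng.integers(g.start, g.end + 1)),
                    ref="G",
                    alt="A",
                    variant_class="SNV",
                    depth_tumor=dp_t,
                    depth_normal=int(rng.integers(30, 61)),
                    allele_depth_tumor=ad,
                    allele_fraction_tumor=ad / dp_t,
                    gene=g.symbol,
                    trinucleotide_context=_random_context(rng, "G"),
                )
            )
        elif scenario == "structural_variant":
            vaf = _truncated_normal(rng, 0.80, 0.05, 0.60, 0.95)
            if rng.random() < 0.5:
                svs.append(
                    StructuralVariantCall(
                        type="DEL", chrom=g.chrom,
                        start=max(1, g.start - 10_000), end=g.end + 10_000,
                        genes_disrupted=(g.symbol,),
                    )
                )
            else:
                cn.append(
                    CopyNumberSegment(
                        chrom=g.chrom, start=max(1, g.start - 50_000),
                        end=g.end + 50_000, copy_state="loss",
                    )
                )
        elif scenario == "cn_loh":
            vaf = _truncated_normal(
                rng, cfg.cn_loh_vaf_mean, cfg.cn_loh_vaf_sd, 0.70, 1.0
            )
            cn.append(
                CopyNumberSegment(
                    chrom=g.chrom, start=max(1, g.start - 100_000),
                    end=g.end + 100_000, copy_state="neutral",
                    baf=float(np.clip(rng.normal(0.85, 0.03), 0.75, 0.98)),
                )
            )
        else:  # none
            vaf = _truncated_normal(
                rng, cfg.retained_vaf_mean, cfg.retained_vaf_sd, 0.30, 0.65
            )

    return PairedTumorData(
        patient_id=patient_id,
        scenario=scenario,
        gene=g.symbol,
        germline_call=germ,
        tumor_vaf_of_germline=vaf,
        somatic_calls=somatic,
        cn_segments=cn,
        svs=svs,
    )


def generate_paired_cohort(
    scenario_counts: dict[str, int],
    panel: Panel,
    seed: int,
    cfg: SimulationConfig = SimulationConfig(),
) -> list[PairedTumorData]:
    """Generate one paired dataset per patient with exact scenario counts
    (scenario order fixed, patient order shuffled deterministically)."""
    rng = np.random.default_rng(seed)
    scenarios = [s for s in SCENARIOS for _ in range(scenario_counts.get(s, 0))]
    order = rng.permutation(len(scenarios))
    return [
        generate_paired_variants(f"PT{i + 1:03d}", scenarios[j], panel, rng, cfg)
        for i, j in enumerate(order)
    ]


# --- mutation catalogs ------------------------------------------------------

def synthetic_signature_matrix(
    names: Sequence[str], seed: int = 2024, concentration: float = 0.08
) -> SignatureMatrix:
    """Deterministic synthetic reference signatures: sparse, peaked Dirichlet
    draws over the 96 channels. These are stand-ins carrying familiar names,
    not the real COSMIC vectors."""
    rng = np.random.default_rng(seed)
    cols = np.column_stack(
        [rng.dirichlet(np.full(96, concentration)) for _ in names]
    )
    # guard against numerically zero columns entries only; columns sum to 1
    return SignatureMatrix(tuple(names), cols / cols.sum(axis=0, keepdims=True))


def miniature_reference_signatures() -> SignatureMatrix:
    """A small fixed synthetic reference set spanning the etiology groups:
    clock-like (SBS1, SBS5), MMR deficiency (SBS6, SBS44), POLE proofreading
    (SBS10a, SBS28) and UV (SBS7a)."""
    return synthetic_signature_matrix(
        ("SBS1", "SBS5", "SBS6", "SBS44", "SBS10a", "SBS28", "SBS7a"), seed=20240101
    )


def sample_catalog(
    mixture: dict[str, float],
    S: SignatureMatrix,
    n_mutations: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Multinomial catalog draw from a signature mixture, plus synthetic
    somatic SNV records (all passing the high-confidence filter) whose
    trinucleotide contexts realize the catalog."""
    from .signatures import MutationCatalog96

    if rng is None:
        rng = np.random.default_rng(seed)
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    w = np.array([mixture.get(n, 0.0) for n in S.names], dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("mixture weights must be non-negative and not all zero")
    w = w / w.sum()
    p = S.matrix @ w
    counts = rng.multinomial(n_mutations, p / p.sum())
    records = []
    for i, k in enumerate(counts):
        if k == 0:
            continue
        label = CHANNELS_96[i]
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        context = five + ref + three
        for _ in range(int(k)):
            dp_t = int(rng.integers(60, 121))
            ad = max(5, round(dp_t * 0.40))
            records.append(
                SomaticVariantCall(
                    chrom=str(rng.choice(_BACKGROUND_CHROMS)),
                    pos=int(rng.integers(1_000_000, 100_000_000)),
                    ref=ref,
                    alt=alt,
                    variant_class="SNV",
                    depth_tumor=dp_t,
                    depth_normal=int(rng.integers(30, 61)),
                    allele_depth_tumor=ad,
                    allele_fraction_tumor=ad / dp_t,
                    trinucleotide_context=context,
                )
            )
    return MutationCatalog96(counts.astype(float)), records
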