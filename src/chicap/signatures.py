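"""96-channel single-base-substitution (SBS) catalogs, reference-signature
refitting by non-negative least squares, etiology flags, and the
germline-somatic concordance call.

Channels follow the canonical pyrimidine-strand convention: six substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G), each expanded by the 5' and 3'
flanking bases in A,C,G,T order — 96 channels, labelled e.g. ``A[C>A]A``.
SNVs whose reference base is a purine are reverse-complemented before
binning.

Refitting solves min ||c - S w||_2 with w >= 0 (scipy NNLS) and then prunes
signatures greedily: a retained signature is dropped whenever refitting
without it costs less than ``pruning_tolerance`` in reconstruction cosine
similarity. This is a deterministic sparse-assignment heuristic in the
spirit of the standard COSMIC refitting tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical channel labels, in canonical order
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> int:
    """Map an SNV with its reference-strand 3-mer context to a channel index.

    Purine reference bases are reverse-complemented into the pyrimidine
    representation first.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(
            f"context {context!r} middle base does not match ref {ref!r}"
        )
    if any(b not in BASES for b in context + alt):
        raise ValueError(f"ambiguous base in {context!r}>{alt!r}")
    if ref in ("A", "G"):  # purine: flip strand
        context = revcomp(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return _CHANNEL_INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


@dataclass
class MutationCatalog96:
    """Counts over the 96 canonical channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (96,):
            raise ValueError(f"catalog must have 96 channels, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("catalog counts must be non-negative")
        self.counts = c.astype(float)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS_96), name="count")

    def to_tsv(self, path: str | Path) -> None:
        self.to_series().rename_axis("channel").reset_index().to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationCatalog96":
        df = pd.read_csv(path, sep="\t")
        s = df.set_index(df.columns[0])[df.columns[1]]
        return cls(s.reindex(list(CHANNELS_96)).to_numpy())


def build_catalog(snvs: Iterable) -> tuple[MutationCatalog96, int]:
    """Bin somatic SNVs (with trinucleotide contexts) into a 96-catalog.

    Records whose context contains an ambiguous base (N) are skipped;
    the number skipped is returned alongside the catalog. A context whose
    middle base disagrees with the reference allele is an error.
    """
    counts = np.zeros(96)
    n_skipped = 0
    for i, s in enumerate(snvs):
        ctx = s.trinucleotide_context
        if ctx is None:
            raise ValueError(f"record {i}: missing trinucleotide context")
        if "N" in ctx.upper() or "N" in s.alt.upper():
            n_skipped += 1
            continue
        if ctx.upper()[1] != s.ref.upper():
            raise ValueError(
                f"record {i} ({s.chrom}:{s.pos}): context {ctx!r} middle base "
                f"!= ref {s.ref!r}"
            )
        counts[channel_of(s.ref, s.alt, ctx)] += 1
    return MutationCatalog96(counts), n_skipped


@dataclass
class SignatureMatrix:
    """k reference signatures, each a probability vector over 96 channels."""

    names: tuple[str, ...]
    matrix: np.ndarray  # shape (96, k), columns sum to 1

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 96:
            raise ValueError(f"matrix must be 96 x k, got {m.shape}")
        if m.shape[1] != len(self.names):
            raise ValueError("number of names does not match number of columns")
        if m.shape[1] == 0:
            raise ValueError("signature matrix has zero columns")
        if np.any(m < 0):
            raise ValueError("signature entries must be non-negative")
        sums = m.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [self.names[j] for j in np.where(np.abs(sums - 1) > 1e-6)[0]]
            raise ValueError(f"signature column(s) do not sum to 1: {bad}")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(tuple(names), self.matrix[:, idx])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=list(CHANNELS_96), columns=list(self.names)
        ).rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.reindex(list(CHANNELS_96))
        if df.isna().any().any():
            raise ValueError(f"{path}: missing or mislabelled channels")
        return cls(tuple(df.columns), df.to_numpy())


@dataclass
class SignatureFitResult:
    proportions: dict[str, float]  # over retained signatures, sum 1
    reconstruction_similarity: float
    retained: tuple[str, ...]
    etiology_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FitConfig:
    pruning_tolerance: float = 0.01  # cosine-similarity cost allowed per removal
    min_contribution: float = 0.0


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _nnls_fit(S: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    w, _ = nnls(S, c)
    return w, _cosine(S @ w, c)


def fit_signatures(
    catalog: MutationCatalog96,
    S: SignatureMatrix,
    cfg: FitConfig = FitConfig(),
) -> SignatureFitResult:
    """Refit a catalog as a non-negative mixture of reference signatures.

    After the initial NNLS solution, signatures are pruned backward: at each
    step every retained signature is tentatively removed and the mixture
    refit; the removal with the smallest similarity cost is accepted if that
    cost is below ``pruning_tolerance`` (ties break on signature name).
    Proportions are the final weights normalized over survivors.
    """
    c = catalog.counts
    if catalog.total == 0:
        raise ValueError("empty catalog")
    names = list(S.names)
    w, sim_full = _nnls_fit(S.matrix, c)
    retained = [n for n, wi in zip(names, w) if wi > 0]
    if not retained:  # degenerate: keep best single signature
        retained = [names[int(np.argmax(S.matrix.T @ c))]]

    def refit(subset: list[str]) -> tuple[np.ndarray, float]:
        idx = [names.index(n) for n in subset]
        return _nnls_fit(S.matrix[:, idx], c)

    w_cur, sim_cur = refit(retained)
    while len(retained) > 1:
        best = None  # (cost, name, w, sim)
        for n in sorted(retained):
            subset = [m for m in retained if m != n]
            w_try, sim_try = refit(subset)
            cost = sim_cur - sim_try
            if cost < cfg.pruning_tolerance:
                if best is None or (cost, n) < (best[0], best[1]):
                    best = (cost, n, w_try, sim_try)
        if best is None:
            break
        _, drop, w_cur, sim_cur = best
        retained = [m for m in retained if m != drop]

    total_w = w_cur.sum()
    props = {n: float(wi / total_w) for n, wi in zip(retained, w_cur)}
    if cfg.min_contribution > 0:
        kept = {n: p for n, p in props.items() if p >= cfg.min_contribution}
        if kept:
            z = sum(kept.values())
            props = {n: p / z for n, p in kept.items()}
    return SignatureFitResult(
        proportions=props,
        reconstruction_similarity=sim_cur,
        retained=tuple(props.keys()),
    )


# --- etiology flags ---------------------------------------------------------

#: default signature groups for three well-characterized mutational
#: processes: mismatch-repair deficiency, POLE exonuclease-proofreading
#: deficiency, and ultraviolet-light exposure.
MMRD_SIGNATURES = frozenset({"SBS6", "SBS14", "SBS15", "SBS20", "SBS21", "SBS26", "SBS44"})
POLE_SIGNATURES = frozenset({"SBS10a", "SBS10b", "SBS28"})
UV_SIGNATURES = frozenset({"SBS7a", "SBS7b", "SBS7c", "SBS7d"})


@dataclass(frozen=True)
class EtiologyConfig:
    mmrd_set: frozenset = MMRD_SIGNATURES
    pole_set: frozenset = POLE_SIGNATURES
    uv_set: frozenset = UV_SIGNATURES
    etiology_threshold: float = 0.10


def etiology_flags(
    fit: SignatureFitResult, cfg: EtiologyConfig = EtiologyConfig()
) -> frozenset[str]:
    """Flag an etiology when its signatures jointly reach the threshold
    proportion (default 0.10, inclusive)."""
    flags = set()
    for flag, sigs in (("MMRd", cfg.mmrd_set), ("POLE", cfg.pole_set), ("UV", cfg.uv_set)):
        if sum(p for n, p in fit.proportions.items() if n in sigs) >= cfg.etiology_threshold:
            flags.add(flag)
    return frozenset(flags)


# --- concordance ------------------------------------------------------------

GENE_GROUPS = ("MMR", "POLE_gene", "NER", "other")
_GROUP_TO_FLAG = {"MMR": "MMRd", "POLE_gene": "POLE", "NER": "UV"}


def concordance_call(
    second_hit,  # SecondHitCall or None (not applicable / no data)
    tmb_hypermutated: bool,
    flags,  # frozenset of etiology flags, or None when no signature data
    germline_gene_group: str,
) -> str:
    """Germline-somatic concordance for one patient.

    Concordant when a genetic second hit was found, or when the tumor is
    hypermutated with a signature etiology matching the germline gene's
    pathway (MMR gene with an MMR-deficiency signature, POLE with a
    proofreading signature, nucleotide-excision repair gene with a UV
    signature). Not evaluable when the second-hit analysis was inconclusive
    (or absent) and there are no signature data (``flags is None``);
    otherwise discordant.
    """
    if germline_gene_group not in GENE_GROUPS:
        raise ValueError(f"unknown gene group {germline_gene_group!r}")
    if second_hit is not None and second_hit.category in (
        "second_mutation",
        "cn_loh",
        "structural_variant",
    ):
        return "concordant"
    expected = _GROUP_TO_FLAG.get(germline_gene_group)
    if flags is not None and tmb_hypermutated and expected is not None and expected in flags:
        return "concordant"
    if (second_hit is None or second_hit.category == "inconclusive") and flags is None:
        return "not_evaluable"
    return "discordant"
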