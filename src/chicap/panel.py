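"""In-silico gene panel registry.

The panel gates all germline reporting: only pathogenic / likely pathogenic
variants that fall inside the genomic footprint of a panel gene are eligible
for reporting, and the per-gene inheritance model plus the adult-onset
dominant exception drive the genotype-consistency rules.

Coordinates are 1-based inclusive (VCF POS convention); a position belongs
to a gene when ``start <= pos <= end``. Each gene carries a single interval
footprint — no exon/transcript model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

INHERITANCE_CODES = frozenset({"AD", "AR", "XL"})

_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

PANEL_COLUMNS = [
    "symbol",
    "chrom",
    "start",
    "end",
    "inheritance",
    "adult_onset_dominant_exception",
    "tumor_suppressor",
]


class PanelValidationError(ValueError):
    """Raised when a panel table violates a structural invariant."""


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix and validate against the recognized chromosomes."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "MT" or c == "M":
        raise PanelValidationError(f"unsupported chromosome: {chrom!r}")
    if c not in _CHROMS:
        raise PanelValidationError(f"unrecognized chromosome: {chrom!r}")
    return c


@dataclass(frozen=True)
class PanelGene:
    """One panel entry.

    ``adult_onset_dominant_exception`` marks an autosomal-recessive gene that
    is also an autosomal dominant, highly penetrant, adult-onset cancer
    predisposition gene: a lone heterozygous P/LP variant in such a gene is
    reportable despite the recessive childhood syndrome.
    ``tumor_suppressor`` marks eligibility for somatic second-hit analysis.
    """

    symbol: str
    chrom: str
    start: int
    end: int
    inheritance: str
    adult_onset_dominant_exception: bool = False
    tumor_suppressor: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbol", self.symbol.upper())
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.inheritance not in INHERITANCE_CODES:
            raise PanelValidationError(
                f"{self.symbol}: unknown inheritance code {self.inheritance!r} "
                f"(expected one of {sorted(INHERITANCE_CODES)})"
            )
        if self.start > self.end:
            raise PanelValidationError(
                f"{self.symbol}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise PanelValidationError(f"{self.symbol}: start must be >= 1")
        if self.adult_onset_dominant_exception and self.inheritance != "AR":
            raise PanelValidationError(
                f"{self.symbol}: adult_onset_dominant_exception requires AR inheritance"
            )

    @property
    def footprint(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start <= pos <= self.end


@dataclass
class Panel:
    """A validated gene panel (non-empty, unique symbols)."""

    name: str
    genes: list[PanelGene] = field(default_factory=list)
    genome_build: str = "hg38"

    def __post_init__(self) -> None:
        if not self.genes:
            raise PanelValidationError(f"panel {self.name!r} is empty")
        if self.genome_build not in ("hg19", "hg38"):
            raise PanelValidationError(
                f"unknown genome build {self.genome_build!r} (expected hg19/hg38)"
            )
        seen: set[str] = set()
        dups: set[str] = set()
        for g in self.genes:
            (dups if g.symbol in seen else seen).add(g.symbol)
        if dups:
            raise PanelValidationError(
                f"duplicate gene symbol(s) in panel {self.name!r}: {sorted(dups)}"
            )
        self._by_symbol = {g.symbol: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, symbol: Optional[str]) -> Optional[PanelGene]:
        if symbol is None:
            return None
        return self._by_symbol.get(symbol.upper())

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._by_symbol


def gene_for_position(panel: Panel, chrom: str, pos: int) -> Optional[PanelGene]:
    """Locate the panel gene whose footprint contains ``(chrom, pos)``.

    Overlapping regions resolve to the gene with the smallest footprint
    (nested regions give the inner gene); ties break on the lexicographically
    smallest symbol. Returns ``None`` when no region contains the position.
    """
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    c = normalize_chrom(chrom)
    hits = [g for g in panel.genes if g.chrom == c and g.start <= pos <= g.end]
    if not hits:
        return None
    return min(hits, key=lambda g: (g.footprint, g.symbol))


def _parse_bool(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f", "", "nan"):
        return False
    raise PanelValidationError(f"row {row}: cannot parse boolean {column}={value!r}")


def load_panel(path: str | Path, name: Optional[str] = None,
               genome_build: str = "hg38") -> Panel:
    """Load and validate a panel from a tab-delimited file.

    Expected columns: symbol, chrom, start, end, inheritance,
    adult_onset_dominant_exception, tumor_suppressor. Lines starting with
    '#' are comments. Symbols are upper-cased; row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{path.name}: missing column(s) {missing}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            genes.append(
                PanelGene(
                    symbol=str(row.symbol),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    inheritance=str(row.inheritance).strip(),
                    adult_onset_dominant_exception=_parse_bool(
                        row.adult_onset_dominant_exception, i,
                        "adult_onset_dominant_exception"),
                    tumor_suppressor=_parse_bool(
                        row.tumor_suppressor, i, "tumor_suppressor"),
                )
            )
        except PanelValidationError as exc:
            raise PanelValidationError(f"row {i}: {exc}") from exc
    return Panel(name=name or path.stem, genes=genes, genome_build=genome_build)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to TSV; ``load_panel(write_panel(p))`` is identity."""
    df = pd.DataFrame(
        [
            {
                "symbol": g.symbol,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "inheritance": g.inheritance,
                "adult_onset_dominant_exception": g.adult_onset_dominant_exception,
                "tumor_suppressor": g.tumor_suppressor,
            }
            for g in panel.genes
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def demo_panel() -> Panel:
    """The bundled 20-gene demonstration panel (approximate hg19 footprints)."""
    from importlib.resources import files

    with (files("chicap.data") / "demo_panel.tsv").open("r") as fh:
        import io as _io

        df_path = _io.StringIO(fh.read())
    df = pd.read_csv(df_path, sep="\t", comment="#", dtype=str)
    genes = [
        PanelGene(
            symbol=r.symbol, chrom=r.chrom, start=int(r.start), end=int(r.end),
            inheritance=r.inheritance,
            adult_onset_dominant_exception=_parse_bool(
                r.adult_onset_dominant_exception, i, "adult_onset_dominant_exception"),
            tumor_suppressor=_parse_bool(r.tumor_suppressor, i, "tumor_suppressor"),
        )
        for i, r in enumerate(df.itertuples(index=False), start=1)
    ]
    return Panel(name="demo-20", genes=genes, genome_build="hg19")
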