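"""Coverage-weighted gene-frequency statistics and substrate profiles.

The frequency of a target gene set in one metagenome is

    frequency = sum(average coverage of target genes) * 100
                / sum(average coverage of all genes)

with per-gene average read coverages taken as given (per-base mean depth as
produced by standard mapping pipelines).  Profiles aggregate these
frequencies per substrate class, optionally stratified by taxon so that the
taxon components of a class sum to the class total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_io import (
    GeneTable,
    IntegrityError,
    PulgateError,
    SubstrateMap,
    UNCLASSIFIED_TAXON,
    ValidationError,
)
from .cluster_detection import is_degradative


class UndefinedFrequencyError(PulgateError):
    """Raised when the total coverage is zero and frequency is undefined."""


@dataclass
class CoverageTable:
    """Per-gene average coverages for one sample."""

    sample_id: str
    coverage: dict[str, float]

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.coverage.items() if c < 0}
        if bad:
            raise ValidationError(f"negative coverages for genes {sorted(bad)[:5]}")

    def total(self) -> float:
        return float(sum(self.coverage.values()))


def read_coverage_table(path: str | Path, sample_id: str | None = None) -> CoverageTable:
    """Read a TSV with columns gene_id and avg_coverage."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "avg_coverage"} <= set(df.columns):
        raise ValidationError(
            f"coverage table {path}: need columns 'gene_id' and 'avg_coverage'"
        )
    if df["gene_id"].duplicated().any():
        raise IntegrityError(f"coverage table {path}: duplicate gene_id rows")
    return CoverageTable(
        sample_id=sample_id or Path(path).stem,
        coverage=dict(zip(df["gene_id"], df["avg_coverage"].astype(float))),
    )


def write_coverage_table(table: CoverageTable, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(table.coverage), "avg_coverage": list(table.coverage.values())}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class FrequencyProfile:
    """Per-substrate (optionally per-taxon) frequencies, in percent.

    ``entries`` maps (substrate_class, taxon) to a percentage; taxon is None
    for unstratified profiles.  ``date`` and ``fraction`` carry sample
    metadata for time-series assembly.
    """

    sample_id: str
    entries: dict[tuple[str, str | None], float]
    date: str | None = None
    fraction: str | None = None

    def __post_init__(self) -> None:
        for key, freq in self.entries.items():
            if not (-1e-9 <= freq <= 100 + 1e-9):
                raise ValidationError(f"frequency out of [0, 100] for {key}: {freq}")

    def class_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for (cls, _), freq in self.entries.items():
            totals[cls] = totals.get(cls, 0.0) + freq
        return totals


def gene_frequency(
    target_gene_ids: Iterable[str], coverage_table: CoverageTable
) -> float:
    """Coverage-weighted frequency of a target gene set, in percent."""
    total = coverage_table.total()
    if total <= 0:
        raise UndefinedFrequencyError(
            f"sample {coverage_table.sample_id}: total coverage is zero; "
            "frequency undefined"
        )
    cov = coverage_table.coverage
    missing = [g for g in target_gene_ids if g not in cov]
    if missing:
        raise IntegrityError(
            f"target gene id(s) absent from coverage table: {missing[:10]}"
        )
    target_sum = sum(cov[g] for g in target_gene_ids)
    return target_sum * 100.0 / total


def substrate_frequency_profile(
    gene_table: GeneTable,
    coverage_table: CoverageTable,
    substrate_map: SubstrateMap,
    group_by_taxon: bool = False,
    date: str | None = None,
    fraction: str | None = None,
) -> FrequencyProfile:
    """Frequency of every substrate class with >= 1 target gene.

    A gene targets a class when it has at least one degradative family
    mapping to that class; a multi-specificity gene contributes its full
    coverage to every class it maps to, so class frequencies are not a
    partition.  With ``group_by_taxon``, each class splits by gene taxon
    (missing taxa pool under "unclassified") and the components sum to the
    class total.
    """
    cov = coverage_table.coverage
    missing = [g.gene_id for g in gene_table.genes() if g.gene_id not in cov]
    if missing:
        raise IntegrityError(
            f"coverage table lacks gene(s) from the gene table: {missing[:10]}"
        )
    targets: dict[str, list] = {}
    for gene in gene_table.genes():
        classes = set()
        for fam in gene.cazyme_families:
            if is_degradative(fam):
                classes |= substrate_map.lookup(fam)
        for cls in classes:
            targets.setdefault(cls, []).append(gene)
    entries: dict[tuple[str, str | None], float] = {}
    for cls, genes in sorted(targets.items()):
        if group_by_taxon:
            by_taxon: dict[str, list[str]] = {}
            for g in genes:
                by_taxon.setdefault(g.taxon or UNCLASSIFIED_TAXON, []).append(g.gene_id)
            for taxon, ids in sorted(by_taxon.items()):
                entries[(cls, taxon)] = gene_frequency(ids, coverage_table)
        else:
            entries[(cls, None)] = gene_frequency(
                [g.gene_id for g in genes], coverage_table
            )
    return FrequencyProfile(
        sample_id=coverage_table.sample_id, entries=entries, date=date, fraction=fraction
    )


def frequency_timeseries(profiles: Sequence[FrequencyProfile]) -> pd.DataFrame:
    """Tidy long-format table (date, fraction, substrate, taxon, frequency)
    sorted by date, for stacked time-series plotting."""
    seen: set[tuple[str | None, str | None]] = set()
    rows = []
    for p in profiles:
        key = (p.date, p.fraction)
        if key in seen:
            raise IntegrityError(f"duplicate (date, fraction) profile: {key}")
        seen.add(key)
        for (cls, taxon), freq in p.entries.items():
            rows.append(
                {
                    "date": p.date,
                    "fraction": p.fraction,
                    "substrate": cls,
                    "taxon": taxon if taxon is not None else "",
                    "frequency": freq,
                }
            )
    df = pd.DataFrame(
        rows, columns=["date", "fraction", "substrate", "taxon", "frequency"]
    )
    return df.sort_values(
        ["date", "fraction", "substrate", "taxon"], kind="mergesort"
    ).reset_index(drop=True)
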