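"""MIMAG-style quality tiers for metagenome-assembled genomes.

Completeness and contamination estimates are consumed as given (typically
CheckM output).  Gating, with the strict/non-strict operators exactly as
defined by the MIMAG standard:

* HQ            — completeness > 90%, contamination < 5%, all of the 5S,
                  16S and 23S rRNA genes present, and >= 18 tRNAs;
* NEAR_COMPLETE — completeness > 90% and contamination < 5% but the
                  rRNA/tRNA requirements unmet (often pooled with HQ
                  downstream);
* MQ            — completeness >= 50% and contamination < 10%;
* LQ            — everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core_io import ValidationError

logger = logging.getLogger("pulgate")

TIERS = ("HQ", "NEAR_COMPLETE", "MQ", "LQ")


@dataclass(frozen=True)
class MagStats:
    mag_id: str
    completeness: float  # percent
    contamination: float  # percent
    has_5s: bool = False
    has_16s: bool = False
    has_23s: bool = False
    trna_count: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100):
            raise ValidationError(
                f"MAG {self.mag_id}: completeness must be in [0, 100], "
                f"got {self.completeness}"
            )
        if self.contamination < 0:
            raise ValidationError(
                f"MAG {self.mag_id}: contamination must be >= 0, "
                f"got {self.contamination}"
            )
        if self.trna_count < 0:
            raise ValidationError(f"MAG {self.mag_id}: trna_count must be >= 0")
        if self.trna_count > 100:
            logger.warning(
                "MAG %s: implausible tRNA count %d", self.mag_id, self.trna_count
            )


def assign_quality_tier(mag_stats: MagStats) -> str:
    """Assign exactly one tier per MAG (see module docstring for the gates)."""
    s = mag_stats
    if s.completeness > 90 and s.contamination < 5:
        if s.has_5s and s.has_16s and s.has_23s and s.trna_count >= 18:
            return "HQ"
        return "NEAR_COMPLETE"
    if s.completeness >= 50 and s.contamination < 10:
        return "MQ"
    return "LQ"


def summarize_tiers(mag_stats_list: Sequence[MagStats]) -> dict[str, int]:
    """Tier histogram plus the pooled HQ-or-near-complete count used when
    near-complete MAGs are treated like HQ downstream."""
    if not mag_stats_list:
        raise ValidationError("cannot summarize an empty MAG list")
    hist = {tier: 0 for tier in TIERS}
    for s in mag_stats_list:
        hist[assign_quality_tier(s)] += 1
    hist["HQ_OR_NEAR_COMPLETE"] = hist["HQ"] + hist["NEAR_COMPLETE"]
    return hist


def read_mag_stats(path: str | Path) -> list[MagStats]:
    """TSV columns: mag_id, completeness, contamination, rrna_5s, rrna_16s,
    rrna_23s, trna_count (rRNA flags as 0/1 or True/False)."""
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str})
    required = {
        "mag_id", "completeness", "contamination",
        "rrna_5s", "rrna_16s", "rrna_23s", "trna_count",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"MAG stats table {path}: missing column(s) {sorted(missing)}")

    def as_bool(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("1", "true", "yes")
        return bool(v)

    return [
        MagStats(
            mag_id=row.mag_id,
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            has_5s=as_bool(row.rrna_5s),
            has_16s=as_bool(row.rrna_16s),
            has_23s=as_bool(row.rrna_23s),
            trna_count=int(row.trna_count),
        )
        for row in df.itertuples(index=False)
    ]


def write_tier_table(
    mag_stats_list: Sequence[MagStats], path: str | Path, pool_near_complete: bool = False
) -> pd.DataFrame:
    """Per-MAG tier table; with pooling, NEAR_COMPLETE reports as HQ in the
    ``reported_tier`` column while the raw tier is retained."""
    rows = []
    for s in mag_stats_list:
        tier = assign_quality_tier(s)
        reported = "HQ" if (pool_near_complete and tier == "NEAR_COMPLETE") else tier
        rows.append({"mag_id": s.mag_id, "tier": tier, "reported_tier": reported})
    df = pd.DataFrame(rows, columns=["mag_id", "tier", "reported_tier"])
    df.to_csv(path, sep="\t", index=False)
    return df
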