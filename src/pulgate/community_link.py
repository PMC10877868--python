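"""Alpha-diversity estimators and ASV-to-MAG interrelation.

Diversity of amplicon sequence variant (ASV) count vectors is summarized by
Shannon entropy, the Gini-Simpson index, the Chao1 richness estimator and
Good's coverage (1 - singletons/reads).  The numerics delegate to
scikit-bio's alpha-diversity routines behind validated wrappers.

ASVs are linked to metagenome-assembled genomes (MAGs) when the ASV occurs
as an exact, mismatch-free substring of a MAG-derived 16S rRNA gene on
either strand (a perfect blastn hit of the short query: 100% identity over
100% of the ASV).  Links are then extended to further MAGs sharing an
average nucleotide identity (ANI) of at least 95% with the anchoring MAG —
one step only, no transitive chaining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from skbio.diversity import alpha as _skbio_alpha

from .core_io import IntegrityError, ValidationError

FRACTIONS = ("FL", "PA3", "PA10")

_VALID_BASES = frozenset("ACGTUN")


# ---------------------------------------------------------------------------
# Community matrix container and readers
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Samples x ASVs count matrix with per-sample size-fraction labels.

    ``counts`` is a pandas DataFrame (rows = samples, columns = ASV ids);
    ``fractions`` maps sample id to FL / PA3 / PA10; ``asv_sequences`` maps
    ASV id to its nucleotide sequence (required only for linking).
    """

    counts: pd.DataFrame
    fractions: dict[str, str]
    asv_sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("ASV counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("ASV counts must be integral")
        for s, f in self.fractions.items():
            if f not in FRACTIONS:
                raise ValidationError(
                    f"sample {s}: fraction must be one of {FRACTIONS}, got {f!r}"
                )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Samples x ASVs counts from TSV (first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Record id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def _as_counts(count_vector, need_positive: bool = True) -> np.ndarray:
    arr = np.asarray(count_vector, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("count vector must be one-dimensional")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if need_positive and not (arr > 0).any():
        raise ValidationError("count vector has no positive entries")
    return arr


def _as_int_counts(count_vector) -> np.ndarray:
    arr = _as_counts(count_vector, need_positive=False)
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError("counts must be integers for this estimator")
    return arr.astype(int)


def shannon(count_vector, log_base: float = math.e) -> float:
    """Shannon entropy H = -sum p_i log(p_i) over positive counts."""
    arr = _as_counts(count_vector)
    return float(_skbio_alpha.shannon(arr[arr > 0], base=log_base))


def simpson(count_vector, form: str = "gini-simpson") -> float:
    """Simpson diversity: 1 - sum p_i^2 (default) or the raw dominance
    sum p_i^2 with ``form="dominance"``."""
    arr = _as_counts(count_vector)
    gini = float(_skbio_alpha.simpson(arr))
    if form == "gini-simpson":
        return gini
    if form == "dominance":
        return 1.0 - gini
    raise ValidationError(f"unknown Simpson form {form!r}")


def chao1(count_vector, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)) (bias-corrected default)
    or the classic S_obs + F1^2/(2 F2)."""
    arr = _as_int_counts(count_vector)
    if not (arr > 0).any():
        raise ValidationError("count vector has no positive entries")
    return float(_skbio_alpha.chao1(arr, bias_corrected=bias_corrected))


def goods_coverage(count_vector) -> float:
    """Good's coverage 1 - F1/N: the estimated sampled fraction of the
    community (F1 = singleton ASVs, N = total reads)."""
    arr = _as_int_counts(count_vector)
    if arr.sum() < 1:
        raise ValidationError("total count must be >= 1")
    return float(_skbio_alpha.goods_coverage(arr))


def subsample_counts(count_vector, n: int, seed: int) -> np.ndarray:
    """Rarefy a count vector to n reads without replacement (seeded), for
    sensitivity checks; the main estimators run on unrarefied counts."""
    arr = _as_int_counts(count_vector)
    total = int(arr.sum())
    if n > total:
        raise ValidationError(f"cannot subsample {n} reads from {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, n).astype(int)


def alpha_diversity_table(
    matrix: CommunityMatrix,
    metrics: Sequence[str] = ("shannon", "simpson", "chao1", "goods"),
) -> pd.DataFrame:
    """Per-sample diversity table with the sample's fraction label."""
    funcs = {
        "shannon": shannon,
        "simpson": simpson,
        "chao1": chao1,
        "goods": goods_coverage,
    }
    unknown = [m for m in metrics if m not in funcs]
    if unknown:
        raise ValidationError(f"unknown metric(s): {unknown}")
    rows = []
    for sample_id, counts in matrix.counts.iterrows():
        row = {"sample_id": sample_id, "fraction": matrix.fractions.get(sample_id, "")}
        for m in metrics:
            row[m] = funcs[m](counts.to_numpy())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ASV <-> MAG linking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AsvMagLink:
    """One ASV-to-MAG link with its evidence type."""

    asv_id: str
    mag_id: str
    evidence: str  # EXACT_16S or ANI_EXTENSION
    via_mag_id: str | None = None

    def __post_init__(self) -> None:
        if self.evidence not in ("EXACT_16S", "ANI_EXTENSION"):
            raise ValidationError(f"unknown evidence type {self.evidence!r}")
        if self.evidence == "EXACT_16S" and self.via_mag_id is not None:
            raise ValidationError("EXACT_16S links carry no via_mag_id")
        if self.evidence == "ANI_EXTENSION" and self.via_mag_id is None:
            raise ValidationError("ANI_EXTENSION links must name the anchoring MAG")


def _normalize_seq(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValidationError(f"{what}: invalid nucleotide character(s) {sorted(bad)}")
    return s


def link_asv_to_mags(
    asv_sequences: Mapping[str, str],
    mag_16s_sequences: Mapping[str, str | Sequence[str]],
) -> list[AsvMagLink]:
    """Exact-containment links: ASV a substring of a MAG 16S on either
    strand, 100% identity over the full ASV length.  Ambiguous N bases never
    match, so an ASV containing N cannot link.  A MAG may carry several 16S
    copies (pass a sequence list); any copy linking suffices.
    """
    links: list[AsvMagLink] = []
    mags: dict[str, list[str]] = {}
    for mag_id, seqs in mag_16s_sequences.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        mags[mag_id] = [_normalize_seq(s, f"MAG {mag_id} 16S") for s in seqs]
    for asv_id in sorted(asv_sequences):
        asv = _normalize_seq(asv_sequences[asv_id], f"ASV {asv_id}")
        if "N" in asv:
            continue  # an N can never be a mismatch-free match
        rc = str(Seq(asv).reverse_complement())
        for mag_id in sorted(mags):
            for subject in mags[mag_id]:
                if asv in subject or rc in subject:
                    links.append(AsvMagLink(asv_id, mag_id, "EXACT_16S"))
                    break
    return links


def read_ani_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns mag_a, mag_b, ani (percent)."""
    df = pd.read_csv(path, sep="\t", dtype={"mag_a": str, "mag_b": str})
    if not {"mag_a", "mag_b", "ani"} <= set(df.columns):
        raise ValidationError(f"ANI table {path}: need columns mag_a, mag_b, ani")
    return df


def _ani_lookup(ani_table: pd.DataFrame) -> dict[tuple[str, str], float]:
    lut: dict[tuple[str, str], float] = {}
    for row in ani_table.itertuples(index=False):
        ani = float(row.ani)
        if not (0 <= ani <= 100):
            raise ValidationError(f"ANI out of [0, 100]: {row.mag_a}-{row.mag_b} {ani}")
        for key in ((row.mag_a, row.mag_b), (row.mag_b, row.mag_a)):
            if key in lut and abs(lut[key] - ani) > 1e-6:
                raise ValidationError(
                    f"asymmetric ANI entries for pair {key}: {lut[key]} vs {ani}"
                )
            lut[key] = ani
    return lut


def extend_links_via_ani(
    links: Sequence[AsvMagLink],
    ani_table: pd.DataFrame,
    threshold: float = 95.0,
) -> list[AsvMagLink]:
    """One-step extension of exact links to MAGs with ANI >= threshold.

    For every EXACT_16S link (asv, A) and MAG B != A with ANI(A, B) >=
    threshold (inclusive), an ANI_EXTENSION link (asv, B, via=A) is added.
    Extensions never chain, duplicates collapse (smallest anchoring MAG id
    wins), and pairs already linked by exact evidence are not duplicated.
    """
    if not (0 < threshold <= 100):
        raise ValidationError(f"threshold must be in (0, 100], got {threshold}")
    lut = _ani_lookup(ani_table)
    exact_pairs = {(l.asv_id, l.mag_id) for l in links if l.evidence == "EXACT_16S"}
    extensions: dict[tuple[str, str], str] = {}
    for link in links:
        if link.evidence != "EXACT_16S":
            continue
        a = link.mag_id
        for (x, b), ani in lut.items():
            if x != a or b == a or ani < threshold:
                continue
            pair = (link.asv_id, b)
            if pair in exact_pairs:
                continue
            if pair not in extensions or a < extensions[pair]:
                extensions[pair] = a
    out = list(links)
    for (asv_id, mag_id), via in sorted(extensions.items()):
        out.append(AsvMagLink(asv_id, mag_id, "ANI_EXTENSION", via_mag_id=via))
    return out
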