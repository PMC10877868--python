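"""Synthetic fixtures with planted ground truth for every pipeline stage.

Generators emulate the shapes of the real inputs — Prokka-style GFF3 gene
coordinates with dbCAN-style annotations, per-gene average-coverage tables,
ASV count matrices with ASV/16S FASTA pools, pairwise ANI tables and MAG
quality statistics — while planting known truths: cluster spans, tiers and
substrates; an exact target-class coverage fraction; realized diversity
values; exact and ANI-extended ASV-MAG links; MAG quality tiers.

Randomness is organized as one independent stream per generator, derived
from the master seed and a fixed stream id, so adding a generator never
perturbs the fixtures of another, and a given spec is byte-identical across
runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    Gene,
    GeneTable,
    SubstrateMap,
    ValidationError,
    read_gff_and_annotations,
    read_substrate_map,
    write_gene_table,
)
from .cluster_detection import Cluster, is_degradative, is_marker
from .coverage_frequency import CoverageTable, write_coverage_table
from .community_link import FRACTIONS
from .mag_quality import MagStats, assign_quality_tier

# fixed per-generator stream ids
_STREAM_GENES = 1
_STREAM_COVERAGE = 2
_STREAM_COMMUNITY = 3
_STREAM_MAGS = 4

_BASES = np.array(list("ACGT"))


class SimulationSpecError(ValidationError):
    """The simulation spec is internally inconsistent."""


# ---------------------------------------------------------------------------
# Cluster templates (rosters drawn from well-described marine PUL types)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterTemplate:
    """Role/family layout of one planted locus with its expected truth."""

    name: str
    genes: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (families, roles)
    tier: str
    substrate: str | None


TEMPLATES: dict[str, ClusterTemplate] = {
    t.name: t
    for t in (
        # laminarin PUL: susCD tandem + GH16/GH17/GH3 (beta-glucan variant-2)
        ClusterTemplate(
            "beta_glucan_pul",
            (
                ((), ("SUSC",)),
                ((), ("SUSD",)),
                (("GH16",), ()),
                (("GH17",), ()),
                (("GH3",), ()),
            ),
            "PUL",
            "beta-1,3-glucan",
        ),
        # alpha-glucan type II PUL: susCD tandem + GH13/GH65/GH31
        ClusterTemplate(
            "alpha_glucan_type2_pul",
            (
                ((), ("SUSC",)),
                ((), ("SUSD",)),
                (("GH13",), ()),
                (("GH65",), ()),
                (("GH31",), ()),
            ),
            "PUL",
            "alpha-glucan",
        ),
        # alginolytic PUL-like cluster: lone TBDT + PL7/PL17 + sulfatase
        ClusterTemplate(
            "alginate_pul_like",
            (
                ((), ("TBDT_OTHER",)),
                (("PL7",), ()),
                (("PL17",), ()),
                ((), ("SULFATASE",)),
            ),
            "PUL_LIKE",
            "alginate",
        ),
        # transporter-free xylanolytic CAZyme-rich cluster
        ClusterTemplate(
            "xylan_cazyme_rich",
            (
                (("GH10",), ()),
                (("GH11",), ()),
                (("GH43",), ()),
            ),
            "CAZYME_RICH",
            "xylan",
        ),
    )
}

#: background marker annotation mixture: degradative CAZymes dominate;
#: susC/susD genes are far rarer genome-wide than CAZymes
_BACKGROUND_KINDS = ("degradative", "sulfatase", "tbdt_other", "susc", "susd")
_BACKGROUND_PROBS = (0.80, 0.10, 0.08, 0.01, 0.01)
_BACKGROUND_FAMILY_POOL = (
    "GH2", "GH5", "GH10", "GH13", "GH16", "GH29", "GH92", "GH28",
    "GH33", "PL1", "PL7", "CE4", "CE8",
)


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCluster:
    contig: int  # 0-based contig number
    start_index: int  # 0-based gene index of the first cluster gene
    template: str


@dataclass(frozen=True)
class CoverageModel:
    distribution: str = "lognormal"
    log_mean: float = 1.0
    log_sigma: float = 1.0
    target_class: str = "beta-1,3-glucan"
    target_fraction: float = 0.07


@dataclass(frozen=True)
class CommunityModel:
    n_samples: int = 9
    n_asvs: int = 100
    log_mean: float = 2.0
    log_sigma: float = 1.5


@dataclass(frozen=True)
class LinkModel:
    n_mags: int = 20
    n_exact_links: int = 10
    n_decoys: int = 10
    n_ani_extensions: int = 3
    asv_length: int = 400
    mag_16s_length: int = 1500


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic study; the seed fully determines
    every generated byte."""

    seed: int = 0
    n_contigs: int = 5
    genes_per_contig: int = 200
    planted_clusters: tuple[PlantedCluster, ...] = (
        PlantedCluster(0, 50, "beta_glucan_pul"),
        PlantedCluster(1, 50, "alpha_glucan_type2_pul"),
        PlantedCluster(2, 50, "alginate_pul_like"),
        PlantedCluster(3, 50, "xylan_cazyme_rich"),
        PlantedCluster(0, 120, "beta_glucan_pul"),
    )
    background_marker_rate: float = 0.0
    window_length: int = 10  # used for the planted-separation invariant
    coverage_model: CoverageModel = CoverageModel()
    community_model: CommunityModel = CommunityModel()
    link_model: LinkModel = LinkModel()
    mag_model: tuple[tuple[str, int], ...] = (
        ("HQ", 4), ("NEAR_COMPLETE", 3), ("MQ", 4), ("LQ", 3),
    )

    def __post_init__(self) -> None:
        if not (0 <= self.background_marker_rate <= 1):
            raise SimulationSpecError("background_marker_rate must be in [0, 1]")
        if not (0 <= self.coverage_model.target_fraction < 1):
            raise SimulationSpecError("planted target fraction must be in [0, 1)")
        lm = self.link_model
        if lm.n_exact_links + lm.n_decoys > self.community_model.n_asvs:
            raise SimulationSpecError("n_asvs smaller than planted link/decoy ASVs")
        by_contig: dict[int, list[PlantedCluster]] = {}
        for pc in self.planted_clusters:
            if pc.template not in TEMPLATES:
                raise SimulationSpecError(f"unknown template {pc.template!r}")
            if pc.contig >= self.n_contigs:
                raise SimulationSpecError("planted cluster on nonexistent contig")
            span_end = pc.start_index + len(TEMPLATES[pc.template].genes)
            if span_end > self.genes_per_contig:
                raise SimulationSpecError("planted cluster exceeds contig length")
            by_contig.setdefault(pc.contig, []).append(pc)
        for contig, pcs in by_contig.items():
            pcs = sorted(pcs, key=lambda p: p.start_index)
            for a, b in zip(pcs, pcs[1:]):
                gap = b.start_index - (a.start_index + len(TEMPLATES[a.template].genes))
                if gap < self.window_length:
                    raise SimulationSpecError(
                        f"planted clusters on contig {contig} overlap or are "
                        f"separated by fewer than window_length genes (gap {gap})"
                    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class PlantedClusterTruth:
    contig_id: str
    first_index: int
    last_index: int
    tier: str
    substrate: str | None
    template: str


@dataclass
class GroundTruth:
    """Everything the generators planted, for recovery scoring."""

    clusters: list[PlantedClusterTruth] = field(default_factory=list)
    target_class: str | None = None
    target_frequency_pct: float | None = None
    diversity: dict[str, dict[str, float]] = field(default_factory=dict)
    exact_links: list[tuple[str, str]] = field(default_factory=list)
    expected_extensions: list[tuple[str, str, str]] = field(default_factory=list)
    mag_tiers: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene fixture
# ---------------------------------------------------------------------------


def build_gene_table(spec: SimulationSpec) -> tuple[GeneTable, GroundTruth]:
    """Construct the annotated gene table in memory with planted clusters."""
    rng = _rng(spec, _STREAM_GENES)
    truth = GroundTruth()
    contigs: dict[str, list[Gene]] = {}
    planted_by_pos = {
        (pc.contig, pc.start_index + offset): (TEMPLATES[pc.template], offset)
        for pc in spec.planted_clusters
        for offset in range(len(TEMPLATES[pc.template].genes))
    }
    planted_strand = {
        (pc.contig, pc.start_index): "+" if rng.random() < 0.5 else "-"
        for pc in spec.planted_clusters
    }
    strand_at: dict[tuple[int, int], str] = {}
    for pc in spec.planted_clusters:
        for offset in range(len(TEMPLATES[pc.template].genes)):
            strand_at[(pc.contig, pc.start_index + offset)] = planted_strand[
                (pc.contig, pc.start_index)
            ]
    for c in range(spec.n_contigs):
        contig_id = f"contig_{c:03d}"
        genes: list[Gene] = []
        pos = 1
        for i in range(spec.genes_per_contig):
            length = 3 * int(rng.integers(100, 800))
            start, end = pos, pos + length - 1
            pos = end + 1 + int(rng.integers(20, 200))
            strand = strand_at.get((c, i)) or ("+" if rng.random() < 0.5 else "-")
            families: tuple[str, ...] = ()
            roles: tuple[str, ...] = ()
            if (c, i) in planted_by_pos:
                template, offset = planted_by_pos[(c, i)]
                families, roles = template.genes[offset]
            elif spec.background_marker_rate > 0 and rng.random() < spec.background_marker_rate:
                kind = _BACKGROUND_KINDS[
                    rng.choice(len(_BACKGROUND_KINDS), p=_BACKGROUND_PROBS)
                ]
                if kind == "degradative":
                    families = (str(rng.choice(_BACKGROUND_FAMILY_POOL)),)
                elif kind == "sulfatase":
                    roles = ("SULFATASE",)
                elif kind == "tbdt_other":
                    roles = ("TBDT_OTHER",)
                elif kind == "susc":
                    roles = ("SUSC",)
                else:
                    roles = ("SUSD",)
            genes.append(
                Gene(
                    gene_id=f"{contig_id}_g{i:04d}",
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    cazyme_families=frozenset(families),
                    roles=frozenset(roles),
                )
            )
        contigs[contig_id] = genes
    table = GeneTable(assembly_id="synthetic_assembly", contigs=contigs)
    for pc in spec.planted_clusters:
        t = TEMPLATES[pc.template]
        truth.clusters.append(
            PlantedClusterTruth(
                contig_id=f"contig_{pc.contig:03d}",
                first_index=pc.start_index,
                last_index=pc.start_index + len(t.genes) - 1,
                tier=t.tier,
                substrate=t.substrate,
                template=t.name,
            )
        )
    return table, truth


def generate_gene_fixture(
    spec: SimulationSpec, out_dir: str | Path
) -> tuple[GeneTable, GroundTruth]:
    """Write GFF3 + annotation TSV for the gene fixture; the written files
    are re-read and checked against the in-memory table before returning."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, truth = build_gene_table(spec)
    gff, annot = out_dir / "genes.gff3", out_dir / "annotations.tsv"
    write_gene_table(table, gff, annot)
    reread = read_gff_and_annotations(gff, annot, assembly_id=table.assembly_id)
    if [g for g in reread.genes()] != [g for g in table.genes()]:
        raise SimulationSpecError("round-trip check failed for the gene fixture")
    return table, truth


# ---------------------------------------------------------------------------
# Coverage fixture
# ---------------------------------------------------------------------------


def generate_coverage_fixture(
    gene_table: GeneTable,
    spec: SimulationSpec,
    out_path: str | Path | None = None,
    substrate_map: SubstrateMap | None = None,
) -> tuple[CoverageTable, float]:
    """Per-gene coverages rescaled so the planted target class holds exactly
    the planted fraction of total coverage; returns the table and the
    planted frequency in percent."""
    cm = spec.coverage_model
    substrate_map = substrate_map or read_substrate_map()
    rng = _rng(spec, _STREAM_COVERAGE)
    genes = list(gene_table.genes())
    cov = rng.lognormal(cm.log_mean, cm.log_sigma, size=len(genes))
    is_target = np.array(
        [
            any(
                is_degradative(f) and cm.target_class in substrate_map.lookup(f)
                for f in g.cazyme_families
            )
            for g in genes
        ]
    )
    f = cm.target_fraction
    if f > 0 and not is_target.any():
        raise SimulationSpecError(
            f"no genes target class {cm.target_class!r}; cannot plant fraction {f}"
        )
    if is_target.any():
        s_tar, s_non = cov[is_target].sum(), cov[~is_target].sum()
        if f == 0:
            cov[is_target] = 0.0
        else:
            cov[is_target] *= f * s_non / ((1.0 - f) * s_tar)
    table = CoverageTable(
        sample_id="synthetic_sample",
        coverage={g.gene_id: float(c) for g, c in zip(genes, cov)},
    )
    if out_path is not None:
        write_coverage_table(table, out_path)
    return table, 100.0 * f


# ---------------------------------------------------------------------------
# Community / linking fixture
# ---------------------------------------------------------------------------


@dataclass
class CommunityFixture:
    counts: pd.DataFrame
    fractions: dict[str, str]
    asv_sequences: dict[str, str]
    mag_16s_sequences: dict[str, str]
    ani_table: pd.DataFrame
    truth: GroundTruth


def _realized_diversity(counts: np.ndarray) -> dict[str, float]:
    """Closed-form diversity of one realized count vector (computed directly
    from the formulas, independently of the estimator wrappers)."""
    c = counts[counts > 0].astype(float)
    p = c / c.sum()
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return {
        "shannon": float(-(p * np.log(p)).sum()),
        "simpson": float(1.0 - (p**2).sum()),
        "chao1": float(len(c) + f1 * (f1 - 1) / (2.0 * (f2 + 1))),
        "goods": float(1.0 - f1 / c.sum()),
    }


def generate_community_fixture(
    spec: SimulationSpec, out_dir: str | Path | None = None
) -> CommunityFixture:
    """ASV counts, ASV/16S sequence pools, ANI table and planted link truth.

    Plants ``n_exact_links`` ASVs cut verbatim from MAG 16S sequences (half
    reverse-complemented), ``n_decoys`` one-mismatch near-copies that must
    never link, and an ANI table holding extension pairs at and above the
    95% species boundary (one at exactly 95.0) plus sub-threshold pairs (one
    at exactly 94.9).
    """
    cm, lm = spec.community_model, spec.link_model
    rng = _rng(spec, _STREAM_COMMUNITY)
    truth = GroundTruth()

    mag_ids = [f"mag_{i:03d}" for i in range(lm.n_mags)]
    mag_16s = {m: _random_seq(rng, lm.mag_16s_length) for m in mag_ids}

    asv_sequences: dict[str, str] = {}
    for i in range(lm.n_exact_links):
        mag = mag_ids[i % lm.n_mags]
        start = int(rng.integers(0, lm.mag_16s_length - lm.asv_length + 1))
        asv = mag_16s[mag][start : start + lm.asv_length]
        if i % 2 == 1:
            asv = _revcomp(asv)
        asv_id = f"asv_exact_{i:03d}"
        asv_sequences[asv_id] = asv
        truth.exact_links.append((asv_id, mag))
    for i in range(lm.n_decoys):
        mag = mag_ids[(i + 7) % lm.n_mags]
        start = int(rng.integers(0, lm.mag_16s_length - lm.asv_length + 1))
        asv = list(mag_16s[mag][start : start + lm.asv_length])
        pos = int(rng.integers(0, lm.asv_length))
        asv[pos] = str(rng.choice([b for b in "ACGT" if b != asv[pos]]))
        asv_sequences[f"asv_decoy_{i:03d}"] = "".join(asv)
    n_background = cm.n_asvs - lm.n_exact_links - lm.n_decoys
    for i in range(n_background):
        asv_sequences[f"asv_bg_{i:04d}"] = _random_seq(rng, lm.asv_length)

    asv_ids = sorted(asv_sequences)
    sample_ids = [f"sample_{i:02d}" for i in range(cm.n_samples)]
    fractions = {s: FRACTIONS[i % len(FRACTIONS)] for i, s in enumerate(sample_ids)}
    rates = rng.lognormal(cm.log_mean, cm.log_sigma, size=(cm.n_samples, cm.n_asvs))
    counts = rng.poisson(rates).astype(int)
    for r in range(cm.n_samples):  # diversity needs >= 1 positive count
        if counts[r].sum() == 0:
            counts[r, 0] = 1
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=asv_ids)
    for s in sample_ids:
        truth.diversity[s] = _realized_diversity(counts_df.loc[s].to_numpy())

    # ANI pairs: anchors are MAGs holding exact links; partners are MAGs
    # without 16S sequences of their own ("other-year" genomes)
    ani_rows = []
    anchor_mags = sorted({mag for _, mag in truth.exact_links})
    for i in range(lm.n_ani_extensions):
        anchor = anchor_mags[i % len(anchor_mags)]
        partner = f"mag_noribo_{i:03d}"
        ani = 95.0 if i == 0 else float(np.round(95.0 + rng.uniform(0.5, 4.0), 2))
        ani_rows.append({"mag_a": anchor, "mag_b": partner, "ani": ani})
    for i in range(lm.n_ani_extensions):
        anchor = anchor_mags[(i + 1) % len(anchor_mags)]
        partner = f"mag_noribo_lo_{i:03d}"
        ani = 94.9 if i == 0 else float(np.round(rng.uniform(80.0, 94.5), 2))
        ani_rows.append({"mag_a": anchor, "mag_b": partner, "ani": ani})
    ani_df = pd.DataFrame(ani_rows, columns=["mag_a", "mag_b", "ani"])

    exact_pairs = set(truth.exact_links)
    expected: dict[tuple[str, str], str] = {}
    for asv_id, mag in truth.exact_links:
        for row in ani_rows:
            if row["ani"] < 95.0:
                continue
            partner = None
            if row["mag_a"] == mag:
                partner = row["mag_b"]
            elif row["mag_b"] == mag:
                partner = row["mag_a"]
            if partner is None or (asv_id, partner) in exact_pairs:
                continue
            key = (asv_id, partner)
            if key not in expected or mag < expected[key]:
                expected[key] = mag
    truth.expected_extensions = [
        (asv, mag, via) for (asv, mag), via in sorted(expected.items())
    ]

    fixture = CommunityFixture(
        counts=counts_df,
        fractions=fractions,
        asv_sequences=asv_sequences,
        mag_16s_sequences=mag_16s,
        ani_table=ani_df,
        truth=truth,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        counts_df.to_csv(out_dir / "asv_counts.tsv", sep="\t")
        _write_fasta(asv_sequences, out_dir / "asvs.fasta")
        _write_fasta(mag_16s, out_dir / "mag_16s.fasta")
        ani_df.to_csv(out_dir / "ani.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample_id": sample_ids, "fraction": [fractions[s] for s in sample_ids]}
        ).to_csv(out_dir / "sample_fractions.tsv", sep="\t", index=False)
    return fixture


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


# ---------------------------------------------------------------------------
# MAG stats fixture
# ---------------------------------------------------------------------------


def generate_mag_stats_fixture(
    spec: SimulationSpec, out_path: str | Path | None = None
) -> tuple[list[MagStats], dict[str, str]]:
    """MAG quality statistics drawn inside each tier's defining region."""
    rng = _rng(spec, _STREAM_MAGS)
    stats: list[MagStats] = []
    truth: dict[str, str] = {}
    n = 0
    for tier, count in spec.mag_model:
        for _ in range(count):
            mag_id = f"sim_mag_{n:03d}"
            n += 1
            if tier == "HQ":
                s = MagStats(mag_id, float(rng.uniform(90.5, 99.9)),
                             float(rng.uniform(0.0, 4.5)), True, True, True,
                             int(rng.integers(18, 47)))
            elif tier == "NEAR_COMPLETE":
                s = MagStats(mag_id, float(rng.uniform(90.5, 99.9)),
                             float(rng.uniform(0.0, 4.5)), True, False, True,
                             int(rng.integers(18, 47)))
            elif tier == "MQ":
                s = MagStats(mag_id, float(rng.uniform(50.0, 89.5)),
                             float(rng.uniform(0.0, 9.5)), bool(rng.random() < 0.5),
                             bool(rng.random() < 0.5), bool(rng.random() < 0.5),
                             int(rng.integers(0, 30)))
            elif tier == "LQ":
                s = MagStats(mag_id, float(rng.uniform(5.0, 49.5)),
                             float(rng.uniform(0.0, 20.0)), False, False, False,
                             int(rng.integers(0, 18)))
            else:
                raise SimulationSpecError(f"unknown MAG tier {tier!r}")
            if assign_quality_tier(s) != tier:  # cannot happen by construction
                raise SimulationSpecError("MAG fixture violates its planted tier")
            stats.append(s)
            truth[mag_id] = tier
    if out_path is not None:
        pd.DataFrame(
            [
                {
                    "mag_id": s.mag_id,
                    "completeness": s.completeness,
                    "contamination": s.contamination,
                    "rrna_5s": int(s.has_5s),
                    "rrna_16s": int(s.has_16s),
                    "rrna_23s": int(s.has_23s),
                    "trna_count": s.trna_count,
                }
                for s in stats
            ]
        ).to_csv(out_path, sep="\t", index=False)
    return stats, truth


# ---------------------------------------------------------------------------
# Whole-study generation and recovery scoring
# ---------------------------------------------------------------------------


def generate_all(spec: SimulationSpec, out_dir: str | Path) -> GroundTruth:
    """Write every fixture plus a consolidated ground_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, truth = generate_gene_fixture(spec, out_dir)
    _, planted_freq = generate_coverage_fixture(
        table, spec, out_path=out_dir / "coverage.tsv"
    )
    community = generate_community_fixture(spec, out_dir=out_dir)
    _, mag_tiers = generate_mag_stats_fixture(spec, out_path=out_dir / "mag_stats.tsv")
    truth.target_class = spec.coverage_model.target_class
    truth.target_frequency_pct = planted_freq
    truth.diversity = community.truth.diversity
    truth.exact_links = community.truth.exact_links
    truth.expected_extensions = community.truth.expected_extensions
    truth.mag_tiers = mag_tiers
    truth.to_json(out_dir / "ground_truth.json")
    return truth


def evaluate_recovery(
    clusters: Sequence[Cluster],
    truth_clusters: Sequence[PlantedClusterTruth],
    exact_span: bool = True,
    check_substrate: bool = False,
) -> tuple[float, float]:
    """(recall, precision) of detected clusters against planted truth.

    With ``exact_span`` a planted cluster is recovered only by a detected
    cluster with identical span and tier (and headline substrate when
    requested); otherwise a detected span merely has to contain the planted
    span with matching tier — the right notion under background noise,
    which can legitimately extend a locus.
    """
    matched_truth: set[int] = set()
    matched_detected: set[int] = set()
    for ti, t in enumerate(truth_clusters):
        for ci, c in enumerate(clusters):
            if c.locus.contig_id != t.contig_id or c.tier != t.tier:
                continue
            if exact_span:
                span_ok = (
                    c.locus.first_index == t.first_index
                    and c.locus.last_index == t.last_index
                )
            else:
                span_ok = (
                    c.locus.first_index <= t.first_index
                    and c.locus.last_index >= t.last_index
                )
            if not span_ok:
                continue
            if check_substrate:
                preds = c.substrates
                if not preds or preds[0].substrate_class != t.substrate:
                    continue
            matched_truth.add(ti)
            matched_detected.add(ci)
            break
    recall = len(matched_truth) / len(truth_clusters) if truth_clusters else 1.0
    precision = len(matched_detected) / len(clusters) if clusters else 1.0
    return recall, precision
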