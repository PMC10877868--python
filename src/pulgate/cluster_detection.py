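"""Sliding-window detection of CAZyme-rich loci and three-tier classification.

A window of ``window_length`` consecutive genes slides along each contig
(step 1 gene); a window is a hit when at least ``min_markers`` of its genes
are marker genes — genes encoding a degradative CAZyme (GH/PL/CE family), a
sulfatase, or a TonB-dependent transporter component (SusC-like, SusD-like
or other TBDT).  Overlapping or abutting hit windows merge into one maximal
locus, trimmed so that its first and last genes are markers.

Merged loci are then classified into mutually exclusive tiers with strict
precedence:

* ``PUL``         — a susCD gene tandem plus >= 1 degradative CAZyme;
* ``PUL_LIKE``    — >= 1 susC-like, susD-like or other TBDT gene plus
                    >= 1 degradative CAZyme, but no tandem;
* ``CAZYME_RICH`` — >= 3 degradative CAZymes and no transporter gene;
* ``UNCLASSIFIED`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import (
    DEGRADATIVE_CLASSES,
    Gene,
    GeneTable,
    IntegrityError,
    ValidationError,
    family_class,
)

TIERS = ("PUL", "PUL_LIKE", "CAZYME_RICH", "UNCLASSIFIED")

#: roles that make a gene count as a transporter ("susC-, susD-like or other
#: TBDT gene") for the PUL-like tier test
TBDT_LIKE_ROLES = frozenset({"SUSC", "SUSD", "TBDT_OTHER"})

#: roles that qualify a gene as a marker for window detection
MARKER_ROLES = frozenset({"SUSC", "SUSD", "TBDT_OTHER", "SULFATASE"})


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the window detector and tier tests.

    ``count_genes_not_domains`` switches the ">= 3 degradative CAZymes"
    test of the CAZYME_RICH tier from counting family instances (a
    multi-domain gene with k degradative families contributes k, the
    default) to counting genes.
    """

    window_length: int = 10
    min_markers: int = 3
    tandem_policy: str = "same_strand_adjacent"
    count_genes_not_domains: bool = False

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValidationError("window_length must be >= 1")
        if not (1 <= self.min_markers <= self.window_length):
            raise ValidationError("need 1 <= min_markers <= window_length")
        if self.tandem_policy not in ("same_strand_adjacent", "adjacent_any_strand"):
            raise ValidationError(f"unknown tandem_policy {self.tandem_policy!r}")


@dataclass(frozen=True)
class CandidateLocus:
    """A maximal merged run of hit windows, trimmed to marker boundaries."""

    contig_id: str
    first_index: int
    last_index: int
    marker_gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.last_index < self.first_index:
            raise ValidationError("locus last_index < first_index")


@dataclass
class Cluster:
    """A classified locus with its member genes and marker tallies."""

    locus: CandidateLocus
    genes: list[Gene]
    tier: str
    degradative_families: tuple[str, ...]  # multiset, one entry per domain
    has_susCD_tandem: bool
    tandem_positions: tuple[tuple[int, int], ...]
    tbdt_like_count: int
    sulfatase_count: int
    substrates: list = field(default_factory=list)  # filled by substrate_typing


def is_degradative(family_label: str) -> bool:
    """True iff the family's class is GH, PL or CE (glycoside hydrolases,
    polysaccharide lyases, carbohydrate esterases); GT/CBM/AA are not
    degradative."""
    return family_class(family_label) in DEGRADATIVE_CLASSES


def is_marker(gene: Gene) -> bool:
    """True iff the gene qualifies as a window marker: it carries a
    degradative CAZyme family or a sulfatase/SusC/SusD/other-TBDT role."""
    if gene.roles & MARKER_ROLES:
        return True
    return any(is_degradative(f) for f in gene.cazyme_families)


def find_candidate_loci(
    gene_table: GeneTable, params: DetectionParams | None = None
) -> list[CandidateLocus]:
    """Detect candidate loci by the sliding-window rule.

    Windows never span contigs; contigs shorter than ``window_length`` are
    tested as a single window covering the whole contig.  Hit windows that
    overlap or abut merge into one maximal locus, trimmed so the first and
    last genes are markers.
    """
    params = params or DetectionParams()
    W, k = params.window_length, params.min_markers
    loci: list[CandidateLocus] = []
    for contig_id, genes in gene_table.contigs.items():
        n = len(genes)
        if n == 0:
            continue
        marker = [is_marker(g) for g in genes]
        # prefix sums of marker indicators for O(1) window counts
        pref = [0]
        for m in marker:
            pref.append(pref[-1] + int(m))
        if n <= W:
            starts = [0] if pref[n] >= k else []
            width = n
        else:
            starts = [s for s in range(n - W + 1) if pref[s + W] - pref[s] >= k]
            width = W
        # merge hit windows [s, s+width-1] that overlap or abut
        runs: list[list[int]] = []
        for s in starts:
            lo, hi = s, s + width - 1
            if runs and lo <= runs[-1][1] + 1:
                runs[-1][1] = hi
            else:
                runs.append([lo, hi])
        for lo, hi in runs:
            while lo <= hi and not marker[lo]:
                lo += 1
            while hi >= lo and not marker[hi]:
                hi -= 1
            if lo > hi:  # cannot happen when k >= 1, kept for safety
                continue
            loci.append(
                CandidateLocus(
                    contig_id=contig_id,
                    first_index=lo,
                    last_index=hi,
                    marker_gene_ids=tuple(
                        genes[i].gene_id for i in range(lo, hi + 1) if marker[i]
                    ),
                )
            )
    return loci


def detect_susCD_tandem(
    genes_in_locus: list[Gene], tandem_policy: str = "same_strand_adjacent"
) -> tuple[bool, list[tuple[int, int]]]:
    """Find susCD tandems: a SusC-like and a SusD-like gene at consecutive
    contig positions (either order), co-oriented under the default policy.

    Genes whose strand was inferred (missing in the GFF) disqualify tandems
    they participate in under ``same_strand_adjacent``.  Returns the flag and
    the list of (index, index+1) gene-index pairs found.
    """
    positions: list[tuple[int, int]] = []
    ordered = sorted(genes_in_locus, key=lambda g: g.index)
    for a, b in zip(ordered, ordered[1:]):
        if b.index != a.index + 1:
            continue
        pair_roles = ({"SUSC"} <= a.roles and {"SUSD"} <= b.roles) or (
            {"SUSD"} <= a.roles and {"SUSC"} <= b.roles
        )
        if not pair_roles:
            continue
        if tandem_policy == "same_strand_adjacent":
            if a.strand != b.strand or a.strand_inferred or b.strand_inferred:
                continue
        positions.append((a.index, b.index))
    return bool(positions), positions


def classify_cluster(
    locus: CandidateLocus,
    gene_table: GeneTable,
    params: DetectionParams | None = None,
) -> Cluster:
    """Classify a candidate locus into PUL / PUL_LIKE / CAZYME_RICH /
    UNCLASSIFIED with strict precedence in that order."""
    params = params or DetectionParams()
    if locus.contig_id not in gene_table.contigs:
        raise IntegrityError(f"locus names unknown contig {locus.contig_id!r}")
    genes = gene_table.contigs[locus.contig_id]
    if not (0 <= locus.first_index <= locus.last_index < len(genes)):
        raise IntegrityError(
            f"locus indices {locus.first_index}-{locus.last_index} out of range "
            f"for contig {locus.contig_id!r} with {len(genes)} genes"
        )
    members = genes[locus.first_index : locus.last_index + 1]

    degradative = tuple(
        sorted(f for g in members for f in sorted(g.cazyme_families) if is_degradative(f))
    )
    n_deg_genes = sum(
        1 for g in members if any(is_degradative(f) for f in g.cazyme_families)
    )
    deg_count = n_deg_genes if params.count_genes_not_domains else len(degradative)

    has_tandem, positions = detect_susCD_tandem(members, params.tandem_policy)
    tbdt_like = sum(1 for g in members if g.roles & TBDT_LIKE_ROLES)
    sulfatase = sum(1 for g in members if "SULFATASE" in g.roles)

    if has_tandem and deg_count >= 1:
        tier = "PUL"
    elif tbdt_like >= 1 and deg_count >= 1:
        tier = "PUL_LIKE"
    elif deg_count >= 3:
        tier = "CAZYME_RICH"
    else:
        tier = "UNCLASSIFIED"

    return Cluster(
        locus=locus,
        genes=list(members),
        tier=tier,
        degradative_families=degradative,
        has_susCD_tandem=has_tandem,
        tandem_positions=tuple(positions),
        tbdt_like_count=tbdt_like,
        sulfatase_count=sulfatase,
    )


def detect_clusters(
    gene_table: GeneTable, params: DetectionParams | None = None
) -> list[Cluster]:
    """Run detection and classification over a whole gene table."""
    params = params or DetectionParams()
    return [
        classify_cluster(locus, gene_table, params)
        for locus in find_candidate_loci(gene_table, params)
    ]
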