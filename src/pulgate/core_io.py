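"""Readers, writers and in-memory containers for annotated gene tables.

The pipeline consumes Prokka-style GFF3 gene coordinates together with a
sidecar TSV of functional annotations (CAZyme family labels in dbCAN style,
transporter/sulfatase role flags, optional taxon), and a family-to-substrate
map emulating dbCAN-sub.  All coordinates are 1-based inclusive; the
half-open convention used internally by some libraries never leaks out of
this module.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger("pulgate")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class PulgateError(Exception):
    """Base class for all package errors."""


class GffParseError(PulgateError):
    """A GFF3 line could not be parsed; the message names the line number."""


class IntegrityError(PulgateError):
    """Cross-references between inputs are inconsistent (duplicate or
    unknown identifiers, out-of-range indices)."""


class ValidationError(PulgateError):
    """A value violates its contract (unknown token, bad range, bad label)."""


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

CAZYME_CLASSES = ("GH", "PL", "CE", "GT", "CBM", "AA")
DEGRADATIVE_CLASSES = ("GH", "PL", "CE")

#: roles a gene may carry besides (or in addition to) CAZyme families
ROLES = frozenset({"SUSC", "SUSD", "TBDT_OTHER", "SULFATASE"})

#: substrate-class vocabulary of the packaged family->substrate map
SUBSTRATE_VOCABULARY = frozenset(
    {
        "beta-1,3-glucan",
        "alpha-glucan",
        "alginate",
        "host-glycan",
        "xylan",
        "peptidoglycan",
        "alpha-mannan",
        "beta-mannan",
        "pectin",
        "fucoidan",
        "sialic-acid",
        "alpha-rhamnoside",
        "chitin",
        "arabinan",
        "cellulose",
    }
)

#: reserved class for degradative families absent from the substrate map
UNASSIGNED_SUBSTRATE = "unassigned"

#: reserved taxon for genes without a taxonomic label
UNCLASSIFIED_TAXON = "unclassified"

_FAMILY_RE = re.compile(r"^(GH|PL|CE|GT|CBM|AA)(\d+)(?:_(\d+))?$")


def parse_family(label: str) -> tuple[str, int, int | None]:
    """Split a CAZyme family label into (class, family number, subfamily).

    Raises :class:`ValidationError` for labels that do not match the
    ``<class><number>[_<subfamily>]`` pattern, e.g. ``GH13_8``.
    """
    m = _FAMILY_RE.match(label)
    if m is None:
        raise ValidationError(f"malformed CAZyme family label: {label!r}")
    cls, fam, sub = m.groups()
    return cls, int(fam), None if sub is None else int(sub)


def base_family(label: str) -> str:
    """Collapse a subfamily label to its base family (``GH13_8`` -> ``GH13``)."""
    cls, fam, _ = parse_family(label)
    return f"{cls}{fam}"


def family_class(label: str) -> str:
    """Return the CAZyme class prefix of a family label."""
    return parse_family(label)[0]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    """One annotated coding gene on a contig.

    ``index`` is the 0-based rank of the gene along its contig after sorting
    by start coordinate; the sliding-window detector operates on indices,
    not base pairs.  ``strand_inferred`` marks genes whose strand was missing
    in the GFF and defaulted to "+"; such genes never support a susCD tandem
    under the strand-aware policy.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cazyme_families: frozenset[str] = frozenset()
    roles: frozenset[str] = frozenset()
    taxon: str | None = None
    index: int = -1
    strand_inferred: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id}: need end >= start >= 1, "
                f"got start={self.start}, end={self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        bad_roles = set(self.roles) - ROLES
        if bad_roles:
            raise ValidationError(
                f"gene {self.gene_id}: unknown role token(s): {sorted(bad_roles)}"
            )
        for fam in self.cazyme_families:
            parse_family(fam)  # raises on malformed labels


@dataclass
class GeneTable:
    """Per-contig ordered gene lists for one assembly.

    Construction sorts each contig by start coordinate, assigns consecutive
    0-based indices, and rejects duplicated gene ids.
    """

    assembly_id: str
    contigs: dict[str, list[Gene]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        ordered: dict[str, list[Gene]] = {}
        for contig_id, genes in self.contigs.items():
            genes = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
            genes = [replace(g, index=i, contig_id=contig_id) for i, g in enumerate(genes)]
            for g in genes:
                if g.gene_id in seen:
                    raise IntegrityError(f"duplicate gene_id: {g.gene_id!r}")
                seen.add(g.gene_id)
            ordered[contig_id] = genes
        self.contigs = ordered

    def genes(self) -> Iterable[Gene]:
        for genes in self.contigs.values():
            yield from genes

    def gene_by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes()}

    def n_genes(self) -> int:
        return sum(len(v) for v in self.contigs.values())


@dataclass
class SubstrateMap:
    """Mapping from CAZyme family labels to substrate-class sets.

    Lookup with a subfamily label falls back to the base family when the
    subfamily has no entry of its own.
    """

    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for fam, classes in self.entries.items():
            parse_family(fam)
            bad = set(classes) - SUBSTRATE_VOCABULARY
            if bad:
                raise ValidationError(
                    f"substrate map entry {fam}: unknown substrate label(s) {sorted(bad)}"
                )
        self.entries = {f: frozenset(c) for f, c in self.entries.items()}

    def lookup(self, family: str) -> frozenset[str]:
        """Substrate classes for a family label; empty set when unmapped."""
        if family in self.entries:
            return self.entries[family]
        base = base_family(family)
        return self.entries.get(base, frozenset())


# ---------------------------------------------------------------------------
# GFF3 + annotation-table reading
# ---------------------------------------------------------------------------


def _prevalidate_gff(gff_path: str | Path) -> None:
    """Line-by-line structural check so errors can name the offending line."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    return
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"{gff_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GffParseError(
                    f"{gff_path}: line {lineno}: non-integer coordinates "
                    f"{fields[3]!r}, {fields[4]!r}"
                ) from None
            if not (1 <= start <= end):
                raise GffParseError(
                    f"{gff_path}: line {lineno}: invalid interval {start}-{end}"
                )
            if fields[6] not in ("+", "-", ".", "?"):
                raise GffParseError(
                    f"{gff_path}: line {lineno}: invalid strand {fields[6]!r}"
                )


def _read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "cazyme_families", "roles"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"annotation table {path}: missing column(s) {sorted(missing)}"
        )
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise IntegrityError(f"annotation table {path}: duplicate gene_id(s) {dups}")
    return df


def _split_tokens(cell: str) -> list[str]:
    return [tok.strip() for tok in cell.split(",") if tok.strip()]


def read_gff_and_annotations(
    gff_path: str | Path,
    annotation_table_path: str | Path | None = None,
    assembly_id: str | None = None,
) -> GeneTable:
    """Build a :class:`GeneTable` from a GFF3 file and a sidecar annotation TSV.

    Parameters
    ----------
    gff_path
        GFF3 with CDS features carrying ``ID`` attributes.
    annotation_table_path
        TSV with columns ``gene_id``, ``cazyme_families`` (comma-separated,
        may be empty), ``roles`` (comma-separated, may be empty) and
        optionally ``taxon``.  Genes absent from the table get empty
        families/roles; table rows naming unknown genes raise
        :class:`IntegrityError`.
    """
    gff_path = Path(gff_path)
    _prevalidate_gff(gff_path)
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, merge_strategy="error"
        )
    except ValueError as exc:
        raise IntegrityError(f"{gff_path}: {exc}") from exc

    contigs: dict[str, list[Gene]] = {}
    for feat in db.features_of_type("CDS"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise GffParseError(
                f"{gff_path}: CDS at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks an ID attribute"
            )
        strand, inferred = feat.strand, False
        if strand not in ("+", "-"):
            logger.warning(
                "gene %s: missing strand in GFF, defaulting to '+'", ids[0]
            )
            strand, inferred = "+", True
        gene = Gene(
            gene_id=ids[0],
            contig_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=strand,
            strand_inferred=inferred,
        )
        contigs.setdefault(feat.seqid, []).append(gene)

    table = GeneTable(assembly_id=assembly_id or gff_path.stem, contigs=contigs)

    if annotation_table_path is not None:
        df = _read_annotation_table(annotation_table_path)
        by_id = table.gene_by_id()
        unknown = [gid for gid in df["gene_id"] if gid not in by_id]
        if unknown:
            raise IntegrityError(
                f"annotation table rows name gene_id(s) absent from the GFF: "
                f"{unknown[:10]}"
            )
        annotated: dict[str, Gene] = {}
        for row in df.itertuples(index=False):
            fams = _split_tokens(row.cazyme_families)
            roles = _split_tokens(row.roles)
            bad = [r for r in roles if r not in ROLES]
            if bad:
                raise ValidationError(
                    f"annotation table: unknown role token(s) {bad} "
                    f"for gene {row.gene_id}"
                )
            for fam in fams:
                parse_family(fam)
            taxon = getattr(row, "taxon", "") or None
            g = by_id[row.gene_id]
            annotated[row.gene_id] = replace(
                g,
                cazyme_families=frozenset(fams),
                roles=frozenset(roles),
                taxon=taxon,
            )
        table = GeneTable(
            assembly_id=table.assembly_id,
            contigs={
                cid: [annotated.get(g.gene_id, g) for g in genes]
                for cid, genes in table.contigs.items()
            },
        )
    return table


def write_gene_table(
    table: GeneTable, gff_path: str | Path, annotation_table_path: str | Path
) -> None:
    """Write a GeneTable back to GFF3 + annotation TSV (round-trip safe)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, genes in table.contigs.items():
            for g in genes:
                strand = "." if g.strand_inferred else g.strand
                fh.write(
                    f"{contig_id}\tpulgate\tCDS\t{g.start}\t{g.end}\t.\t"
                    f"{strand}\t0\tID={g.gene_id}\n"
                )
    rows = [
        {
            "gene_id": g.gene_id,
            "cazyme_families": ",".join(sorted(g.cazyme_families)),
            "roles": ",".join(sorted(g.roles)),
            "taxon": g.taxon or "",
        }
        for g in table.genes()
    ]
    pd.DataFrame(rows, columns=["gene_id", "cazyme_families", "roles", "taxon"]).to_csv(
        annotation_table_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Substrate map reading
# ---------------------------------------------------------------------------


def read_substrate_map(tsv_path: str | Path | None = None) -> SubstrateMap:
    """Load a family->substrate map; the packaged default when path is None.

    The TSV has columns ``family`` and ``substrates`` (semicolon-separated).
    Duplicate family rows union their substrate sets.
    """
    if tsv_path is None:
        ref = resources.files("pulgate").joinpath("data/substrate_map.tsv")
        with resources.as_file(ref) as p:
            return read_substrate_map(p)
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    if not {"family", "substrates"} <= set(df.columns):
        raise ValidationError(
            f"substrate map {tsv_path}: need columns 'family' and 'substrates'"
        )
    entries: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        classes = {tok.strip() for tok in row.substrates.split(";") if tok.strip()}
        entries.setdefault(row.family, set()).update(classes)
    return SubstrateMap(entries={f: frozenset(c) for f, c in entries.items()})


# ---------------------------------------------------------------------------
# Cluster report writing / reading
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "assembly_id",
    "contig_id",
    "first_gene_id",
    "last_gene_id",
    "start",
    "end",
    "first_index",
    "last_index",
    "n_genes",
    "tier",
    "has_susCD_tandem",
    "tbdt_like_count",
    "sulfatase_count",
    "degradative_families",
    "substrates",
]


def cluster_record(cluster, assembly_id: str) -> dict:
    """Flatten a classified Cluster into a serializable record."""
    genes = cluster.genes
    return {
        "assembly_id": assembly_id,
        "contig_id": cluster.locus.contig_id,
        "first_gene_id": genes[0].gene_id,
        "last_gene_id": genes[-1].gene_id,
        "start": genes[0].start,
        "end": genes[-1].end,
        "first_index": cluster.locus.first_index,
        "last_index": cluster.locus.last_index,
        "n_genes": len(genes),
        "tier": cluster.tier,
        "has_susCD_tandem": bool(cluster.has_susCD_tandem),
        "tbdt_like_count": int(cluster.tbdt_like_count),
        "sulfatase_count": int(cluster.sulfatase_count),
        "degradative_families": ",".join(cluster.degradative_families),
        "substrates": ";".join(
            f"{p.substrate_class}:{p.supporting_gene_count}" for p in cluster.substrates
        ),
    }


def write_cluster_report(
    clusters, path: str | Path, format: str = "tsv", assembly_id: str = ""
) -> None:
    """Serialize classified clusters to TSV or JSON (identical content)."""
    if format not in ("tsv", "json"):
        raise ValidationError(f"report format must be 'tsv' or 'json', got {format!r}")
    records = [cluster_record(c, assembly_id) for c in clusters]
    if format == "tsv":
        pd.DataFrame(records, columns=_REPORT_COLUMNS).to_csv(
            path, sep="\t", index=False
        )
    else:
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")


def read_cluster_report(path: str | Path, format: str = "tsv") -> list[dict]:
    """Read a cluster report back into the same record dicts."""
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    records = []
    for row in df.to_dict(orient="records"):
        for col in ("start", "end", "first_index", "last_index", "n_genes",
                    "tbdt_like_count", "sulfatase_count"):
            row[col] = int(row[col])
        row["has_susCD_tandem"] = row["has_susCD_tandem"] == "True"
        records.append(row)
    return records
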