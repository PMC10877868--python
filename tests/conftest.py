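"""Shared builders for hand-crafted gene tables and clusters."""

from __future__ import annotations

import pytest

from pulgate import (
    CandidateLocus,
    DetectionParams,
    Gene,
    GeneTable,
    classify_cluster,
)


def make_genes(specs, contig_id="c1"):
    """Build a contig's gene list from (families, roles, strand) triples."""
    genes = []
    pos = 1
    for i, (families, roles, strand) in enumerate(specs):
        genes.append(
            Gene(
                gene_id=f"{contig_id}_g{i:04d}",
                contig_id=contig_id,
                start=pos,
                end=pos + 899,
                strand=strand,
                cazyme_families=frozenset(families),
                roles=frozenset(roles),
                index=i,
            )
        )
        pos += 1000
    return genes


def make_table(specs_by_contig, assembly_id="test_assembly"):
    """GeneTable from {contig_id: [(families, roles, strand), ...]}."""
    return GeneTable(
        assembly_id=assembly_id,
        contigs={
            cid: make_genes(specs, cid) for cid, specs in specs_by_contig.items()
        },
    )


def cluster_from_specs(specs, params=None, contig_id="c1"):
    """Classify a locus spanning every gene of a single hand-built contig."""
    table = make_table({contig_id: specs})
    locus = CandidateLocus(
        contig_id=contig_id,
        first_index=0,
        last_index=len(specs) - 1,
        marker_gene_ids=(),
    )
    return classify_cluster(locus, table, params or DetectionParams())


@pytest.fixture
def default_params():
    return DetectionParams()
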