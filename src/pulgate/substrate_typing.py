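"""Substrate-class prediction for clusters and rule-based glucan PUL typing.

Substrate prediction counts, per substrate class, the cluster genes carrying
at least one degradative family that maps to the class (dbCAN-sub style); a
multi-specificity gene may support several classes.  The glucan typologies
operate on base GH families only and ignore families outside each scheme's
hallmark alphabet:

alpha-glucan PULs
    type I   — only GH13 (one or more copies);
    type II  — GH13 + GH65, optionally with GH31;
    type III — GH13 + GH77 + GH57;
    type IV  — only GH13 + GH31.

beta-glucan (laminarin) PULs
    GH16-only — only GH16;
    variant-2 — GH16 or GH17, together with GH3 (no other hallmarks);
    variant-1 — at least 3 of {GH149, GH17, GH16, GH158, GH30}
                (the roster admits variations; the threshold is tunable).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import (
    SubstrateMap,
    UNASSIGNED_SUBSTRATE,
    ValidationError,
    base_family,
)
from .cluster_detection import Cluster, is_degradative

ALPHA_GLUCAN_ALPHABET = frozenset({"GH13", "GH31", "GH57", "GH65", "GH77"})
BETA_GLUCAN_ALPHABET = frozenset({"GH3", "GH16", "GH17", "GH30", "GH149", "GH158"})
VARIANT1_HALLMARKS = frozenset({"GH149", "GH17", "GH16", "GH158", "GH30"})

ALPHA_LABELS = ("I", "II", "III", "IV", "none")
BETA_LABELS = ("variant-1", "variant-2", "GH16-only", "none")


@dataclass(frozen=True)
class SubstratePrediction:
    substrate_class: str
    supporting_gene_count: int
    supporting_families: frozenset[str]

    def __post_init__(self) -> None:
        if self.supporting_gene_count < 1:
            raise ValidationError("a substrate prediction needs >= 1 supporting gene")


@dataclass(frozen=True)
class GlucanType:
    """Label of a cluster under one of the two glucan typing schemes."""

    scheme: str  # "alpha" or "beta"
    label: str

    def __post_init__(self) -> None:
        valid = {"alpha": ALPHA_LABELS, "beta": BETA_LABELS}.get(self.scheme)
        if valid is None:
            raise ValidationError(f"unknown glucan scheme {self.scheme!r}")
        if self.label not in valid:
            raise ValidationError(
                f"label {self.label!r} not valid for scheme {self.scheme!r}"
            )


def predict_substrates(
    cluster: Cluster, substrate_map: SubstrateMap
) -> list[SubstratePrediction]:
    """Per-class supporting-gene counts for one cluster.

    Classes are returned sorted by descending gene count, then ascending
    label.  Genes whose degradative families all lack a map entry are
    tallied under the reserved "unassigned" class.  Genes without any
    degradative family contribute nothing.
    """
    gene_counts: dict[str, int] = {}
    families: dict[str, set[str]] = {}
    for gene in cluster.genes:
        deg = [f for f in gene.cazyme_families if is_degradative(f)]
        if not deg:
            continue
        classes_hit: set[str] = set()
        unmapped: set[str] = set()
        for fam in deg:
            mapped = substrate_map.lookup(fam)
            if mapped:
                for cls in mapped:
                    classes_hit.add(cls)
                    families.setdefault(cls, set()).add(fam)
            else:
                unmapped.add(fam)
        if not classes_hit and unmapped:
            classes_hit.add(UNASSIGNED_SUBSTRATE)
            families.setdefault(UNASSIGNED_SUBSTRATE, set()).update(unmapped)
        for cls in classes_hit:
            gene_counts[cls] = gene_counts.get(cls, 0) + 1
    preds = [
        SubstratePrediction(cls, count, frozenset(families[cls]))
        for cls, count in gene_counts.items()
    ]
    preds.sort(key=lambda p: (-p.supporting_gene_count, p.substrate_class))
    return preds


def _base_families(cluster: Cluster, alphabet: frozenset[str]) -> frozenset[str]:
    return frozenset(
        base_family(f) for f in cluster.degradative_families
    ) & alphabet


def type_alpha_glucan_pul(cluster: Cluster) -> GlucanType:
    """Assign the alpha-glucan PUL type from the cluster's hallmark GH set."""
    F = _base_families(cluster, ALPHA_GLUCAN_ALPHABET)
    if F == {"GH13"}:
        label = "I"
    elif F in ({"GH13", "GH65"}, {"GH13", "GH65", "GH31"}):
        label = "II"
    elif F == {"GH13", "GH77", "GH57"}:
        label = "III"
    elif F == {"GH13", "GH31"}:
        label = "IV"
    else:
        label = "none"
    return GlucanType(scheme="alpha", label=label)


def type_beta_glucan_pul(
    cluster: Cluster, variant1_min_families: int = 3
) -> GlucanType:
    """Assign the beta-glucan (laminarin) PUL type.

    Precedence GH16-only > variant-2 > variant-1 makes the labelling total
    over all subsets of the hallmark alphabet.
    """
    F = _base_families(cluster, BETA_GLUCAN_ALPHABET)
    if F == {"GH16"}:
        label = "GH16-only"
    elif F <= {"GH16", "GH17", "GH3"} and "GH3" in F and ("GH16" in F or "GH17" in F):
        label = "variant-2"
    elif len(F & VARIANT1_HALLMARKS) >= variant1_min_families:
        label = "variant-1"
    else:
        label = "none"
    return GlucanType(scheme="beta", label=label)


def annotate_substrates(
    clusters: list[Cluster], substrate_map: SubstrateMap
) -> list[Cluster]:
    """Fill each cluster's ``substrates`` field in place and return the list."""
    for c in clusters:
        c.substrates = predict_substrates(c, substrate_map)
    return clusters


def headline_substrate(cluster: Cluster) -> str | None:
    """The top-ranked substrate class of a cluster, or None if unpredicted."""
    preds = cluster.substrates
    return preds[0].substrate_class if preds else None
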