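"""Biosynthetic gene cluster extraction and cross-species synteny.

Secondary-metabolite pathways in fungi are typically encoded by clusters of
co-localized genes: a backbone synthase, tailoring enzymes, a pathway
regulator and an efflux transporter.  This module delineates the cluster
around an anchor gene (e.g. the trichodiene synthase *tri5*) by intergenic
gap chaining over GFF3 gene features, assigns functional roles to cluster
members from their domain annotations, and compares cluster composition and
gene order between genomes via reciprocal-best-hit orthology and Kendall
rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import kendalltau

from .classify import DomainAnnotation
from .phylo import AlignmentParams, pairwise_identity


@dataclass(frozen=True)
class GeneFeature:
    """One gene feature; coordinates 1-based inclusive base pairs."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class ClusterModel:
    """An anchor-centered gene cluster, members sorted by start."""

    anchor_id: str
    members: tuple  # of (gene_id, role) pairs in coordinate order
    features: tuple  # of GeneFeature, same order
    contig: str

    @property
    def span_kb(self) -> float:
        return (self.features[-1].end - self.features[0].start + 1) / 1000.0

    @property
    def gene_ids(self) -> tuple:
        return tuple(g for g, _ in self.members)


@dataclass(frozen=True)
class RoleRule:
    """Maps domain accessions or description keywords to a member role."""

    role: str
    accessions: frozenset = frozenset()
    keywords: tuple = ()

    def __post_init__(self):
        if not self.accessions and not self.keywords:
            raise ValueError("a role rule needs at least one trigger")

    def matches(self, annotations: Sequence[DomainAnnotation]) -> bool:
        for ann in annotations:
            if ann.accession in self.accessions:
                return True
            desc = ann.description.lower()
            if any(kw.lower() in desc for kw in self.keywords):
                return True
        return False


DEFAULT_ROLE_RULES = (
    RoleRule("trichodiene synthase", frozenset({"PF06330", "PIRSF001388"}), ("trichodiene",)),
    RoleRule("Zn2-C6 transcription factor", frozenset({"PF00172"}), ("zn(2)-cys(6)", "zn2-c6", "zinc cluster")),
    RoleRule("oxygenase", frozenset({"PF00067"}), ("oxygenase", "p450")),
    RoleRule("alpha-beta hydrolase", frozenset({"PF12697"}), ("alpha/beta hydrolase", "abhydrolase")),
    RoleRule("MFS transporter", frozenset({"PF07690"}), ("major facilitator", "mfs")),
    RoleRule("carbonic anhydrase", frozenset({"PF00194"}), ("carbonic anhydrase",)),
)


def extract_cluster(
    features: Iterable[GeneFeature],
    anchor_id: str,
    max_gap: int = 3000,
    roles: Optional[Mapping[str, str]] = None,
) -> ClusterModel:
    """Grow a cluster left and right from the anchor by gap chaining.

    The next gene on the anchor's contig joins the cluster while the
    intergenic gap does not exceed ``max_gap`` base pairs.  Output is
    invariant to the input order of features.
    """
    anchors = [f for f in features if f.gene_id == anchor_id]
    if not anchors:
        raise ValueError(f"anchor {anchor_id!r} not found")
    if len(anchors) > 1:
        raise ValueError(f"anchor {anchor_id!r} is duplicated")
    anchor = anchors[0]
    on_contig = sorted((f for f in features if f.contig == anchor.contig), key=lambda f: (f.start, f.gene_id))
    idx = on_contig.index(anchor)
    lo = idx
    while lo > 0 and on_contig[lo].start - on_contig[lo - 1].end - 1 <= max_gap:
        lo -= 1
    hi = idx
    while hi < len(on_contig) - 1 and on_contig[hi + 1].start - on_contig[hi].end - 1 <= max_gap:
        hi += 1
    chosen = tuple(on_contig[lo : hi + 1])
    roles = roles or {}
    members = tuple((f.gene_id, roles.get(f.gene_id, "")) for f in chosen)
    return ClusterModel(anchor_id, members, chosen, anchor.contig)


def assign_gene_roles(
    annotations: Mapping[str, Sequence[DomainAnnotation]],
    rules: Sequence[RoleRule] = DEFAULT_ROLE_RULES,
) -> dict:
    """Assign each member its first matching role; default 'hypothetical protein'."""
    out = {}
    for gene_id, anns in annotations.items():
        role = "hypothetical protein"
        for rule in rules:
            if rule.matches(anns):
                role = rule.role
                break
        out[gene_id] = role
    return out


def _reciprocal_best_pairs(
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    proteins: Mapping[str, str],
    threshold: float,
    params: Optional[AlignmentParams] = None,
) -> list[tuple]:
    ident: dict[tuple, float] = {}
    for ga in ids_a:
        for gb in ids_b:
            ident[(ga, gb)] = pairwise_identity(proteins[ga], proteins[gb], params)
    pairs = []
    for ga in ids_a:
        gb = max(ids_b, key=lambda g: (ident[(ga, g)], g))
        if ident[(ga, gb)] < threshold:
            continue
        back = max(ids_a, key=lambda g: (ident[(g, gb)], g))
        if back == ga:
            pairs.append((ga, gb))
    return pairs


def synteny_compare(
    cluster_a: ClusterModel,
    cluster_b: ClusterModel,
    proteins: Mapping[str, str],
    identity_threshold: float = 50.0,
    params: Optional[AlignmentParams] = None,
) -> tuple[list, float]:
    """Shared members and gene-order conservation between two clusters.

    Orthologs are reciprocal best hits with percent identity at or above
    ``identity_threshold``.  Order conservation is the absolute Kendall tau
    of the shared members' rank orders after orientation normalization
    (clusters whose anchors lie on opposite strands are compared in
    reversed order); with at most one shared pair it is 1.0 by convention.
    """
    pairs = _reciprocal_best_pairs(cluster_a.gene_ids, cluster_b.gene_ids, proteins, identity_threshold, params)
    if len(pairs) <= 1:
        return pairs, 1.0
    strand_a = next(f.strand for f in cluster_a.features if f.gene_id == cluster_a.anchor_id)
    strand_b = next(f.strand for f in cluster_b.features if f.gene_id == cluster_b.anchor_id)
    order_b = list(cluster_b.gene_ids)
    if strand_a != strand_b:
        order_b = order_b[::-1]
    rank_a = {g: i for i, g in enumerate(cluster_a.gene_ids)}
    rank_b = {g: i for i, g in enumerate(order_b)}
    xs = [rank_a[ga] for ga, _ in pairs]
    ys = [rank_b[gb] for _, gb in pairs]
    tau = kendalltau(xs, ys).statistic
    return pairs, abs(float(tau))


def presence_matrix(
    genomes: Mapping[str, Mapping[str, str]],
    queries: Mapping[str, str],
    identity_threshold: float = 50.0,
    params: Optional[AlignmentParams] = None,
):
    """Species-by-gene presence table via reciprocal best identity.

    ``genomes`` maps species to their protein sets (id -> sequence);
    a query gene is present in a species when its reciprocal best hit there
    reaches ``identity_threshold`` percent identity.  Raising the threshold
    never adds a presence.
    """
    import pandas as pd

    if not genomes:
        raise ValueError("at least one genome is required")
    qnames = list(queries)
    table = {}
    for species, prots in genomes.items():
        pids = list(prots)
        ident = {
            (q, g): pairwise_identity(queries[q], prots[g], params) for q in qnames for g in pids
        }
        row = {}
        for q in qnames:
            if not pids:
                row[q] = False
                continue
            g = max(pids, key=lambda x: (ident[(q, x)], x))
            back = max(qnames, key=lambda x: (ident[(x, g)], x))
            row[q] = ident[(q, g)] >= identity_threshold and back == q
        table[species] = row
    frame = pd.DataFrame.from_dict(table, orient="index")
    return frame.reindex(index=list(genomes), columns=qnames).fillna(False).astype(bool)
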