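"""Rule-based functional classification of terpene synthase proteins.

Each protein is assigned to exactly one leaf of a functional taxonomy from
three streams of evidence: database domain annotations (InterProScan-style
accessions), catalytic-motif hits from :mod:`tpsinv.motifs`, and the presence
of a C-terminal transmembrane helix.  The default taxonomy partitions the
Trichoderma terpene synthase family into 15 terminal groups spanning
sesquiterpene synthases of the TRI5 superfamily, terpene synthase C enzymes,
squalene synthase, oxidosqualene cyclase, protein-prenylation enzymes,
Class II diterpene synthases and the polyprenyl synthase superfamily;
prenylation and polyprenyl subtypes (GGTase 1/2, FTase; GGPP/FPP synthase,
indole diterpene synthase, chimeric-like) are attached as secondary
annotations rather than leaves.

Leaves are evaluated in precedence order; the first leaf whose domain, motif
and transmembrane requirements are all satisfied wins, which makes the
mapping total and deterministic.  Proteins satisfying no leaf are reported
as ``unclassified`` rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .motifs import FoldCall, MotifHit, MotifPattern, classify_fold, default_motifs, detect_tm_helix, scan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DomainAnnotation:
    """One database hit on a protein; coordinates 1-based inclusive."""

    protein_id: str
    source_db: str
    accession: str
    start: int
    end: int
    description: str = ""


@dataclass(frozen=True)
class FunctionalGroup:
    """A terminal classification label and its evidence requirements.

    ``required_domains`` is a tuple of any-of sets: every set must be hit by
    at least one observed accession.  ``required_motifs`` are motif pattern
    names that must all be present.
    """

    id: str
    display_name: str
    required_domains: tuple = ()
    required_motifs: frozenset = frozenset()
    forbidden_domains: frozenset = frozenset()
    needs_tm: bool = False
    precedence: int = 0

    def satisfied_by(self, accessions: set, motif_names: set, tm: Optional[tuple]) -> Optional[list[str]]:
        """Evidence strings when all requirements hold, else ``None``."""
        evidence = []
        for anyof in self.required_domains:
            found = anyof & accessions
            if not found:
                return None
            evidence.append(f"domain:{'|'.join(sorted(found))}")
        missing = self.required_motifs - motif_names
        if missing:
            return None
        evidence.extend(f"motif:{m}" for m in sorted(self.required_motifs))
        if self.forbidden_domains & accessions:
            return None
        if self.needs_tm:
            if tm is None:
                return None
            evidence.append(f"tm:{tm[0]}+{tm[1]}")
        return evidence


@dataclass(frozen=True)
class Taxonomy:
    """Ordered set of functional groups; leaves sorted by precedence."""

    leaves: tuple
    version: str = "default"

    def __post_init__(self):
        ids = [g.id for g in self.leaves]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate group ids in taxonomy")
        precs = [g.precedence for g in self.leaves]
        if len(precs) != len(set(precs)):
            raise ValueError("duplicate precedence values in taxonomy")
        object.__setattr__(self, "leaves", tuple(sorted(self.leaves, key=lambda g: g.precedence)))

    def __len__(self):
        return len(self.leaves)

    def group(self, group_id: str) -> FunctionalGroup:
        for g in self.leaves:
            if g.id == group_id:
                return g
        raise KeyError(group_id)


@dataclass
class ClassificationResult:
    protein_id: str
    group_id: str  # a leaf id or "unclassified"
    fold_call: FoldCall
    evidence: list = field(default_factory=list)
    subtype: str = ""


# Secondary (subtype) annotations keyed by diagnostic accession.
SUBTYPE_ACCESSIONS = {
    "PTHR11774:SF4": "GGTase1",
    "PTHR11774:SF11": "GGTase2",
    "PTHR11774:SF6": "FTase",
    "PTHR12001:SF47": "GGPP_synthase",
    "PTHR11525:SF0": "FPP_synthase",
    "INDOLE_DITS": "indole_diTS",
    "CHIMERIC_LIKE": "chimeric_like",
}


def _parse_bool(s: str) -> bool:
    return s.strip() in ("1", "true", "True", "yes")


def parse_taxonomy_table(text: str, version: str = "custom") -> Taxonomy:
    """Parse a tab-separated taxonomy config (see bundled ``taxonomy.tsv``)."""
    leaves = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 7:
            raise ValueError(f"taxonomy line {lineno}: expected 7 tab-separated fields")
        gid, name, domains, motifs, forbidden, needs_tm, precedence = parts[:7]
        req = tuple(
            frozenset(a.strip() for a in grp.split(",") if a.strip())
            for grp in domains.split("|")
            if grp.strip()
        )
        leaves.append(
            FunctionalGroup(
                id=gid.strip(),
                display_name=name.strip(),
                required_domains=req,
                required_motifs=frozenset(m.strip() for m in motifs.split(",") if m.strip()),
                forbidden_domains=frozenset(d.strip() for d in forbidden.split(",") if d.strip()),
                needs_tm=_parse_bool(needs_tm),
                precedence=int(precedence),
            )
        )
    return Taxonomy(tuple(leaves), version=version)


def load_taxonomy(path=None) -> Taxonomy:
    """Load a taxonomy config, or the bundled 15-leaf default."""
    if path is None:
        text = resources.files("tpsinv.data").joinpath("taxonomy.tsv").read_text()
        return parse_taxonomy_table(text, version="default-15")
    with open(path) as fh:
        return parse_taxonomy_table(fh.read())


def classify_protein(
    domains: Sequence[DomainAnnotation],
    fold_call: Optional[FoldCall] = None,
    motif_hits: Sequence[MotifHit] = (),
    tm: Optional[tuple] = None,
    taxonomy: Optional[Taxonomy] = None,
) -> ClassificationResult:
    """Assign one protein to the first taxonomy leaf it satisfies.

    ``unclassified`` is a value, not an error: proteins lacking any known
    signature stay visible in the inventory.
    """
    taxonomy = taxonomy or load_taxonomy()
    accessions = {d.accession for d in domains}
    motif_names = {h.pattern_name for h in motif_hits}
    protein_id = domains[0].protein_id if domains else ""
    subtype = ",".join(sorted({SUBTYPE_ACCESSIONS[a] for a in accessions if a in SUBTYPE_ACCESSIONS}))
    fold_call = fold_call or FoldCall("none")
    for leaf in taxonomy.leaves:
        evidence = leaf.satisfied_by(accessions, motif_names, tm)
        if evidence is not None:
            return ClassificationResult(protein_id, leaf.id, fold_call, evidence, subtype)
    return ClassificationResult(protein_id, "unclassified", fold_call, [], subtype)


def classify_panel(
    proteins: Sequence[tuple],
    domain_rows: Iterable[DomainAnnotation],
    patterns: Optional[Sequence[MotifPattern]] = None,
    taxonomy: Optional[Taxonomy] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify a panel of ``(protein_id, sequence)`` records.

    Domain rows referencing unknown protein ids are skipped with a logged
    warning.  Returns the per-protein classification table and per-group
    counts (including ``unclassified``); counts always sum to the panel size.
    """
    patterns = patterns if patterns is not None else default_motifs()
    taxonomy = taxonomy or load_taxonomy()
    ids = [pid for pid, _ in proteins]
    by_protein: dict[str, list[DomainAnnotation]] = {pid: [] for pid in ids}
    for row in domain_rows:
        if row.protein_id not in by_protein:
            logger.warning("domain row for unknown protein %r skipped", row.protein_id)
            continue
        by_protein[row.protein_id].append(row)
    rows = []
    for pid, seq in proteins:
        hits = scan(seq, patterns)
        fold = classify_fold(hits, patterns)
        tm = detect_tm_helix(seq)
        res = classify_protein(by_protein[pid], fold, hits, tm, taxonomy)
        rows.append(
            {
                "protein_id": pid,
                "group_id": res.group_id,
                "subtype": res.subtype,
                "fold": fold.value,
                "n_motif_hits": len(hits),
                "evidence": ";".join(res.evidence),
            }
        )
    table = pd.DataFrame(
        rows, columns=["protein_id", "group_id", "subtype", "fold", "n_motif_hits", "evidence"]
    )
    counts = table["group_id"].value_counts() if len(table) else pd.Series(dtype=int)
    return table, counts


# Groups excluded from expression-candidate selection: Class II enzymes,
# terpene-precursor synthases feeding primary metabolism, and the
# protein-prenylation machinery.
EXCLUDED_GROUPS = frozenset(
    {"had_bifunctional", "oxidosqualene_cyclase", "class2_diterpene", "protein_prenylation"}
)
EXCLUDED_SUBTYPES = frozenset({"GGPP_synthase", "FPP_synthase"})


def select_expression_candidates(inventory: pd.DataFrame) -> pd.DataFrame:
    """Filter an inventory table down to expression-study candidates.

    Keeps Class I terpene synthases, dropping :data:`EXCLUDED_GROUPS` and the
    GGPP/FPP synthase subtypes of the polyprenyl superfamily.  An optional
    ``override`` column with ``include``/``exclude`` values takes precedence
    over the rule.
    """
    if inventory.empty:
        return inventory
    subtype = inventory["subtype"] if "subtype" in inventory else pd.Series("", index=inventory.index)
    keep = ~inventory["group_id"].isin(EXCLUDED_GROUPS) & ~subtype.fillna("").isin(EXCLUDED_SUBTYPES)
    if "override" in inventory:
        override = inventory["override"].fillna("")
        keep = keep & (override != "exclude") | (override == "include")
    return inventory[keep]


def table1_inventory() -> pd.DataFrame:
    """The bundled 16-gene T. gamsii T6085 terpene synthase inventory."""
    text = resources.files("tpsinv.data").joinpath("table1_tgamsii.tsv").read_text()
    rows = []
    for raw in text.splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = (raw.split("\t") + ["", ""])[:5]
        rows.append(dict(zip(["jgi_id", "name", "group_id", "subtype", "override"], parts)))
    return pd.DataFrame(rows, columns=["jgi_id", "name", "group_id", "subtype", "override"])
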