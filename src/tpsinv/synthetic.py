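"""Deterministic synthetic fixtures for the terpene synthase pipeline.

Three generators emulate the pipeline's real-world inputs:

* a protein panel with one or more members per functional group, each
  carrying its group's domain accessions (as InterProScan-style annotation
  rows) and catalytic motifs planted verbatim into a random background —
  with the background sanitized so that no *unplanned* motif or
  transmembrane signal appears, which makes truth labels exactly
  recoverable at mutation rate zero;
* a trichodiene-synthase-anchored gene cluster locus (anchor plus six
  flanking genes — regulator, tailoring enzymes and transporter — spanning
  21.2 kb) as GFF3-style gene features with member proteins and domain
  annotations;
* qPCR Ct tables with planted fold changes, reference-gene and basal
  structure, replicate hierarchy, Gaussian Ct noise and explicit
  non-detections, built so that the exact Livak computation on a
  zero-noise table returns the planted folds.

All outputs are byte-deterministic in the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import DomainAnnotation, Taxonomy, load_taxonomy
from .cluster import GeneFeature
from .motifs import CANONICAL, KYTE_DOOLITTLE, MotifPattern, default_motifs, scan

# ---------------------------------------------------------------------------
# Protein panel

# Concrete motif instantiations planted per group (order = placement order).
GROUP_MOTIF_PLANTS: dict[str, tuple] = {
    "had_bifunctional": ("DDAAE", "DADTT"),
    "tri5": ("DDSRE", "NDLFSFYKE"),
    "longiborneol": ("DDHFD",),
    "tri5_unchar1": ("DDAAE",),
    "tri5_unchar2": ("DDAAE",),
    "presilphiperfolanol": ("DDAAD",),
    "pentalenene": ("DDAAE", "NSD", "DTE"),
    "tsc_unchar3": ("DDAAE",),
    "tsc_unchar4": ("DDAAE",),
    "squalene_synthase": (),
    "protein_prenylation": (),
    "oxidosqualene_cyclase": ("DCTAE", "QW", "QW", "QW", "QW", "QW"),
    "sqs_psy_unchar5": (),
    "class2_diterpene": ("DADD",),
    "polyprenyl_superfamily": ("DDAAD", "DDAAD"),
}

# Fixed domain accessions emitted per group; replicated members of the
# prenylation and polyprenyl leaves cycle through subtype accessions.
GROUP_DOMAINS: dict[str, tuple] = {
    "had_bifunctional": ("PF13419", "PTHR43611:SF3", "IPR008930"),
    "tri5": ("PF06330", "PIRSF001388"),
    "longiborneol": ("PF06330",),
    "tri5_unchar1": ("PF06330", "UNCHAR1"),
    "tri5_unchar2": ("PF06330", "UNCHAR2"),
    "presilphiperfolanol": ("PF03936",),
    "pentalenene": ("PF03936",),
    "tsc_unchar3": ("PF03936", "UNCHAR3"),
    "tsc_unchar4": ("PF03936", "UNCHAR4"),
    "squalene_synthase": ("PF00494", "PTHR11626:SF2", "PS01044"),
    "protein_prenylation": (),
    "oxidosqualene_cyclase": ("PF13249", "PF13243", "PTHR11764", "PS01074"),
    "sqs_psy_unchar5": ("PF00494", "PTHR21181:SF13"),
    "class2_diterpene": ("PTHR31739:SF4", "PIRSF026498"),
    "polyprenyl_superfamily": ("PF00348",),
}

SUBTYPE_CYCLES: dict[str, tuple] = {
    "protein_prenylation": (
        ("GGTase1", ("PTHR11774:SF4",)),
        ("GGTase2", ("PTHR11774:SF11",)),
        ("FTase", ("PTHR11774:SF6",)),
    ),
    "polyprenyl_superfamily": (
        ("GGPP_synthase", ("PTHR12001:SF47", "PS00723", "PS00444")),
        ("FPP_synthase", ("PTHR11525:SF0", "PS00723", "PS00444")),
        ("indole_diTS", ("INDOLE_DITS",)),
        ("chimeric_like", ("CHIMERIC_LIKE",)),
    ),
}

TM_GROUPS = frozenset({"squalene_synthase"})

_SOURCE_DB = {
    "PF": "Pfam",
    "PTHR": "PANTHER",
    "PS": "PROSITE",
    "PIRSF": "PIRSF",
    "IPR": "InterPro",
}


def _source_db(accession: str) -> str:
    for prefix in ("PIRSF", "PTHR", "PF", "PS", "IPR"):
        if accession.startswith(prefix):
            return _SOURCE_DB[prefix]
    return "CLUSTER"  # placeholder phylogenetic-cluster evidence


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic protein panel."""

    taxonomy: Optional[Taxonomy] = None
    n_per_group: int = 1
    mutation_rate: float = 0.0
    background_length: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation_rate must lie in [0, 1)")


# Transmembrane helix plant: 19 residues of hydropathy 2.5 (cysteine)
# between glutamate flanks.  With the default Kyte-Doolittle window of 19
# and threshold 1.6, windows reaching at most two residues into a flank
# pass and deeper ones fail, so the covered run is exactly 23 residues.
_TM_HELIX = "E" * 6 + "C" * 19 + "E" * 6
TM_RUN_LENGTH = 23


def mutate_sequence(seq: str, rate: float, protected: Iterable[int], seed: int) -> str:
    """Substitute residues outside ``protected`` (0-based positions).

    Each unprotected position mutates independently with probability
    ``rate`` to a uniformly drawn *different* canonical residue; length is
    preserved.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    protected = set(protected)
    rng = np.random.default_rng(seed)
    out = list(seq)
    n = len(out)
    draws = rng.random(n)
    choices = rng.integers(0, 19, size=n)
    for i in range(n):
        if i in protected or draws[i] >= rate:
            continue
        alphabet = CANONICAL.replace(out[i], "")
        out[i] = alphabet[choices[i] % len(alphabet)]
    return "".join(out)


def _breaker_residue(allowed: frozenset) -> Optional[str]:
    for candidate in "GPAVST":
        if candidate not in allowed:
            return candidate
    return None


def _sanitize(
    seq: list,
    protected: set,
    patterns: Sequence[MotifPattern],
    tm_allowed_starts: Optional[range],
    max_rounds: int = 300,
) -> None:
    """Remove unplanned motif matches and hydropathy windows, in place.

    Planted windows (``protected``) are never touched; offending background
    positions are deterministically rewritten.
    """
    n = len(seq)
    for _ in range(max_rounds):
        changed = False
        hits = scan("".join(seq), patterns)
        for hit in hits:
            span = range(hit.start - 1, hit.start - 1 + len(hit.matched))
            if all(p in protected for p in span):
                continue
            pat = next(p for p in patterns if p.name == hit.pattern_name)
            fixed = False
            # prefer the most constrained (most literal) unprotected position
            order = sorted(
                (k for k in range(len(span)) if span[k] not in protected),
                key=lambda k: len(pat.compiled[k]),
            )
            for k in order:
                breaker = _breaker_residue(pat.compiled[k])
                if breaker is not None:
                    seq[span[k]] = breaker
                    fixed = changed = True
                    break
            if fixed:
                break  # rescan from scratch
        if changed:
            continue
        if tm_allowed_starts is not None:
            window = 19
            values = [KYTE_DOOLITTLE[r] for r in seq]
            for s in range(n - window + 1):
                if s in tm_allowed_starts:
                    continue
                if sum(values[s : s + window]) / window >= 1.6:
                    candidates = [k for k in range(s, s + window) if k not in protected]
                    candidates = [k for k in candidates if values[k] > KYTE_DOOLITTLE["D"]]
                    if candidates:
                        # de-hydrophobize the strongest contributor
                        seq[max(candidates, key=lambda k: values[k])] = "D"
                        changed = True
                        break
        if not changed:
            return
    raise RuntimeError("sanitization did not converge")  # pragma: no cover


def _build_protein(
    group_id: str,
    rng: np.random.Generator,
    background_length: int,
    patterns: Sequence[MotifPattern],
) -> tuple[str, set]:
    """Random background with the group's motifs (and TM helix) planted."""
    L = background_length
    seq = [CANONICAL[i] for i in rng.integers(0, 20, size=L)]
    protected: set = set()
    pos = int(L * 0.55)
    for motif in GROUP_MOTIF_PLANTS[group_id]:
        if pos + len(motif) > L - 40:
            pos = int(L * 0.25)  # wrap around for long plant lists
        seq[pos : pos + len(motif)] = list(motif)
        protected.update(range(pos, pos + len(motif)))
        pos += len(motif) + 25
    tm_allowed = None
    if group_id in TM_GROUPS:
        start = L - 12 - len(_TM_HELIX)
        seq[start : start + len(_TM_HELIX)] = list(_TM_HELIX)
        protected.update(range(start, start + len(_TM_HELIX)))
        helix_start = start + 6
        tm_allowed = range(helix_start - 2, helix_start + 3)
    _sanitize(seq, protected, patterns, tm_allowed)
    return "".join(seq), protected


def generate_protein_panel(
    spec: PanelSpec,
) -> tuple[list, list, pd.DataFrame]:
    """Generate the panel: protein records, domain rows and truth labels.

    Returns ``(records, domain_rows, truth)`` where records are
    ``(protein_id, sequence)`` pairs, domain rows are
    :class:`~tpsinv.classify.DomainAnnotation` and truth is a DataFrame
    with protein_id, group_id and subtype.  Every protein carries its
    group's required motifs verbatim; mutation (if any) never touches the
    planted windows.
    """
    taxonomy = spec.taxonomy or load_taxonomy()
    patterns = default_motifs()
    unknown = [g.id for g in taxonomy.leaves if g.id not in GROUP_MOTIF_PLANTS]
    if unknown:
        raise ValueError(f"no generator recipe for groups: {unknown}")
    records: list = []
    domain_rows: list = []
    truth_rows: list = []
    for leaf_index, leaf in enumerate(taxonomy.leaves):
        for rep in range(spec.n_per_group):
            rng = np.random.default_rng([spec.seed, leaf_index, rep])
            pid = f"{leaf.id}_{rep + 1:02d}"
            seq, protected = _build_protein(leaf.id, rng, spec.background_length, patterns)
            if spec.mutation_rate > 0:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                seq = mutate_sequence(seq, spec.mutation_rate, protected, sub_seed)
            accessions = list(GROUP_DOMAINS[leaf.id])
            subtype = ""
            if leaf.id in SUBTYPE_CYCLES:
                cycle = SUBTYPE_CYCLES[leaf.id]
                subtype, extra = cycle[rep % len(cycle)]
                accessions.extend(extra)
            for acc in accessions:
                domain_rows.append(
                    DomainAnnotation(pid, _source_db(acc), acc, 10, len(seq) - 10, f"{leaf.display_name} signature")
                )
            records.append((pid, seq))
            truth_rows.append({"protein_id": pid, "group_id": leaf.id, "subtype": subtype})
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "group_id", "subtype"])
    return records, domain_rows, truth


# ---------------------------------------------------------------------------
# Cluster locus

DEFAULT_MEMBER_ROLES = (
    ("tgA", "Zn2-C6 transcription factor"),
    ("tgB", "oxygenase"),
    ("tgC", "alpha-beta hydrolase"),
    ("tgD", "oxygenase"),
    ("tgE", "MFS transporter"),
    ("tgF", "carbonic anhydrase"),
)

_ROLE_DOMAINS = {
    "Zn2-C6 transcription factor": ("PF00172", "fungal Zn(2)-Cys(6) binuclear cluster domain"),
    "oxygenase": ("PF00067", "cytochrome P450 oxygenase"),
    "alpha-beta hydrolase": ("PF12697", "alpha/beta hydrolase fold"),
    "MFS transporter": ("PF07690", "Major Facilitator Superfamily transporter"),
    "carbonic anhydrase": ("PF00194", "carbonic anhydrase"),
    "trichodiene synthase": ("PF06330", "trichodiene synthase (TRI5)"),
}


@dataclass(frozen=True)
class ClusterLayout:
    """Layout of the anchor-centered synthetic locus.

    The default reproduces a 21.2 kb trichodiene-synthase cluster: three
    members upstream of the anchor and three downstream, 500 bp intergenic
    gaps, member genes of 2.7 kb and a 2.0 kb anchor.
    """

    anchor_name: str = "tri5"
    member_roles: tuple = DEFAULT_MEMBER_ROLES
    total_span: float = 21.2  # kilobases
    intergenic_gaps: Optional[tuple] = None
    strands: Optional[tuple] = None
    upstream_count: int = 3
    contig: str = "contig_1"
    origin: int = 1001
    anchor_length: Optional[int] = None

    def __post_init__(self):
        if self.total_span <= 0:
            raise ValueError("total_span must be > 0")
        gaps = self.intergenic_gaps
        if gaps is not None:
            if len(gaps) != len(self.member_roles):
                raise ValueError("need one intergenic gap per member")
            if any(g < 0 for g in gaps):
                raise ValueError("intergenic gaps must be >= 0")
        names = [self.anchor_name] + [n for n, _ in self.member_roles]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene names in layout")

    def resolve(self) -> tuple[list, list, list]:
        """(ordered gene names+roles, lengths, gaps) summing to the span."""
        span_bp = int(round(self.total_span * 1000))
        n_members = len(self.member_roles)
        gaps = list(self.intergenic_gaps) if self.intergenic_gaps is not None else [500] * n_members
        if n_members == 0:
            anchor_len = self.anchor_length or span_bp
            return [(self.anchor_name, "trichodiene synthase")], [anchor_len], []
        anchor_len = self.anchor_length or 2000
        remaining = span_bp - anchor_len - sum(gaps)
        if remaining < n_members:
            raise ValueError("total_span too small for the requested layout")
        base = remaining // n_members
        lengths_members = [base] * n_members
        lengths_members[-1] += remaining - base * n_members  # absorb rounding
        ordered = []
        lengths = []
        up = self.member_roles[: self.upstream_count]
        down = self.member_roles[self.upstream_count :]
        for k, (name, role) in enumerate(up):
            ordered.append((name, role))
            lengths.append(lengths_members[k])
        ordered.append((self.anchor_name, "trichodiene synthase"))
        lengths.append(anchor_len)
        for k, (name, role) in enumerate(down):
            ordered.append((name, role))
            lengths.append(lengths_members[self.upstream_count + k])
        return ordered, lengths, gaps


@dataclass(frozen=True)
class ClusterLocus:
    features: tuple  # GeneFeature, coordinate order
    roles: dict  # gene_id -> role
    proteins: dict  # gene_id -> amino-acid sequence
    domains: dict  # gene_id -> list[DomainAnnotation]


def generate_cluster_locus(layout: Optional[ClusterLayout] = None, seed: int = 0) -> ClusterLocus:
    """Emit the synthetic anchor locus: features, roles, proteins, domains."""
    layout = layout or ClusterLayout()
    ordered, lengths, gaps = layout.resolve()
    default_strands = ("+", "-", "+", "+", "-", "+", "-")
    strands = layout.strands or tuple(default_strands[i % len(default_strands)] for i in range(len(ordered)))
    if len(strands) != len(ordered):
        raise ValueError("need one strand per gene")
    features = []
    pos = layout.origin
    for k, ((name, role), length) in enumerate(zip(ordered, lengths)):
        features.append(GeneFeature(layout.contig, pos, pos + length - 1, strands[k], name))
        pos += length + (gaps[k] if k < len(gaps) else 0)
    rng = np.random.default_rng([seed, 77])
    roles = {name: role for name, role in ordered}
    proteins = {}
    domains = {}
    for name, role in ordered:
        aa_len = 300
        proteins[name] = "".join(CANONICAL[i] for i in rng.integers(0, 20, size=aa_len))
        acc, desc = _ROLE_DOMAINS.get(role, ("", "hypothetical protein"))
        domains[name] = (
            [DomainAnnotation(name, _source_db(acc), acc, 5, aa_len - 5, desc)] if acc else []
        )
    return ClusterLocus(tuple(features), roles, proteins, domains)


# ---------------------------------------------------------------------------
# Ct tables

LIQUID_CONDITIONS = ("MM", "sucrose", "H2O2", "N_starvation", "NaCl")
EXPRESSION_GENES = ("ts1", "ts3", "ts4", "ts5", "ts6", "ts7", "ts9", "ts11", "tri5")


@dataclass(frozen=True)
class CtDesign:
    """Design of a synthetic qPCR Ct table.

    ``planted_fold`` maps (gene, condition) to the true 2^-ddCt; unlisted
    cells default to 1.  The basal condition and the reference gene must be
    1 everywhere.  ``absent`` cells are emitted as non-detections (empty Ct).
    """

    genes: tuple = EXPRESSION_GENES
    conditions: tuple = LIQUID_CONDITIONS
    basal_condition: str = "MM"
    planted_fold: Mapping = field(default_factory=dict)
    reference_gene: str = "beta-tubulin"
    n_bio: int = 3
    n_tech: int = 3
    noise_sd: float = 0.0
    absent: frozenset = frozenset()
    seed: int = 0
    base_ct_reference: float = 20.0
    base_ct_target: float = 24.0

    def __post_init__(self):
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.basal_condition not in self.conditions:
            raise ValueError("basal condition missing from conditions")
        for (gene, cond), fold in self.planted_fold.items():
            if fold <= 0:
                raise ValueError(f"planted fold for {(gene, cond)} must be > 0")
            if cond == self.basal_condition and fold != 1:
                raise ValueError("basal condition folds must be 1")
            if gene == self.reference_gene and fold != 1:
                raise ValueError("reference gene folds must be 1")

    def fold(self, gene: str, condition: str) -> float:
        return float(self.planted_fold.get((gene, condition), 1.0))


def generate_ct_table(design: CtDesign) -> pd.DataFrame:
    """Emit the Ct table; exact Livak recovery holds at zero noise.

    The reference gene sits at a base Ct of 20 cycles and targets at 24;
    a planted fold f lowers the target's condition Ct by log2(f).  The
    Livak statistic is invariant to these arbitrary bases.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    genes = list(design.genes)
    if design.reference_gene not in genes:
        genes.append(design.reference_gene)
    for gene in genes:
        for cond in design.conditions:
            base = design.base_ct_reference if gene == design.reference_gene else design.base_ct_target
            fold = 1.0 if gene == design.reference_gene else design.fold(gene, cond)
            absent = (gene, cond) in design.absent
            for bio in range(1, design.n_bio + 1):
                for tech in range(1, design.n_tech + 1):
                    if absent:
                        ct = float("nan")
                    else:
                        noise = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
                        ct = base - math.log2(fold) + noise
                    rows.append(
                        {"gene": gene, "condition": cond, "bio_rep": bio, "tech_rep": tech, "ct": ct}
                    )
    return pd.DataFrame(rows, columns=["gene", "condition", "bio_rep", "tech_rep", "ct"])


def liquid_culture_design(noise_sd: float = 0.0, seed: int = 0, n_bio: int = 3, n_tech: int = 3) -> CtDesign:
    """Liquid-culture stress experiment: basal minimal medium vs sucrose,
    oxidative, nitrogen-starvation and saline conditions, with the reported
    fold changes planted and the three never-detected genes absent."""
    folds = {
        ("ts3", "sucrose"): 0.1,
        ("ts4", "sucrose"): 18.7,
        ("ts1", "sucrose"): 2.0,
        ("ts9", "sucrose"): 2.0,
        ("ts3", "H2O2"): 0.3,
        ("ts6", "H2O2"): 0.6,
        ("ts9", "H2O2"): 2.7,
        ("ts3", "N_starvation"): 0.4,
        ("ts11", "N_starvation"): 0.4,
        ("ts3", "NaCl"): 0.02,
        ("ts4", "NaCl"): 0.1,
        ("ts6", "NaCl"): 0.33,
        ("ts9", "NaCl"): 0.2,
        ("ts11", "NaCl"): 0.25,
    }
    absent = frozenset((g, c) for g in ("tri5", "ts5", "ts7") for c in LIQUID_CONDITIONS)
    return CtDesign(
        planted_fold=folds, noise_sd=noise_sd, absent=absent, seed=seed, n_bio=n_bio, n_tech=n_tech
    )


def root_colonization_design(noise_sd: float = 0.0, seed: int = 0, n_bio: int = 3, n_tech: int = 3) -> CtDesign:
    """Wheat-root colonization experiment: basal mycelium on PDA vs roots."""
    folds = {
        ("tri5", "roots"): 134.0,
        ("ts3", "roots"): 0.59,
        ("ts4", "roots"): 0.03,
        ("ts5", "roots"): 1.58,
        ("ts6", "roots"): 1.52,
        ("ts9", "roots"): 0.28,
        ("ts11", "roots"): 2.58,
    }
    absent = frozenset({("ts7", "PDA"), ("ts7", "roots")})
    return CtDesign(
        conditions=("PDA", "roots"),
        basal_condition="PDA",
        planted_fold=folds,
        noise_sd=noise_sd,
        absent=absent,
        seed=seed,
        n_bio=n_bio,
        n_tech=n_tech,
    )


def spike_interaction_design(noise_sd: float = 0.0, seed: int = 0, n_bio: int = 3, n_tech: int = 3) -> CtDesign:
    """Wheat-spike experiment: antagonist alone (basal) vs with the pathogen."""
    folds = {("ts11", "with_pathogen"): 1.45}
    active = ("ts1", "ts6", "ts9", "ts11")
    absent = frozenset(
        (g, c)
        for g in EXPRESSION_GENES
        if g not in active
        for c in ("alone", "with_pathogen")
    )
    return CtDesign(
        genes=active,
        conditions=("alone", "with_pathogen"),
        basal_condition="alone",
        planted_fold=folds,
        noise_sd=noise_sd,
        absent=absent,
        seed=seed,
        n_bio=n_bio,
        n_tech=n_tech,
    )
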