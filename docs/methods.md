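# Methods

This note documents the scientific conventions behind `tpsinv`: what each
module computes, the defaults that matter, what the synthetic fixtures do
and do not emulate, and the design choices made where more than one
reasonable convention exists.

## Motif grammars and fold calls

Catalytic metal-binding motifs are expressed in a minimal grammar: plain
amino-acid letters match themselves, `x` matches any of the 20 canonical
residues, and a bracketed set such as `[DE]` matches any of its members.
The bundled motif table (`tpsinv/data/motifs.tsv`) covers the family's
published consensus motifs: the generic Class I `D[DE]xx[DE]` and its
`DDxxD`/`DDxxE` variants, the Class II `DxDD` and its `DxDTT` variant, the
trichodiene synthase aspartate-rich motif `DDS[RI]E` (covering the
DDSRE/DDSIE forms) with its `NDLFSFYKE` triad, the longiborneol synthase
`[DN][DE]HFD` family (covering DDHFD/DEHFD and the partially conserved
NDHFD), the oxidosqualene cyclase `DC[TI][AS]E` family (the classical DCTAE
and its DCTSE/DCISE variants), the QW structural repeat, and the NSD/DTE
triad of pentalenene-synthase-like proteins. The NSD/DTE entry is encoded
as the two literal tripeptides flagged accessory; the full consensus of
this triad is not published, so the encoding is a placeholder convention
rather than an assertion about the native motif.

Scanning is exact and exhaustive: every window of every pattern is tested,
overlapping matches are all reported (needed, e.g., to count the two DDxxD
motifs of polyprenyl synthases), positions are 1-based inclusive to match
GFF3 conventions, and the ambiguity code `X` in input sequences satisfies
only full wildcards — an unknown residue cannot certify a catalytic
aspartate. Profile-HMM searching was deliberately replaced by exact
consensus matching: consensus strings are what the literature prints, and
exact matching is deterministic and directly testable against a brute-force
oracle. The fold call is a pure function of the fold-class tags among a
protein's hits: Class I evidence only → `class_I`, Class II only →
`class_II`, both → `bifunctional`, neither → `none`; accessory motifs never
change the call.

## Transmembrane-helix detection

Squalene synthases carry a C-terminal transmembrane anchor. The detector
slides a Kyte–Doolittle window (default 19 residues, textbook default) over
the C-terminal half of the protein (`cterm_fraction = 0.5`) and marks
windows whose mean hydropathy reaches 1.6; the reported helix is the
longest run of residues covered by any marked window. Note a property of
this (standard) union-of-windows convention: a very hydrophobic core
bleeds into its flanks, because a window containing a few flanking residues
still clears the threshold. A 23-residue poly-leucine stretch therefore
reports a run longer than 23, whereas a marginally hydrophobic helix has
sharp boundaries. The synthetic squalene-synthase fixture exploits this
deliberately: its planted helix is 19 residues of hydropathy 2.5 flanked by
glutamates, for which windows reaching at most two residues into a flank
pass and deeper ones fail — the detected run is exactly the 23 residues of
the native squalene-synthase anchor.

## The 15-group taxonomy

The default taxonomy (`tpsinv/data/taxonomy.tsv`) partitions the family
into 15 terminal groups. Groups are defined by required domain accessions
(with any-of sets), required motif names, optional forbidden accessions and
a transmembrane requirement, and are evaluated in precedence order; the
first satisfied leaf wins, so classification is total, deterministic and
independent of input order. Proteins satisfying no leaf are reported as
`unclassified`, never dropped.

Two conventions deserve comment:

- *Granularity.* The family literature names more functional labels than
  groups; this taxonomy merges the three protein-prenylation enzymes
  (GGTase 1, GGTase 2, FTase) into one leaf and the polyprenyl-domain
  enzymes (GGPP synthase, FPP synthase, indole diterpene synthase,
  chimeric-like) into another, with subtypes attached as secondary
  annotations keyed by their diagnostic PANTHER/PROSITE accessions. This
  matches the color-cluster granularity of family-wide phylogenies while
  keeping the count of 15; the taxonomy is a plain-text config and can be
  swapped wholesale.
- *Uncharacterized groups.* The five uncharacterized groups have no public
  database signature — in the original analysis they are defined by
  phylogenetic clustering. The taxonomy encodes them with placeholder
  cluster accessions (`UNCHAR1`–`UNCHAR5`, likewise `INDOLE_DITS`,
  `CHIMERIC_LIKE` for subtypes), which the synthetic generator emits in the
  domain TSV as `CLUSTER`-sourced rows. These placeholders stand in for
  clade-membership evidence; on real data they would be produced by
  `phylo.assign_by_reference` (whose labels are advisory: when a rule label
  and a phylogenetic label conflict, the deterministic rule label wins).
- *Expression candidates.* The selector keeps Class I terpene synthases
  and drops the HAD-like bifunctional, oxidosqualene cyclase, Class II
  diterpene synthase and protein-prenylation groups plus the GGPP/FPP
  synthase subtypes. Squalene synthase is *not* excluded: although it
  feeds triterpene precursor metabolism, the published candidate set
  includes it, and the stated exclusion set above reproduces that set
  exactly on the bundled 16-gene inventory without an override. An
  `override` column (include/exclude) is supported for inventories where a
  rule alone cannot reproduce a curated selection.

## Pairwise alignment, identity, trees

Global alignment is Gotoh affine-gap dynamic programming under BLOSUM62
(gap open 10, extend 0.5; a gap of length L costs `open + (L−1)·extend`;
terminal gaps are penalized). The DP is vectorized row-by-row, the
horizontal state is folded in with a running-maximum recurrence, and the
traceback breaks ties deterministically (diagonal > up > left). Scores are
cross-checked in the test suite against Biopython's independent pairwise
aligner. Percent identity defaults to the `trimmed` convention (terminal
gap-run columns excluded from the denominator), with a `full` option that
divides by all columns; only under `full` is identity 100 equivalent to
sequence equality (a nested substring reaches 100 under `trimmed`). Both
conventions are exposed because published pairwise identities rarely state
which one was used.

Trees are built by canonical neighbor joining on p-distances
(1 − identity/100; no rate correction — no model is needed for
clade-membership tests at fixture scale). Ties in the Q criterion resolve
to the lowest (row, column) pair in agglomeration order; negative branch
lengths are clamped to zero with the deficit moved to the sister edge so
path lengths are preserved. On additive matrices NJ is exact, which the
suite verifies against randomly generated trees of up to 8 taxa. Bootstrap
supports resample alignment columns with replacement (default 100
replicates, one RNG stream seeded once; taxa are canonicalized to sorted
order so input order cannot matter) and report the percentage of replicate
topologies containing each internal bipartition. This NJ + nonparametric
bootstrap stack is a deliberate desk-scale proxy for Bayesian/ML tree
building: it is dependency-free, deterministic, and sufficient to express
the decision rule that matters here — clade membership at support ≥ 50.

A query is labeled by the reference clade it nests within: walking from the
query tip towards the root, the first ancestor containing references
yields its label when those references agree and the clade's support meets
the threshold; a mixed clade or insufficient support yields `unassigned`.
When the query attaches directly at the (trifurcating) root, the nearest
pure-labeled root subtree passing the threshold is used, with proximity
measured by mean p-distance. Multiple alignment for mixed-length inputs is
progressive (profiles merged bottom-up along a preliminary NJ guide tree
with sum-of-pairs BLOSUM scoring and a flat per-column gap cost of 8) —
adequate for reference panels of a few dozen sequences, not a general MSA
engine.

## Cluster extraction and synteny

Cluster delineation is intergenic-gap chaining: starting from the anchor
gene, neighbors on the same contig join while the intergenic gap is at most
`max_gap` (default 3000 bp). This transparent rule reproduces the intended
21.2 kb seven-gene fixture cluster; a dedicated BGC caller's boundary rule
on real genomes may differ, and `max_gap` is exposed for that reason.
Member roles come from first-match rules over domain accessions and
description keywords (Zn2-C6 transcription factor, oxygenase, alpha-beta
hydrolase, MFS transporter, carbonic anhydrase, trichodiene synthase;
unmatched members are "hypothetical protein"). Synteny between two
clusters uses reciprocal-best-hit orthologs at ≥ 50 % identity; order
conservation is the absolute Kendall tau of the shared members' ranks
after orientation normalization (if the anchors lie on opposite strands one
order is reversed — synteny is strand-relative), with ≤ 1 shared pair
defined as 1.0. Species-by-gene presence uses the same reciprocal-best
rule, so raising the identity threshold can only remove presences.
Horizontal-gene-transfer inference is explicitly out of scope.

## Livak 2^−ΔΔCt analysis

Technical replicates are averaged arithmetically; a cell whose technical
replicates are at least half non-detections is called absent (the
"majority-absent" rule is this package's convention — source data only
report that transcripts were undetected — and the aggregation is exposed
separately so other rules can be applied). ΔCt subtracts the reference
gene's Ct within the same condition and biological replicate; ΔΔCt
subtracts the mean basal ΔCt; the reported fold is `2^(−mean ΔΔCt)` — the
geometric mean of replicate folds — so the basal condition is exactly 1 by
construction and the reference gene is exactly 1 everywhere. Folds are
invariant to adding any constant to all Ct values. Absent cells propagate
to absent results, never imputed; a gene absent in the basal condition has
no defined fold anywhere.

Per gene, conditions are compared by one-way ANOVA on ΔΔCt — the log2
scale — rather than on raw folds, because folds are log-normal under
additive Ct noise (the choice of scale is otherwise unstated in common
practice). Per-condition stars come from the Tukey HSD comparison against
the basal condition at the conventional thresholds (ns at p ≥ 0.05, `*`
below 0.05, `**` below 0.01, `***` below 0.001; the boundary p = 0.05 is
not significant). ANOVA is run per gene across conditions (consistent with
per-gene significance stars on expression bar charts). Zero within-group
variance — the noise-free fixtures — is degenerate for both F and Tukey
statistics: equal means are flagged and reported not-significant; unequal
means with zero variance are reported as p = 0. Disease-severity
percentages are compared by one-way ANOVA after the angular transform
`x → arcsin(sqrt(x/100))`. Primer-efficiency correction and
multiple-testing correction across genes are out of scope (the latter
matching common practice for small candidate panels).

## Synthetic fixtures

The generators exist so every pipeline stage has an input whose ground
truth is known exactly.

*Protein panel.* Each functional group contributes proteins of 400
residues (background drawn uniformly from the 20 canonical amino acids; no
compositional realism is claimed or needed) with the group's motifs planted
verbatim starting at 55 % of the length, 25 residues apart, and the
squalene-synthase TM helix planted near the C-terminus. The background is
then sanitized: any unplanned motif match or hydropathy window is broken by
deterministically rewriting one background residue, so a clean panel
carries exactly its intended signals — the oxidosqualene cyclase protein
has exactly five QW motifs, and the squalene synthase exactly one
23-residue TM run. Mutation (per-residue substitution at a configurable
rate) never touches planted windows, but it can *create* motifs in the
background; this is the intended degradation channel, and label-recovery
accuracy is therefore 1.0 at mutation 0, non-increasing in the rate, and
stays 1.0 under heavy mutation for groups whose rules are determined by
the (mutation-free) domain TSV alone. Everything is byte-deterministic in
the seed, with per-protein RNG streams so panels of different sizes share
prefixes.

*Cluster locus.* The default layout places three members upstream and
three downstream of a 2.0 kb anchor, members of 2.7 kb with 500 bp gaps,
totalling exactly 21.2 kb, with roles regulator (Zn2-C6 TF), oxygenase,
alpha-beta hydrolase, anchor, oxygenase, MFS transporter, carbonic
anhydrase along the contig. Member proteins are random sequences with
role-diagnostic domain annotations; cross-species fixtures are built by
copying and perturbing them.

*Ct tables.* The reference gene sits at a base Ct of 20 cycles and targets
at 24 (arbitrary but fixed; the Livak statistic is invariant to the bases);
a planted fold f lowers the target's condition Ct by log2 f, so the exact
pipeline on a zero-noise table returns f to floating-point accuracy.
Gaussian noise of configurable SD is added per technical measurement.
Non-detections are emitted as empty Ct fields. Three preset designs mirror
the study conditions the package emulates: liquid cultures (basal minimal
medium; sucrose, H₂O₂, nitrogen starvation, NaCl; reported folds such as
ts4 = 18.7 under sucrose and ts9 = 2.7 under H₂O₂ planted; tri5/ts5/ts7
never detected), root colonization (basal PDA mycelium; tri5 = 134,
ts4 = 0.03 among others), and the wheat-spike interaction (ts11 = 1.45).
Where a condition's published description gives a direction but no number
(ts1 and ts9 induction under sucrose, the NaCl repression range 0.02–0.33),
the presets plant fixed values consistent with the description.

What the fixtures do *not* emulate: nucleotide sequence, introns, realistic
phylogenetic sequence evolution (no indels, no rate heterogeneity, no
compositional bias), inter-gene correlation in expression noise, or
genome-scale inventories. Passing tests therefore demonstrate that the
*computations* are correct and invertible on inputs with known truth — not
that the rules would achieve any particular accuracy on real proteomes,
where domain annotations are noisy and motif variants escape printed
consensus strings.

## Problem sizes

The bundled analyses run at fixture scale by design: panels of 15–300
proteins of 400 residues, reference sets of a handful of ~120-residue
sequences with 30–100 bootstrap replicates, clusters of 7 genes with
~300-residue products, and Ct tables up to a few thousand rows. These
sizes exercise every code path while keeping the whole suite fast and
deterministic.

## Known limitations

- Exact consensus matching cannot find motif variants outside the printed
  alternatives; a pHMM backend would be the natural extension.
- The 15-group partition is one consistent reading of the family
  literature; the exact membership of the published groups is not
  enumerated anywhere, which is why the taxonomy is a swappable config.
- NJ + bootstrap is a proxy for model-based phylogenetics; supports are not
  posterior probabilities.
- The gap-chaining cluster extractor is not a BGC caller; on real genomes
  its boundaries depend on `max_gap`.
- Reproducing published genome-scale numbers (family sizes per species,
  cross-species TRI5 identities) requires the real proteomes and is outside
  the package's scope.
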