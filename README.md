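# tpsinv — terpene synthase inventory toolkit

`tpsinv` is a small, fully tested pipeline for characterizing the terpene
synthase (TS) gene family of filamentous fungi, modeled on the inventory of
the genus *Trichoderma*. TS enzymes — terpene cyclases and prenyl
transferases — build the terpenoid backbone chemistry that underpins fungal
secondary metabolism, and whole-genome annotation of the family combines
several heterogeneous kinds of evidence. The package implements each step as
a library module with a thin command-line front end:

- **Motif scanning** (`tpsinv.motifs`): compiles the catalytic aspartate-rich
  metal-binding motifs of the family — Class I `D[D/E]xx[D/E]`-type motifs
  (ionization-dependent catalysis), Class II `DxDD`/`DxDTT` motifs
  (protonation-dependent catalysis), the trichodiene synthase
  `DDSRE/DDSIE` + `NDLFSFYKE` active center, the oxidosqualene cyclase
  `DCTAE`-family motif and QW structural repeats — into a deterministic
  grammar matcher that reports every (overlapping) match, and derives the
  Class I / Class II / bifunctional fold call. A Kyte–Doolittle hydropathy
  scan detects the C-terminal transmembrane helix diagnostic of squalene
  synthases.
- **Rule-based classification** (`tpsinv.classify`): assigns each protein to
  exactly one of 15 functional groups from its InterProScan-style domain
  accessions, motif summary and TM evidence, evaluated in precedence order;
  prenylation and polyprenyl subtypes (GGTase 1/2, FTase, GGPP/FPP synthase,
  indole diterpene synthase) are carried as secondary annotations. A
  rule-based selector reduces an inventory to expression-study candidates
  (Class I TSs, excluding precursor and prenylation enzymes).
- **Phylogenetic assignment** (`tpsinv.phylo`): BLOSUM62 affine-gap global
  alignment, percent identity, neighbor joining with deterministic
  tie-breaking, column-bootstrap supports, and clade-membership labeling of
  query proteins against references of known function (label accepted at
  bootstrap support ≥ 50 by default).
- **Cluster context** (`tpsinv.cluster`): extracts the biosynthetic gene
  cluster around an anchor gene (e.g. the trichodiene synthase gene *tri5*)
  from GFF3 features by intergenic-gap chaining, assigns member roles
  (regulator, tailoring enzymes, transporter), and compares composition and
  gene order across genomes by reciprocal-best-hit orthology and Kendall
  rank correlation.
- **Expression analysis** (`tpsinv.expression`): the Livak 2^−ΔΔCt method
  over hierarchical qPCR Ct tables (technical → biological replicates),
  normalized against β-tubulin and a basal condition, with per-gene one-way
  ANOVA on the ΔΔCt scale, Tukey HSD post-hoc stars, non-detection
  propagation, and the angular-transform ANOVA used for disease-severity
  percentages.
- **Synthetic fixtures** (`tpsinv.synthetic`): seed-deterministic generators
  for protein panels with planted signatures, a 21.2 kb anchor-gene locus
  (anchor + six flanking genes), and Ct tables with planted fold changes —
  built so the pipeline provably inverts them.

## Worked example

```sh
tpsinv generate panel --seed 1 --out demo/panel
tpsinv classify --fasta demo/panel/panel.fasta --domains demo/panel/panel_domains.tsv \
    --out demo/classes.tsv
```

prints one count per functional group (15 groups, one synthetic protein
each):

```
group_id
had_bifunctional          1
tri5                      1
longiborneol              1
...
polyprenyl_superfamily    1
```

Cluster extraction around the trichodiene synthase anchor:

```sh
tpsinv generate locus --seed 1 --out demo/locus
tpsinv cluster --gff demo/locus/locus.gff3 --domains demo/locus/locus_domains.tsv --anchor tri5
```

```
tgA   1001   3700  +  Zn2-C6 transcription factor
tgB   4201   6900  -  oxygenase
tgC   7401  10100  +  alpha-beta hydrolase
tri5 10601  12600  +  trichodiene synthase
tgD  13101  15800  -  oxygenase
tgE  16301  19000  +  MFS transporter
tgF  19501  22200  -  carbonic anhydrase
# span_kb=21.2
```

i.e. the anchor plus six genes — one regulator, four tailoring enzymes and
one efflux transporter — spanning 21.2 kb.

Relative expression from a zero-noise Ct table planted with known fold
changes (basal = minimal medium, reference = β-tubulin):

```sh
tpsinv generate ct --seed 1 --out demo/ct.csv
tpsinv express --ct demo/ct.csv --ref-gene beta-tubulin --basal MM
```

reports, among others, `ts4 / sucrose  fold_mean 18.7  ***` — the planted
induction recovered exactly — and absent calls for the three genes whose
transcripts the table marks as never detected.

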