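"""File-format adapters: FASTA, InterProScan-style TSV, GFF3, Ct CSV."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import DomainAnnotation
from .cluster import GeneFeature

DOMAIN_TSV_COLUMNS = ["protein_id", "source_db", "accession", "start", "end", "description"]


def read_fasta(path) -> list:
    """Protein records as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable, path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_domain_tsv(path) -> list:
    """InterProScan-style TSV (no header): one DomainAnnotation per row."""
    frame = pd.read_csv(
        str(path), sep="\t", header=None, names=DOMAIN_TSV_COLUMNS, dtype={"protein_id": str}, comment="#"
    )
    frame["description"] = frame["description"].fillna("")
    return [
        DomainAnnotation(r.protein_id, r.source_db, r.accession, int(r.start), int(r.end), r.description)
        for r in frame.itertuples()
    ]


def write_domain_tsv(rows: Sequence[DomainAnnotation], path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{r.protein_id}\t{r.source_db}\t{r.accession}\t{r.start}\t{r.end}\t{r.description}\n")


def write_gff3(features: Sequence[GeneFeature], path) -> None:
    """Write gene features as minimal GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda x: (x.contig, x.start)):
            fh.write(
                f"{f.contig}\ttpsinv\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tID={f.gene_id}\n"
            )


def read_gff3(path) -> list:
    """Gene features from GFF3 via gffutils (``gene`` feature type only)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        out.append(GeneFeature(feat.seqid, feat.start, feat.end, feat.strand, gene_id))
    return out
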