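"""Annotated genomes: GenBank / GFF3+FASTA loading into a common record.

Source coordinates (1-based inclusive in both formats) are converted to
0-based half-open internally. CDS translations supplied in the file are
used verbatim; otherwise the CDS is translated with the bacterial code
(table 11), minus-strand features from the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

TAX_RANKS = ("phylum", "family", "genus", "species")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    contig_id: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    protein: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.gene_id}: [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.protein:
            raise ValueError(f"CDS {self.gene_id} has an empty protein")


@dataclass
class GenomeRecord:
    genome_id: str
    genes: list[GeneAnnotation]
    taxonomy: dict[str, str] = field(default_factory=dict)
    complete: bool = True

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene ids in genome {self.genome_id}")

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id!r} not in genome {self.genome_id}")


def _translate_cds(nt: str) -> str:
    prot = str(Seq(nt).translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot


def _cds_protein(contig_seq: str, start: int, end: int, strand: str) -> str:
    if end > len(contig_seq):
        raise ValueError(f"CDS [{start},{end}) outside contig of length {len(contig_seq)}")
    nt = contig_seq[start:end]
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
    return _translate_cds(nt)


def load_genbank(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    path = Path(path)
    genes: list[GeneAnnotation] = []
    n_cds = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        contig_seq = str(rec.seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            start, end = int(feat.location.start), int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            gene_id = (
                feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [f"cds{n_cds}"]))
            )[0]
            if "translation" in feat.qualifiers:
                protein = feat.qualifiers["translation"][0]
            else:
                protein = _cds_protein(contig_seq, start, end, strand)
            genes.append(GeneAnnotation(gene_id, rec.id, start, end, strand, protein))
    return GenomeRecord(genome_id=genome_id or path.stem, genes=genes)


def load_gff3(gff_path: str | Path, fasta_path: str | Path,
              genome_id: str | None = None) -> GenomeRecord:
    gff_path, fasta_path = Path(gff_path), Path(fasta_path)
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="error", id_spec="ID",
    )
    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in contigs:
            raise ValueError(f"GFF3 contig {feat.seqid!r} missing from {fasta_path}")
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        strand = "-" if feat.strand == "-" else "+"
        protein = _cds_protein(contigs[feat.seqid], start, end, strand)
        genes.append(GeneAnnotation(feat.id, feat.seqid, start, end, strand, protein))
    return GenomeRecord(genome_id=genome_id or gff_path.stem, genes=genes)


def load_annotations(path: str | Path, fasta: str | Path | None = None,
                     genome_id: str | None = None) -> GenomeRecord:
    """Load a genome from GenBank, or from GFF3 plus its FASTA."""
    if fasta is not None:
        return load_gff3(path, fasta, genome_id=genome_id)
    return load_genbank(path, genome_id=genome_id)


def attach_taxonomy(record: GenomeRecord, taxonomy: dict[str, str],
                    complete: bool | None = None) -> GenomeRecord:
    record.taxonomy = {r: taxonomy[r] for r in TAX_RANKS if r in taxonomy}
    if complete is not None:
        record.complete = complete
    return record
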