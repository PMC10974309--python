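"""Gene models and GFF3 input/output.

Coordinates are 1-based inclusive throughout, matching GFF3. A gene holds one
or more transcripts; introns are the gaps between consecutive exons of a
transcript and are derived, never stored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def sorted_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        exons = self.sorted_exons()
        out = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class Gene:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    transcripts: list[Transcript] = field(default_factory=list)

    def validate(self) -> None:
        for tx in self.transcripts:
            for s, e in tx.exons:
                if s < self.start or e > self.end or s > e:
                    raise ValueError(
                        f"malformed gene model: exon ({s},{e}) of "
                        f"{tx.transcript_id} outside gene {self.gene_id} "
                        f"span ({self.start},{self.end})"
                    )


def write_gff3(genes: list[Gene], path: str | os.PathLike) -> None:
    """Emit gene -> mRNA -> exon features, GFF3 version 3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id)):
            fh.write(
                f"{g.contig}\tevesurveyor\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for tx in g.transcripts:
                exons = tx.sorted_exons()
                fh.write(
                    f"{g.contig}\tevesurveyor\tmRNA\t{exons[0][0]}\t"
                    f"{exons[-1][1]}\t.\t{g.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(exons, 1):
                    fh.write(
                        f"{g.contig}\tevesurveyor\texon\t{s}\t{e}\t.\t"
                        f"{g.strand}\t.\tID={tx.transcript_id}.exon{i};"
                        f"Parent={tx.transcript_id}\n"
                    )


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    """Load gene -> mRNA -> exon structures from a GFF3 file.

    Raises ValueError (naming the gene) when an exon lies outside its
    gene span.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = Gene(
            gene_id=gf.id,
            contig=gf.seqid,
            start=gf.start,
            end=gf.end,
            strand=gf.strand,
        )
        for mf in db.children(gf, featuretype="mRNA", order_by="start"):
            tx = Transcript(transcript_id=mf.id)
            for ef in db.children(mf, featuretype="exon", order_by="start"):
                tx.exons.append((ef.start, ef.end))
            gene.transcripts.append(tx)
        gene.validate()
        genes.append(gene)
    return genes
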