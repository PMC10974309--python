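"""Translated homology discovery of endogenous viral elements (EVEs).

Rhabdoviruses are negative-sense RNA viruses whose genomes are never naturally
present as DNA, so a DNA match to a rhabdoviral protein implies germline
integration. This module finds such integrations by a six-frame translated
seed-and-extend search (ungapped, BLOSUM62, Karlin-Altschul E-values), merges
high-scoring segment pairs (HSPs) into candidate loci, and annotates each
locus with its genomic context (intronic / exonic / intergenic) and its
orientation relative to the host gene.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genes import Gene

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_EVALUE_MAX = 1e-5


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Context(str, Enum):
    INTRONIC = "INTRONIC"
    EXONIC = "EXONIC"
    INTERGENIC = "INTERGENIC"


class Orientation(str, Enum):
    PLUS = "PLUS"
    MINUS = "MINUS"


class RelativeOrientation(str, Enum):
    SAME = "SAME"
    OPPOSITE = "OPPOSITE"
    NA = "NA"


def _blosum62_array() -> tuple[np.ndarray, dict[str, int]]:
    m = substitution_matrices.load("BLOSUM62")
    alphabet = str(m.alphabet)
    idx = {aa: i for i, aa in enumerate(alphabet)}
    arr = np.array(m, dtype=np.int64)
    return arr, idx


@dataclass(frozen=True)
class ScoringScheme:
    """Ungapped translated-search parameters.

    The Karlin-Altschul constants are the published values for ungapped
    BLOSUM62 statistics; bit score = (lambda*S - ln K)/ln 2 and
    E = m*n*2**(-bit), with m the total query length (aa) and n the total
    six-frame translated genome length (aa).
    """

    seed_word_size: int = 3
    seed_score_min: int = 11
    x_drop: int = 20
    karlin_lambda: float = 0.318
    karlin_k: float = 0.13
    evalue_max: float = DEFAULT_EVALUE_MAX

    def __post_init__(self):
        if self.seed_word_size < 1:
            raise ValueError("seed_word_size must be >= 1")

    def score(self, a: str, b: str) -> int:
        arr, idx = _SCORES
        return int(arr[idx.get(a, idx["X"]), idx.get(b, idx["X"])])


_SCORES = _blosum62_array()


@dataclass
class Hsp:
    """An ungapped high-scoring segment pair (query protein vs translated
    genome). Coordinates are 1-based inclusive; subject coordinates are on
    the forward strand of the contig with start <= end."""

    query_id: str
    query_start: int
    query_end: int
    contig: str
    subject_start: int
    subject_end: int
    frame: int  # one of +-1,+-2,+-3
    raw_score: int
    bit_score: float
    evalue: float
    pct_identity: float


@dataclass
class EveLocus:
    locus_id: str
    contig: str
    start: int
    end: int
    orientation: Orientation
    hsps: list[Hsp] = field(default_factory=list)
    best_query_id: str | None = None
    context: Context | None = None
    host_gene_id: str | None = None
    relative_orientation: RelativeOrientation = RelativeOrientation.NA

    @property
    def bit_score(self) -> float:
        return max((h.bit_score for h in self.hsps), default=0.0)

    @property
    def evalue(self) -> float:
        return min((h.evalue for h in self.hsps), default=math.inf)

    @property
    def pct_identity(self) -> float:
        best = max(self.hsps, key=lambda h: h.bit_score, default=None)
        return best.pct_identity if best else 0.0


@dataclass
class FrameTranslation:
    frame: int
    protein: str
    # per-aa forward-strand nt interval, 1-based inclusive
    aa_nt: list[tuple[int, int]]


def _translate_codons(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def six_frame_translate(contig_seq: str) -> list[FrameTranslation]:
    """Translate all six reading frames with per-residue coordinate maps.

    Frames +1..+3 read the forward strand starting at offsets 0..2; frames
    -1..-3 read the reverse complement the same way. Codons containing N
    translate to X. The coordinate map gives, for each amino acid, the
    1-based inclusive nt interval on the *forward* strand.
    """
    seq = contig_seq.upper()
    L = len(seq)
    out: list[FrameTranslation] = []
    rc = revcomp(seq)
    for off in range(3):
        prot = _translate_codons(seq[off:])
        aa_nt = [(off + 3 * i + 1, off + 3 * i + 3) for i in range(len(prot))]
        out.append(FrameTranslation(frame=off + 1, protein=prot, aa_nt=aa_nt))
    for off in range(3):
        prot = _translate_codons(rc[off:])
        # aa i occupies rc positions [off+3i+1, off+3i+3] (1-based);
        # forward coordinate of rc position p is L - p + 1
        aa_nt = [(L - (off + 3 * i + 3) + 1, L - (off + 3 * i + 1) + 1)
                 for i in range(len(prot))]
        out.append(FrameTranslation(frame=-(off + 1), protein=prot, aa_nt=aa_nt))
    return out


def _extend(query: str, subject: str, qpos: int, spos: int, w: int,
            scheme: ScoringScheme) -> tuple[int, int, int]:
    """Ungapped x-drop extension of an exact seed of width w at
    (qpos, spos) (0-based). Returns (q_start, q_end_exclusive, score)."""
    arr, idx = _SCORES
    xa = idx["X"]
    score = sum(
        arr[idx.get(query[qpos + k], xa), idx.get(subject[spos + k], xa)]
        for k in range(w)
    )
    # right extension
    best = score
    best_right = qpos + w
    cur = score
    i, j = qpos + w, spos + w
    while i < len(query) and j < len(subject):
        cur += arr[idx.get(query[i], xa), idx.get(subject[j], xa)]
        i += 1
        j += 1
        if cur > best:
            best, best_right = cur, i
        elif best - cur > scheme.x_drop:
            break
    # left extension
    cur = best
    best_left = qpos
    i, j = qpos - 1, spos - 1
    running = best
    while i >= 0 and j >= 0:
        running += arr[idx.get(query[i], xa), idx.get(subject[j], xa)]
        if running > cur:
            cur, best_left = running, i
        elif cur - running > scheme.x_drop:
            break
        i -= 1
        j -= 1
    return best_left, best_right, int(cur)


def search(query_proteins: dict[str, str], genome: dict[str, str],
           scheme: ScoringScheme | None = None) -> list[Hsp]:
    """Six-frame translated seed-and-extend homology search.

    Seeds are exact word matches of ``seed_word_size`` residues whose match
    score reaches ``seed_score_min``; each seed is extended without gaps in
    both directions with x-drop termination. HSPs failing the E-value
    threshold are discarded.
    """
    if scheme is None:
        scheme = ScoringScheme()
    arr, idx = _SCORES
    w = scheme.seed_word_size

    translations: list[tuple[str, FrameTranslation]] = []
    for contig, seq in genome.items():
        for ft in six_frame_translate(seq):
            translations.append((contig, ft))

    n_total = sum(len(ft.protein) for _, ft in translations)
    m_total = sum(len(q) for q in query_proteins.values())

    # seed index: word -> list of (translation index, aa offset)
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, (_, ft) in enumerate(translations):
        p = ft.protein
        for i in range(len(p) - w + 1):
            index.setdefault(p[i : i + w], []).append((ti, i))

    hsps: list[Hsp] = []
    for qid, qseq in query_proteins.items():
        seen: dict[tuple, Hsp] = {}
        for qpos in range(len(qseq) - w + 1):
            word = qseq[qpos : qpos + w]
            self_score = sum(
                arr[idx.get(c, idx["X"]), idx.get(c, idx["X"])] for c in word
            )
            if self_score < scheme.seed_score_min:
                continue
            for ti, spos in index.get(word, []):
                contig, ft = translations[ti]
                qs, qe, score = _extend(qseq, ft.protein, qpos, spos, w, scheme)
                ss = spos - (qpos - qs)
                se = ss + (qe - qs)
                key = (ti, qs, ss)
                if key in seen:
                    continue
                bit = (scheme.karlin_lambda * score - math.log(scheme.karlin_k)) / math.log(2)
                ev = m_total * n_total * 2.0 ** (-bit)
                if ev >= scheme.evalue_max:
                    seen[key] = None  # type: ignore[assignment]
                    continue
                nident = sum(
                    1 for k in range(qe - qs) if qseq[qs + k] == ft.protein[ss + k]
                )
                nt_intervals = ft.aa_nt[ss:se]
                nt_start = min(a for a, _ in nt_intervals)
                nt_end = max(b for _, b in nt_intervals)
                seen[key] = Hsp(
                    query_id=qid,
                    query_start=qs + 1,
                    query_end=qe,
                    contig=contig,
                    subject_start=nt_start,
                    subject_end=nt_end,
                    frame=ft.frame,
                    raw_score=score,
                    bit_score=bit,
                    evalue=ev,
                    pct_identity=nident / (qe - qs),
                )
        hsps.extend(h for h in seen.values() if h is not None)
    hsps.sort(key=lambda h: (h.contig, h.subject_start, h.subject_end, h.frame,
                             h.query_id))
    return hsps


def merge_hsps_to_loci(hsps: list[Hsp], max_gap_nt: int = 100) -> list[EveLocus]:
    """Chain same-contig, same-strand HSPs within ``max_gap_nt`` into loci.

    Opposite-strand HSPs are never merged: two overlapping insertions in
    opposite transcriptional orientations must remain distinct loci.
    Merging is idempotent and independent of input order.
    """
    groups: dict[tuple[str, int], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.contig, 1 if h.frame > 0 else -1), []).append(h)

    loci: list[EveLocus] = []
    for (contig, sign), hs in sorted(groups.items()):
        hs = sorted(hs, key=lambda h: (h.subject_start, h.subject_end))
        cluster: list[Hsp] = []
        clusters: list[list[Hsp]] = []
        cur_end = None
        for h in hs:
            if cur_end is not None and h.subject_start - cur_end - 1 <= max_gap_nt:
                cluster.append(h)
                cur_end = max(cur_end, h.subject_end)
            else:
                if cluster:
                    clusters.append(cluster)
                cluster = [h]
                cur_end = h.subject_end
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            best = max(cl, key=lambda h: h.bit_score)
            loci.append(
                EveLocus(
                    locus_id="",
                    contig=contig,
                    start=min(h.subject_start for h in cl),
                    end=max(h.subject_end for h in cl),
                    orientation=Orientation.PLUS if sign > 0 else Orientation.MINUS,
                    hsps=cl,
                    best_query_id=best.query_id,
                )
            )
    loci.sort(key=lambda l: (l.contig, l.start, l.end, l.orientation.value))
    for i, locus in enumerate(loci, 1):
        locus.locus_id = f"EVE{i:03d}"
    return loci


def annotate_context(locus: EveLocus, gene_models: list[Gene]) -> EveLocus:
    """Set genomic context and orientation relative to the host gene.

    INTRONIC requires full containment inside one intron of one transcript;
    any exon intersection wins EXONIC (so a locus straddling an exon-intron
    junction is EXONIC); everything else is INTERGENIC.
    """
    context = Context.INTERGENIC
    host: Gene | None = None
    for gene in gene_models:
        if gene.contig != locus.contig:
            continue
        gene.validate()
        for tx in gene.transcripts:
            for s, e in tx.sorted_exons():
                if locus.start <= e and locus.end >= s:
                    context, host = Context.EXONIC, gene
        if context is Context.EXONIC:
            break
        for tx in gene.transcripts:
            for s, e in tx.introns():
                if s <= locus.start and locus.end <= e:
                    context, host = Context.INTRONIC, gene
    locus.context = context
    if host is None:
        locus.host_gene_id = None
        locus.relative_orientation = RelativeOrientation.NA
    else:
        locus.host_gene_id = host.gene_id
        locus_strand = "+" if locus.orientation is Orientation.PLUS else "-"
        locus.relative_orientation = (
            RelativeOrientation.SAME
            if locus_strand == host.strand
            else RelativeOrientation.OPPOSITE
        )
    return locus


def locus_span_length(coord_a: int, coord_b: int) -> tuple[int, Orientation]:
    """Span length and implied orientation of a 1-based inclusive coordinate
    pair, following the convention that descending coordinates denote a
    minus-strand feature.
    """
    if coord_a < 1 or coord_b < 1:
        raise ValueError("coordinates must be >= 1")
    length = abs(coord_a - coord_b) + 1
    orientation = Orientation.MINUS if coord_a > coord_b else Orientation.PLUS
    return length, orientation


def discover(genome: dict[str, str], query_proteins: dict[str, str],
             gene_models: list[Gene] | None = None,
             scheme: ScoringScheme | None = None,
             max_gap_nt: int = 100) -> list[EveLocus]:
    """Full discovery pass: search, merge, annotate."""
    hsps = search(query_proteins, genome, scheme)
    loci = merge_hsps_to_loci(hsps, max_gap_nt=max_gap_nt)
    if gene_models is not None:
        for locus in loci:
            annotate_context(locus, gene_models)
    return loci


def write_loci_tsv(loci: list[EveLocus], path: str | os.PathLike) -> None:
    cols = ("locus_id contig start end orientation context host_gene "
            "best_query bit_score evalue pct_identity").split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for l in loci:
            fh.write(
                "\t".join(
                    [
                        l.locus_id,
                        l.contig,
                        str(l.start),
                        str(l.end),
                        l.orientation.value,
                        l.context.value if l.context else "NA",
                        l.host_gene_id or "NA",
                        l.best_query_id or "NA",
                        f"{l.bit_score:.2f}",
                        f"{l.evalue:.3g}",
                        f"{l.pct_identity:.4f}",
                    ]
                )
                + "\n"
            )


def write_loci_bed(loci: list[EveLocus], path: str | os.PathLike) -> None:
    """BED6 export (0-based half-open at the file boundary)."""
    with open(path, "w") as fh:
        for l in loci:
            strand = "+" if l.orientation is Orientation.PLUS else "-"
            fh.write(
                f"{l.contig}\t{l.start - 1}\t{l.end}\t{l.locus_id}\t"
                f"{int(round(l.bit_score))}\t{strand}\n"
            )


def extract_locus_seqs(loci: list[EveLocus], genome: dict[str, str]) -> dict[str, str]:
    """Locus sequences oriented 5'->3' on the locus strand."""
    out = {}
    for l in loci:
        seq = genome[l.contig][l.start - 1 : l.end]
        if l.orientation is Orientation.MINUS:
            seq = revcomp(seq)
        out[l.locus_id] = seq
    return out
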