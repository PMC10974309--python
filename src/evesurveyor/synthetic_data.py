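"""Synthetic genomes, small-RNA libraries and population panels with ground
truth.

Every downstream stage of the pipeline (discovery, small-RNA profiling,
population survey) is exercised on data generated here, so each generator
records machine-readable truth: where each viral fragment was planted and in
what orientation/context, which locus and strand each read came from, and
which samples carry/transcribe which element.

Planting uses replacement semantics: the reverse-translated viral fragment
overwrites an equal-length window inside the target intron (or exon, or
intergenic segment), so gene-model coordinates never shift and a fragment
longer than its target region is an explicit error.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .eve_discovery import revcomp
from .genes import Gene, Transcript

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# fixed most-frequent-codon reverse-translation table (determinism over
# realism; based on common metazoan codon preferences)
MOST_FREQUENT_CODON = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
STOP_CODONS = ["TAA", "TAG", "TGA"]


@dataclass
class InsertionSpec:
    source_protein_id: str
    fragment_aa_len: int
    aa_divergence: float = 0.0
    n_frameshifts: int = 0
    n_stop_mutations: int = 0
    target_context: str = "INTRONIC"  # INTRONIC | EXONIC | INTERGENIC
    orientation: str = "SAME"         # SAME | OPPOSITE (vs host gene strand)

    def __post_init__(self):
        if not 0.0 <= self.aa_divergence <= 1.0:
            raise ValueError("aa_divergence must be in [0,1]")
        if self.n_frameshifts < 0 or self.n_stop_mutations < 0:
            raise ValueError("mutation counts must be >= 0")


@dataclass
class SrnaProfileSpec:
    """Parameters of one simulated small-RNA read population.

    ``size_distribution`` maps read length (nt) to probability;
    ``hotspot_windows`` are 1-based inclusive intervals in locus coordinates
    whose per-base sampling weight is multiplied by ``hotspot_multiplier``.
    """

    target_locus_id: str | None
    profile: str  # PIRNA_LIKE | DEGRADATION | SIRNA_LIKE
    n_reads: int
    size_distribution: dict[int, float]
    plus_strand_fraction: float = 1.0
    u_bias: float | None = None
    hotspot_windows: list[tuple[int, int]] = field(default_factory=list)
    hotspot_multiplier: float = 10.0
    background_reads: int = 0

    def __post_init__(self):
        total = sum(self.size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("size_distribution must sum to 1")
        if min(self.size_distribution) < 15:
            raise ValueError(
                "size_distribution support below 15 nt conflicts with the "
                "read length filter"
            )

    @classmethod
    def pirna_like(cls, target_locus_id, n_reads=1000, plus_strand_fraction=1.0,
                   u_bias=0.25, hotspot_windows=(), background_reads=0):
        """piRNA-target profile: 24-29 nt, one strand, coverage hotspots.
        The 5' base is unbiased by default (u_bias = background 0.25)."""
        sizes = {24: 0.10, 25: 0.15, 26: 0.25, 27: 0.25, 28: 0.15, 29: 0.10}
        return cls(target_locus_id, "PIRNA_LIKE", n_reads, sizes,
                   plus_strand_fraction, u_bias, list(hotspot_windows),
                   background_reads=background_reads)

    @classmethod
    def degradation(cls, target_locus_id, n_reads=40, background_reads=0):
        """Degradation profile: low abundance, 15-35 nt uniform, both strands."""
        sizes = {l: 1.0 / 21 for l in range(15, 36)}
        return cls(target_locus_id, "DEGRADATION", n_reads, sizes,
                   plus_strand_fraction=0.5, u_bias=None,
                   background_reads=background_reads)

    @classmethod
    def sirna_like(cls, target_locus_id, n_reads=1000, background_reads=0):
        """siRNA-like: 20-22 nt from both strands."""
        sizes = {20: 0.25, 21: 0.5, 22: 0.25}
        return cls(target_locus_id, "SIRNA_LIKE", n_reads, sizes,
                   plus_strand_fraction=0.5, u_bias=None,
                   background_reads=background_reads)


@dataclass
class SimulationConfig:
    seed: int
    contig_lengths: list[int]
    gc_content: float = 0.4
    # (n_exons, exon_len_bp, intron_len_bp, strand)
    gene_specs: list[tuple[int, int, int, str]] = field(default_factory=list)
    insertion_specs: list[InsertionSpec] = field(default_factory=list)
    srna_specs: list[SrnaProfileSpec] = field(default_factory=list)
    source_proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0,1]")
        if any(l <= 0 for l in self.contig_lengths):
            raise ValueError("contig lengths must be > 0")


@dataclass
class EveTruthRecord:
    locus_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    source_protein_id: str
    context: str
    host_gene_id: str | None
    relative_orientation: str  # SAME | OPPOSITE | NA
    fragment_aa_start: int  # 1-based on the source protein
    fragment_aa_end: int


@dataclass
class ReadLabel:
    read_id: str
    locus_id: str | None  # None = background
    strand: str
    length: int
    start: int  # 1-based 5'-most locus/genome coordinate of the window


@dataclass
class GroundTruth:
    records: list[EveTruthRecord] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)
    read_labels: list[ReadLabel] = field(default_factory=list)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, size=length)])


def _build_fragment(spec: InsertionSpec, protein: str,
                    rng: np.random.Generator) -> tuple[str, int, int]:
    """Reverse-translate a protein fragment and degrade it per the
    InsertionSpec. Returns (nt fragment on coding strand, aa_start, aa_end),
    1-based."""
    if len(protein) < spec.fragment_aa_len:
        raise ValueError(
            f"protein {spec.source_protein_id} shorter than fragment_aa_len"
        )
    start = int(rng.integers(0, len(protein) - spec.fragment_aa_len + 1))
    frag = protein[start : start + spec.fragment_aa_len]
    codons = [MOST_FREQUENT_CODON[a] for a in frag]
    n = len(codons)

    n_mut = int(round(spec.aa_divergence * n))
    positions = list(rng.choice(n, size=min(n_mut + spec.n_stop_mutations, n),
                                replace=False))
    for p in positions[:n_mut]:
        choices = [c for c in SENSE_CODONS if c != codons[p]]
        codons[p] = choices[int(rng.integers(0, len(choices)))]
    for p in positions[n_mut:]:
        codons[p] = STOP_CODONS[int(rng.integers(0, 3))]

    nt = "".join(codons)
    for _ in range(spec.n_frameshifts):
        pos = int(rng.integers(0, len(nt)))
        base = "ACGT"[int(rng.integers(0, 4))]
        nt = (nt[:pos] + base + nt[pos:])[: len(nt)]
    return nt, start + 1, start + spec.fragment_aa_len


def _candidate_windows(genes: list[Gene], contig_lengths: dict[str, int],
                       context: str, need_len: int,
                       used: list[tuple[str, int, int]]):
    """Yield (contig, window_start, window_end, gene-or-None) candidates able
    to hold a fragment of need_len with >=1 bp of flanking context."""

    def free(contig, s, e):
        return all(not (contig == c and s <= ue and e >= us)
                   for c, us, ue in used)

    out = []
    if context in ("INTRONIC", "EXONIC"):
        for g in genes:
            intervals = []
            for tx in g.transcripts:
                intervals += tx.introns() if context == "INTRONIC" else tx.sorted_exons()
            for s, e in intervals:
                if e - s + 1 >= need_len + 2:
                    ws = s + ((e - s + 1) - need_len) // 2
                    if free(g.contig, ws, ws + need_len - 1):
                        out.append((g.contig, ws, ws + need_len - 1, g))
    else:  # INTERGENIC
        for contig, clen in contig_lengths.items():
            spans = sorted((g.start, g.end) for g in genes if g.contig == contig)
            gaps, prev = [], 0
            for s, e in spans:
                gaps.append((prev + 1, s - 1))
                prev = max(prev, e)
            gaps.append((prev + 1, clen))
            for s, e in gaps:
                if e - s + 1 >= need_len + 2:
                    ws = s + ((e - s + 1) - need_len) // 2
                    if free(contig, ws, ws + need_len - 1):
                        out.append((contig, ws, ws + need_len - 1, None))
    return out


def plant_insertion(genome: dict[str, str], gene_models: list[Gene],
                    spec: InsertionSpec, viral_protein: str,
                    rng: np.random.Generator,
                    _used: list[tuple[str, int, int]] | None = None,
                    locus_id: str = "locus1",
                    ) -> tuple[dict[str, str], EveTruthRecord]:
    """Overwrite a window of the genome with a degraded reverse-translated
    viral-protein fragment, in the requested context and orientation."""
    nt, aa_s, aa_e = _build_fragment(spec, viral_protein, rng)
    contig_lengths = {c: len(s) for c, s in genome.items()}
    cands = _candidate_windows(gene_models, contig_lengths,
                               spec.target_context, len(nt), _used or [])
    if not cands:
        raise ValueError(
            f"no {spec.target_context} region can hold a {len(nt)} nt "
            f"fragment of {spec.source_protein_id} (insertion longer than "
            f"available target region, or no compatible gene)"
        )
    contig, ws, we, host = cands[int(rng.integers(0, len(cands)))]

    if host is not None:
        strand = host.strand if spec.orientation == "SAME" else (
            "-" if host.strand == "+" else "+")
        rel = spec.orientation
    else:
        strand = "+" if spec.orientation == "SAME" else "-"
        rel = "NA"
    if strand == "-":
        nt = revcomp(nt)

    seq = genome[contig]
    genome = dict(genome)
    genome[contig] = seq[: ws - 1] + nt + seq[we:]
    if _used is not None:
        _used.append((contig, ws, we))
    rec = EveTruthRecord(
        locus_id=locus_id, contig=contig, start=ws, end=we, strand=strand,
        source_protein_id=spec.source_protein_id,
        context=spec.target_context,
        host_gene_id=host.gene_id if host else None,
        relative_orientation=rel,
        fragment_aa_start=aa_s, fragment_aa_end=aa_e,
    )
    return genome, rec


def simulate_genome(config: SimulationConfig
                    ) -> tuple[dict[str, str], list[Gene], GroundTruth]:
    """Build contigs, lay out gene models, and plant the configured viral
    insertions. Fully deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    genome = {
        f"contig{i+1}": random_dna(rng, L, config.gc_content)
        for i, L in enumerate(config.contig_lengths)
    }
    contigs = list(genome)

    # lay out genes round-robin over contigs, left to right, 200 bp margins
    genes: list[Gene] = []
    cursor = {c: 200 for c in contigs}
    for gi, (n_exons, exon_len, intron_len, strand) in enumerate(config.gene_specs):
        contig = contigs[gi % len(contigs)]
        span = n_exons * exon_len + max(0, n_exons - 1) * intron_len
        start = cursor[contig] + 1
        end = start + span - 1
        if end > len(genome[contig]) - 200:
            raise ValueError(
                f"gene_specs[{gi}] does not fit on {contig} "
                f"(needs {span} bp at offset {start})"
            )
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append((pos, pos + exon_len - 1))
            pos += exon_len + intron_len
        gid = f"gene{gi+1}"
        genes.append(Gene(gid, contig, start, end, strand,
                          [Transcript(f"{gid}.t1", exons)]))
        cursor[contig] = end + 200

    # source proteins: supplied, or generated deterministically
    proteins = dict(config.source_proteins)
    for spec in config.insertion_specs:
        if spec.source_protein_id not in proteins:
            proteins[spec.source_protein_id] = random_protein(
                rng, spec.fragment_aa_len + 50)

    truth = GroundTruth(proteins=proteins)
    used: list[tuple[str, int, int]] = []
    for i, spec in enumerate(config.insertion_specs):
        try:
            genome, rec = plant_insertion(
                genome, genes, spec, proteins[spec.source_protein_id], rng,
                _used=used, locus_id=f"planted{i+1}")
        except ValueError as exc:
            raise ValueError(f"insertion_specs[{i}]: {exc}") from exc
        truth.records.append(rec)
    return genome, genes, truth


# ---------------------------------------------------------------------------
# small RNA simulation

def simulate_small_rna(genome: dict[str, str], truth: GroundTruth,
                       spec: SrnaProfileSpec, rng: np.random.Generator,
                       quality: int = 40,
                       ) -> tuple[list[SeqRecord], list[ReadLabel]]:
    """Sample small-RNA reads from a planted locus (strand, size and hotspot
    structure per spec) plus uniform background reads from the rest of the
    genome. Qualities are constant Phred ``quality`` (Phred+33 on output)."""
    lengths = sorted(spec.size_distribution)
    probs = np.array([spec.size_distribution[l] for l in lengths])
    probs = probs / probs.sum()

    records: list[SeqRecord] = []
    labels: list[ReadLabel] = []

    def emit(read_id, seq, locus_id, strand, start):
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
        labels.append(ReadLabel(read_id, locus_id, strand, len(seq), start))

    if spec.target_locus_id is not None:
        rec = next(r for r in truth.records if r.locus_id == spec.target_locus_id)
        region = genome[rec.contig][rec.start - 1 : rec.end]
        L = len(region)
        weights = np.ones(L)
        for s, e in spec.hotspot_windows:
            weights[max(0, s - 1) : min(L, e)] *= spec.hotspot_multiplier
        for i in range(spec.n_reads):
            l = int(lengths[rng.choice(len(lengths), p=probs)])
            l = min(l, L)
            w = weights[: L - l + 1].copy()
            s0 = int(rng.choice(len(w), p=w / w.sum()))  # 0-based window start
            window = region[s0 : s0 + l]
            strand = "+" if rng.random() < spec.plus_strand_fraction else "-"
            seq = window if strand == "+" else revcomp(window)
            if spec.u_bias is not None:
                # u_bias is the exact probability that the 5' base is U/T
                if rng.random() < spec.u_bias:
                    seq = "T" + seq[1:]
                elif seq[0] == "T":
                    seq = "ACG"[int(rng.integers(0, 3))] + seq[1:]
            emit(f"{spec.target_locus_id}_r{i+1}", seq, spec.target_locus_id,
                 strand, rec.start + s0)

    contigs = list(genome)
    clens = np.array([len(genome[c]) for c in contigs], dtype=float)
    eve_windows = [(r.contig, r.start, r.end) for r in truth.records]
    for i in range(spec.background_reads):
        for _ in range(100):
            ci = int(rng.choice(len(contigs), p=clens / clens.sum()))
            contig = contigs[ci]
            l = int(lengths[rng.choice(len(lengths), p=probs)])
            s0 = int(rng.integers(0, len(genome[contig]) - l + 1))
            if all(not (contig == c and s0 + 1 <= e and s0 + l >= s)
                   for c, s, e in eve_windows):
                break
        window = genome[contig][s0 : s0 + l]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = window if strand == "+" else revcomp(window)
        emit(f"bg_r{i+1}", seq, None, strand, s0 + 1)
    return records, labels


# ---------------------------------------------------------------------------
# population panel

@dataclass
class PanelSample:
    sample_id: str
    species: str
    locality: str
    has_eve: dict[str, bool] = field(default_factory=dict)
    transcribes: dict[str, bool] = field(default_factory=dict)
    dna_available: bool = True
    cdna_available: bool = True


def simulate_population_panel(genome: dict[str, str], truth: GroundTruth,
                              panel: list[PanelSample],
                              rng: np.random.Generator, flank: int = 60,
                              ) -> dict[str, tuple[list[SeqRecord] | None,
                                                   list[SeqRecord] | None]]:
    """Per-sample DNA and cDNA sequence sets.

    A sample's DNA contains the EVE-bearing genomic region iff it carries the
    element; its cDNA contains the EVE-spanning transcript iff it transcribes
    it (transcription without carriage is rejected as biologically
    impossible). Every available compartment also carries a neutral decoy
    fragment so PCR-negative samples are still non-empty.
    """
    out = {}
    by_id = {r.locus_id: r for r in truth.records}
    for sample in panel:
        for eve, t in sample.transcribes.items():
            if t and not sample.has_eve.get(eve, False):
                raise ValueError(
                    f"sample {sample.sample_id}: transcribes {eve} without "
                    f"carrying it"
                )
        dna: list[SeqRecord] | None = None
        cdna: list[SeqRecord] | None = None
        if sample.dna_available:
            dna = [SeqRecord(Seq(random_dna(rng, 400)),
                             id=f"{sample.sample_id}_decoy_dna", description="")]
            for eve, present in sorted(sample.has_eve.items()):
                if present:
                    r = by_id[eve]
                    s = max(0, r.start - 1 - flank)
                    e = min(len(genome[r.contig]), r.end + flank)
                    dna.append(SeqRecord(Seq(genome[r.contig][s:e]),
                                         id=f"{sample.sample_id}_{eve}_gdna",
                                         description=""))
        if sample.cdna_available:
            cdna = [SeqRecord(Seq(random_dna(rng, 400)),
                              id=f"{sample.sample_id}_decoy_cdna", description="")]
            for eve, transcribed in sorted(sample.transcribes.items()):
                if transcribed:
                    r = by_id[eve]
                    s = max(0, r.start - 1 - flank // 2)
                    e = min(len(genome[r.contig]), r.end + flank // 2)
                    cdna.append(SeqRecord(Seq(genome[r.contig][s:e]),
                                          id=f"{sample.sample_id}_{eve}_cdna",
                                          description=""))
        out[sample.sample_id] = (dna, cdna)
    return out


def design_primer_pair(genome: dict[str, str], record: EveTruthRecord,
                       primer_len: int = 20, name: str | None = None):
    """Primer pair targeting a planted locus: forward = the first
    ``primer_len`` nt of the region, reverse = reverse complement of the
    last ``primer_len`` nt; expected amplicon = the full region."""
    from .population_survey import PrimerPair

    region = genome[record.contig][record.start - 1 : record.end]
    return PrimerPair(
        name=name or record.locus_id,
        forward=region[:primer_len],
        reverse=revcomp(region[-primer_len:]),
        expected_amplicon_len=len(region),
    )


# ---------------------------------------------------------------------------
# writers

def write_genome_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_proteins_fasta(proteins: dict[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in proteins.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: list[SeqRecord], path: str | os.PathLike) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_truth(truth: GroundTruth, tsv_path, json_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("locus_id\tcontig\tstart\tend\tstrand\tsource_protein\t"
                 "context\thost_gene\trelative_orientation\n")
        for r in truth.records:
            fh.write(f"{r.locus_id}\t{r.contig}\t{r.start}\t{r.end}\t"
                     f"{r.strand}\t{r.source_protein_id}\t{r.context}\t"
                     f"{r.host_gene_id or 'NA'}\t{r.relative_orientation}\n")
    payload = {
        "records": [vars(r) for r in truth.records],
        "proteins": truth.proteins,
        "read_labels": [vars(l) for l in truth.read_labels],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
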