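"""End-to-end pipeline driver: simulate -> discover -> profile.

Everything is deterministic for a fixed config (including its seed): running
the pipeline twice into two directories produces byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from . import eve_discovery, smallrna_profile, synthetic_data
from .genes import write_gff3


def run_pipeline(config: synthetic_data.SimulationConfig,
                 outdir: str | os.PathLike) -> dict:
    """Simulate a genome per config, rediscover the planted elements, and
    profile/classify any configured small-RNA libraries. Writes FASTA/GFF3/
    truth, the loci table/BED/FASTA and per-locus profile outputs under
    ``outdir`` and returns the in-memory results."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    genome, gene_models, truth = synthetic_data.simulate_genome(config)
    synthetic_data.write_genome_fasta(genome, out / "genome.fa")
    write_gff3(gene_models, out / "genes.gff3")
    synthetic_data.write_proteins_fasta(truth.proteins, out / "proteins.faa")

    loci = eve_discovery.discover(genome, truth.proteins, gene_models)
    eve_discovery.write_loci_tsv(loci, out / "loci.tsv")
    eve_discovery.write_loci_bed(loci, out / "loci.bed")
    locus_seqs = eve_discovery.extract_locus_seqs(loci, genome)
    with open(out / "loci.fa", "w") as fh:
        for lid, seq in locus_seqs.items():
            fh.write(f">{lid}\n{seq}\n")

    profiles = []
    if config.srna_specs:
        rng = np.random.default_rng(config.seed + 1)
        records, labels = [], []
        for spec in config.srna_specs:
            recs, labs = synthetic_data.simulate_small_rna(genome, truth, spec, rng)
            records += recs
            labels += labs
        truth.read_labels = labels
        synthetic_data.write_fastq(records, out / "smallrna.fastq")

        # profile against the *planted* loci regions (truth-defined)
        planted_seqs = {
            r.locus_id: genome[r.contig][r.start - 1 : r.end]
            for r in truth.records
        }
        kept, stats = smallrna_profile.preprocess_reads(
            str(out / "smallrna.fastq"))
        alns = smallrna_profile.align_reads(kept, planted_seqs)
        results = []
        for lid, seq in planted_seqs.items():
            prof = smallrna_profile.compute_profile(alns, lid, len(seq))
            cls, _ = smallrna_profile.classify_profile(prof)
            results.append((prof, cls))
            smallrna_profile.write_profile_json(
                prof, cls, out / f"profile_{lid}.json")
        smallrna_profile.write_profile_summary(results, out / "profiles.tsv")
        profiles = results

    synthetic_data.write_truth(truth, out / "truth.tsv", out / "truth.json")
    return {"genome": genome, "genes": gene_models, "truth": truth,
            "loci": loci, "profiles": profiles}
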