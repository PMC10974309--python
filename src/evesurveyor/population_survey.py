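"""In-silico PCR presence/transcription survey across sample panels.

Each sample contributes a genomic DNA sequence set and/or a cDNA set; a
primer pair scores POSITIVE in a compartment when it predicts at least one
amplicon there, NEGATIVE otherwise, and ND (not determined) when the
compartment was not assayed. The packaged default primers are the assay's
published pairs (a histone positive control and one pair per nucleocapsid
EVE, expected products 500/319/415 bp).

Annealing stringency (at most one mismatch overall, an exact 3'-terminal
block) is a deliberately simple surrogate for real PCR specificity: a
mismatch at the 3' end blocks polymerase extension, so it is always
disqualifying.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd

from .eve_discovery import revcomp


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str  # 5'->3'
    reverse: str  # 5'->3'
    expected_amplicon_len: int | None = None

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if len(p) < 10:
                raise ValueError(f"primer of pair {self.name} shorter than 10 nt")
            if any(c not in "ACGT" for c in p.upper()):
                raise ValueError(f"primer of pair {self.name} not over ACGT")


DEFAULT_PRIMERS: list[PrimerPair] = [
    PrimerPair("Histone", "GAAAAGCAGGCAAACACTC", "GAAGGATGGGTGGAAAGG", 500),
    PrimerPair("NcP1.1", "GGAACCCCAGAACGATACAA", "GACAGAGGCACGCGAAGTAT", 319),
    PrimerPair("NcP2", "TTCGAAGTGTCGCTTGCAGCC", "GCAACCCCAAACTCCTACAA", 415),
]


@dataclass
class SurveyRecord:
    sample_id: str
    species: str
    locality: str
    dna_call: dict[str, str] = field(default_factory=dict)  # name -> POSITIVE/NEGATIVE/ND
    rna_call: dict[str, str] = field(default_factory=dict)


@dataclass
class SurveySummary:
    n_samples: int
    n_dna_positive: dict[str, int]
    n_rna_positive: dict[str, int]
    n_dna_both: int
    n_rna_both: int
    n_dna_only: dict[str, int]
    n_rna_only: dict[str, int]
    consistency_ok: bool


def find_primer_sites(template: str, primer: str, max_mismatch: int = 1,
                      three_prime_exact: int = 3,
                      ) -> list[tuple[int, str, int]]:
    """Annealing sites of a primer on both strands of a template.

    Returns (position, strand, n_mismatch) with position the 1-based
    template coordinate of the window's leftmost base. A site requires at
    most ``max_mismatch`` mismatches overall and none within the primer's
    3'-terminal ``three_prime_exact`` bases. N in the template never
    matches.
    """
    primer = primer.upper()
    if len(primer) < three_prime_exact:
        raise ValueError("primer shorter than the exact 3' block")
    template = template.upper()
    k = len(primer)
    sites: list[tuple[int, str, int]] = []
    rc = revcomp(primer)
    for start in range(len(template) - k + 1):
        win = template[start : start + k]
        # plus strand: primer read left->right, 3' end at the right
        mm = sum(1 for a, b in zip(win, primer) if a != b)
        if mm <= max_mismatch:
            tail = sum(1 for a, b in zip(win[k - three_prime_exact:],
                                         primer[k - three_prime_exact:])
                       if a != b)
            if tail == 0:
                sites.append((start + 1, "+", mm))
        # minus strand: revcomp(primer) matches the window; the primer's 3'
        # end corresponds to the window's leftmost base
        mm = sum(1 for a, b in zip(win, rc) if a != b)
        if mm <= max_mismatch:
            tail = sum(1 for a, b in zip(win[:three_prime_exact],
                                         rc[:three_prime_exact]) if a != b)
            if tail == 0:
                sites.append((start + 1, "-", mm))
    return sites


def predict_amplicons(template: str, pair: PrimerPair, max_len: int = 3000,
                      max_mismatch: int = 1, three_prime_exact: int = 3,
                      ) -> list[tuple[int, int, int]]:
    """Predicted PCR products: a plus-strand site of one primer paired with
    a downstream minus-strand site of the other, 3' ends facing each other.
    Returns (start, end, length), 1-based inclusive on the template."""
    f_sites = find_primer_sites(template, pair.forward, max_mismatch,
                                three_prime_exact)
    r_sites = find_primer_sites(template, pair.reverse, max_mismatch,
                                three_prime_exact)
    out: list[tuple[int, int, int]] = []
    for left_primer, right_primer in ((pair.forward, pair.reverse),
                                      (pair.reverse, pair.forward)):
        lsites = f_sites if left_primer is pair.forward else r_sites
        rsites = r_sites if right_primer is pair.reverse else f_sites
        for lp, lstrand, _ in lsites:
            if lstrand != "+":
                continue
            l_end3 = lp + len(left_primer) - 1
            for rp, rstrand, _ in rsites:
                if rstrand != "-":
                    continue
                if l_end3 >= rp:  # 3' ends must face each other
                    continue
                end = rp + len(right_primer) - 1
                length = end - lp + 1
                if length <= max_len:
                    out.append((lp, end, length))
    return sorted(set(out))


def score_sample(dna_seqs: list | None, cdna_seqs: list | None,
                 pairs: list[PrimerPair] | None = None,
                 sample_id: str = "sample", species: str = "NA",
                 locality: str = "NA", max_len: int = 3000) -> SurveyRecord:
    """POSITIVE iff >=1 amplicon for the pair in the compartment; a missing
    compartment yields ND for every pair there."""
    if not dna_seqs and not cdna_seqs:
        raise ValueError(f"sample {sample_id}: no DNA and no cDNA provided")
    pairs = pairs if pairs is not None else DEFAULT_PRIMERS
    rec = SurveyRecord(sample_id, species, locality)

    def call(seqs):
        out = {}
        for pair in pairs:
            if seqs is None:
                out[pair.name] = "ND"
                continue
            hit = any(predict_amplicons(str(s.seq) if hasattr(s, "seq") else str(s),
                                        pair, max_len=max_len)
                      for s in seqs)
            out[pair.name] = "POSITIVE" if hit else "NEGATIVE"
        return out

    rec.dna_call = call(dna_seqs if dna_seqs else None)
    rec.rna_call = call(cdna_seqs if cdna_seqs else None)
    return rec


def summarize_matrix(records: list[SurveyRecord],
                     eve_names: list[str] | None = None,
                     ) -> tuple[SurveySummary, pd.DataFrame]:
    """Presence/transcription matrix plus per-EVE totals.

    ND calls are excluded from all positive/negative counts. The matrix is
    ordered by locality then species; duplicate sample ids are rejected.
    ``n_both``/``n_only`` are computed over the first two EVE assays when
    more than one is surveyed.
    """
    if not records:
        raise ValueError("no survey records")
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {', '.join(dup)}")
    if eve_names is None:
        eve_names = sorted({k for r in records for k in r.dna_call})

    rows = []
    for r in sorted(records, key=lambda r: (r.locality, r.species, r.sample_id)):
        row = {"sample_id": r.sample_id, "species": r.species,
               "locality": r.locality}
        for e in eve_names:
            row[f"{e}_dna"] = r.dna_call.get(e, "ND")
            row[f"{e}_rna"] = r.rna_call.get(e, "ND")
        rows.append(row)
    matrix = pd.DataFrame(rows)

    def positives(calls_attr, eve):
        return [r.sample_id for r in records
                if getattr(r, calls_attr).get(eve) == "POSITIVE"]

    n_dna_pos = {e: len(positives("dna_call", e)) for e in eve_names}
    n_rna_pos = {e: len(positives("rna_call", e)) for e in eve_names}
    if len(eve_names) >= 2:
        a, b = eve_names[0], eve_names[1]
        dna_a, dna_b = set(positives("dna_call", a)), set(positives("dna_call", b))
        rna_a, rna_b = set(positives("rna_call", a)), set(positives("rna_call", b))
        n_dna_both = len(dna_a & dna_b)
        n_rna_both = len(rna_a & rna_b)
        n_dna_only = {a: len(dna_a - dna_b), b: len(dna_b - dna_a)}
        n_rna_only = {a: len(rna_a - rna_b), b: len(rna_b - rna_a)}
    else:
        n_dna_both = n_rna_both = 0
        n_dna_only = {e: n_dna_pos[e] for e in eve_names}
        n_rna_only = {e: n_rna_pos[e] for e in eve_names}

    consistency = all(
        n_dna_only.get(e, 0) + n_dna_both <= n_dna_pos.get(e, 0)
        or len(eve_names) < 2
        for e in eve_names
    ) and all(v <= len(records) for v in n_dna_pos.values())

    summary = SurveySummary(
        n_samples=len(records),
        n_dna_positive=n_dna_pos, n_rna_positive=n_rna_pos,
        n_dna_both=n_dna_both, n_rna_both=n_rna_both,
        n_dna_only=n_dna_only, n_rna_only=n_rna_only,
        consistency_ok=consistency,
    )
    return summary, matrix


def read_primer_tsv(path: str | os.PathLike) -> list[PrimerPair]:
    """TSV columns: name, forward, reverse, expected_amplicon_len (optional)."""
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, row in df.iterrows():
        exp = row.get("expected_amplicon_len")
        pairs.append(PrimerPair(str(row["name"]), str(row["forward"]),
                                str(row["reverse"]),
                                int(exp) if pd.notna(exp) else None))
    return pairs


def write_summary_json(summary: SurveySummary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(vars(summary), fh, indent=1, sort_keys=True)
        fh.write("\n")
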