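"""Small-RNA signature profiling of candidate EVE loci.

A locus targeted by primary piRNAs accumulates 24-29 nt reads from
predominantly one strand, with discontinuous coverage concentrated in
hotspots; a locus whose transcripts are merely turned over yields a
low-abundance mixture of lengths from both strands (a degradation profile).
This module reproduces that decision chain: quality filtering and adapter
trimming, mismatch-tolerant end-to-end alignment to locus sequences,
size/strand/5'-base/coverage profiling, an exact binomial test for 5'-U
enrichment, and a rule-based classifier.

Classifier thresholds operationalize the qualitative criteria (piRNA size
class 24-29 nt, single-strandedness, minimum depth); they are deliberate,
declared defaults and every one is tunable.
"""

from __future__ import annotations

import gzip
import json
import math
import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from Bio import SeqIO
from scipy.stats import binomtest

from .eve_discovery import revcomp


class ProfileClass(str, Enum):
    PIRNA_TARGET = "PIRNA_TARGET"
    DEGRADATION = "DEGRADATION"
    SIRNA_LIKE = "SIRNA_LIKE"
    INSUFFICIENT = "INSUFFICIENT"


@dataclass
class ReadFilterConfig:
    min_mean_phred: int = 20
    min_length_nt: int = 15
    max_length_nt: int = 35
    disallow_ambiguous: bool = True
    adapter_seq: str | None = None
    adapter_min_overlap: int = 6

    def __post_init__(self):
        if self.min_length_nt < 1 or self.min_length_nt > self.max_length_nt:
            raise ValueError("require 1 <= min_length_nt <= max_length_nt")


@dataclass
class AlignmentPolicy:
    max_mismatches: int = 1
    multimap_rule: str = "ALL_BEST"  # or UNIQUE_ONLY
    # indels are never allowed; both strands always searched

    def __post_init__(self):
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class FilterStats:
    """Removal counters, attributed to exactly one (first-matching) reason."""
    n_input: int = 0
    n_kept: int = 0
    low_quality: int = 0
    ambiguous: int = 0
    too_short: int = 0
    too_long: int = 0
    adapter_trimmed: int = 0


@dataclass
class Read:
    read_id: str
    seq: str
    quals: list[int]


@dataclass
class Alignment:
    read_id: str
    locus_id: str
    offset: int  # 1-based start on the locus plus strand
    strand: str  # '+' or '-'
    n_mismatch: int
    weight: float
    length: int
    read_seq: str  # as sequenced (5'->3')


@dataclass
class SmallRnaProfile:
    locus_id: str
    locus_len: int
    size_hist_plus: dict[int, float]
    size_hist_minus: dict[int, float]
    five_prime_counts: dict[tuple[int, str], float]
    coverage_plus: np.ndarray
    coverage_minus: np.ndarray
    n_aligned: float
    pirna_fraction: float
    major_strand_fraction: float
    u_fraction_pirna: float
    gini: float
    hotspots: list[tuple[int, int]]


@dataclass
class ClassifierThresholds:
    min_reads: int = 100
    pirna_len_lo: int = 24
    pirna_len_hi: int = 29
    min_pirna_fraction: float = 0.5
    min_strand_fraction: float = 0.8
    sirna_len_lo: int = 20
    sirna_len_hi: int = 22
    min_sirna_fraction: float = 0.5

    def __post_init__(self):
        if not (15 <= self.pirna_len_lo <= self.pirna_len_hi <= 35):
            raise ValueError("require 15 <= pirna_len_lo <= pirna_len_hi <= 35")


# ---------------------------------------------------------------------------
# preprocessing

def _looks_phred64(quals: list[int]) -> bool:
    # Phred+33-decoded values above ~45 only occur when the file was really
    # Phred+64 (raw chars beyond 'J')
    return any(q > 45 for q in quals)


def _trim_adapter(seq: str, quals: list[int], adapter: str,
                  min_overlap: int) -> tuple[str, list[int], bool]:
    """3' adapter removal: leftmost position where the read suffix matches a
    prefix of the adapter with >= min_overlap bases and at most 1 mismatch
    per 10 nt of overlap."""
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - i)
        mism = sum(1 for a, b in zip(seq[i : i + overlap], adapter[:overlap])
                   if a != b)
        if mism <= overlap // 10:
            return seq[:i], quals[:i], True
    return seq, quals, False


def parse_fastq(path: str | os.PathLike) -> list[Read]:
    """Phred+33 FASTQ (plain or gzip). Malformed records raise with index."""
    opener = gzip.open if str(path).endswith(".gz") else open
    reads: list[Read] = []
    with opener(str(path), "rt") as fh:
        it = SeqIO.parse(fh, "fastq")
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {idx}: {exc}") from exc
            reads.append(Read(rec.id, str(rec.seq).upper(),
                              rec.letter_annotations["phred_quality"]))
            idx += 1
    return reads


def preprocess_reads(reads: list[Read] | str | os.PathLike,
                     cfg: ReadFilterConfig | None = None,
                     ) -> tuple[list[Read], FilterStats]:
    """Adapter trimming then quality/ambiguity/length filtering, each removal
    attributed to the first matching reason (quality, ambiguous, too short,
    too long — in that order)."""
    if cfg is None:
        cfg = ReadFilterConfig()
    if not isinstance(reads, list):
        reads = parse_fastq(reads)
    stats = FilterStats(n_input=len(reads))
    kept: list[Read] = []
    for r in reads:
        seq, quals = r.seq, r.quals
        if _looks_phred64(quals):
            raise ValueError(
                f"read {r.read_id}: quality values look Phred+64 encoded; "
                f"this pipeline requires Phred+33"
            )
        if cfg.adapter_seq:
            seq, quals, trimmed = _trim_adapter(
                seq, quals, cfg.adapter_seq.upper(), cfg.adapter_min_overlap)
            if trimmed:
                stats.adapter_trimmed += 1
        if len(quals) > 0 and sum(quals) / len(quals) < cfg.min_mean_phred:
            stats.low_quality += 1
            continue
        if cfg.disallow_ambiguous and any(c not in "ACGT" for c in seq):
            stats.ambiguous += 1
            continue
        if len(seq) < cfg.min_length_nt:
            stats.too_short += 1
            continue
        if len(seq) > cfg.max_length_nt:
            stats.too_long += 1
            continue
        kept.append(Read(r.read_id, seq, quals))
        stats.n_kept += 1
    return kept, stats


# ---------------------------------------------------------------------------
# alignment

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def align_reads(reads: list[Read], loci_seqs: dict[str, str],
                policy: AlignmentPolicy | None = None) -> list[Alignment]:
    """All end-to-end, indel-free placements of each read on either strand
    of each locus with at most ``max_mismatches`` mismatches.

    Under ALL_BEST only the minimal-mismatch stratum of each read is kept
    and each placement carries weight 1/(placements kept); under UNIQUE_ONLY
    a read contributes only when it has exactly one placement.
    """
    if policy is None:
        policy = AlignmentPolicy()
    enc = {lid: _encode(s.upper()) for lid, s in loci_seqs.items()}
    out: list[Alignment] = []
    for r in reads:
        placements: list[tuple[int, str, int, str]] = []  # (mm, locus, off, strand)
        fwd = _encode(r.seq)
        rev = _encode(revcomp(r.seq))
        L = len(r.seq)
        if L == 0:
            continue
        for lid, ref in enc.items():
            if L > len(ref):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, L)
            mm_f = (windows != fwd).sum(axis=1)
            mm_r = (windows != rev).sum(axis=1)
            for pos in np.nonzero(mm_f <= policy.max_mismatches)[0]:
                placements.append((int(mm_f[pos]), lid, int(pos) + 1, "+"))
            for pos in np.nonzero(mm_r <= policy.max_mismatches)[0]:
                placements.append((int(mm_r[pos]), lid, int(pos) + 1, "-"))
        if not placements:
            continue
        if policy.multimap_rule == "ALL_BEST":
            best = min(p[0] for p in placements)
            placements = [p for p in placements if p[0] == best]
            w = 1.0 / len(placements)
        elif policy.multimap_rule == "UNIQUE_ONLY":
            if len(placements) != 1:
                continue
            w = 1.0
        else:
            raise ValueError(f"unknown multimap_rule {policy.multimap_rule}")
        for mm, lid, off, strand in placements:
            out.append(Alignment(r.read_id, lid, off, strand, mm, w, L, r.seq))
    return out


# ---------------------------------------------------------------------------
# profile

def gini_coefficient(values: np.ndarray) -> float:
    """Gini of a nonnegative vector (0 = even, ->1 = concentrated)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    total = v.sum()
    if n == 0 or total == 0:
        return 0.0
    ranks = np.arange(1, n + 1)
    return float((2 * (ranks * v).sum()) / (n * total) - (n + 1) / n)


def compute_profile(alignments: list[Alignment], locus_id: str,
                    locus_len: int, hotspot_factor: float = 5.0,
                    hotspot_min_len: int = 10) -> SmallRnaProfile:
    """Accumulate weighted size/strand/5'-base histograms and per-base
    coverage; call hotspots as maximal runs of pooled coverage >=
    ``hotspot_factor`` x mean nonzero coverage, at least
    ``hotspot_min_len`` nt long."""
    size_p: dict[int, float] = {}
    size_m: dict[int, float] = {}
    five: dict[tuple[int, str], float] = {}
    cov_p = np.zeros(locus_len)
    cov_m = np.zeros(locus_len)
    n_aligned = 0.0
    pirna_w = 0.0
    pirna_u = 0.0
    for a in alignments:
        if a.locus_id != locus_id:
            continue
        n_aligned += a.weight
        hist = size_p if a.strand == "+" else size_m
        hist[a.length] = hist.get(a.length, 0.0) + a.weight
        base = a.read_seq[0]  # the read's first sequenced base
        five[(a.length, base)] = five.get((a.length, base), 0.0) + a.weight
        cov = cov_p if a.strand == "+" else cov_m
        cov[a.offset - 1 : a.offset - 1 + a.length] += a.weight
        if 24 <= a.length <= 29:
            pirna_w += a.weight
            if base == "T":
                pirna_u += a.weight

    plus_total = sum(size_p.values())
    minus_total = sum(size_m.values())
    major = (max(plus_total, minus_total) / n_aligned) if n_aligned > 0 else 1.0
    pirna_fraction = pirna_w / n_aligned if n_aligned > 0 else 0.0
    u_fraction = pirna_u / pirna_w if pirna_w > 0 else float("nan")

    pooled = cov_p + cov_m
    nonzero = pooled[pooled > 0]
    hotspots: list[tuple[int, int]] = []
    if len(nonzero) > 0:
        thr = hotspot_factor * nonzero.mean()
        above = pooled >= thr
        i = 0
        while i < locus_len:
            if above[i]:
                j = i
                while j + 1 < locus_len and above[j + 1]:
                    j += 1
                if j - i + 1 >= hotspot_min_len:
                    hotspots.append((i + 1, j + 1))
                i = j + 1
            else:
                i += 1

    return SmallRnaProfile(
        locus_id=locus_id, locus_len=locus_len,
        size_hist_plus=size_p, size_hist_minus=size_m,
        five_prime_counts=five,
        coverage_plus=cov_p, coverage_minus=cov_m,
        n_aligned=n_aligned, pirna_fraction=pirna_fraction,
        major_strand_fraction=major, u_fraction_pirna=u_fraction,
        gini=gini_coefficient(pooled), hotspots=hotspots,
    )


def five_prime_enrichment_test(profile: SmallRnaProfile,
                               null_p: float = 0.25) -> tuple[float, float]:
    """One-sided exact binomial test of 5'-U enrichment among 24-29 nt reads
    against a background proportion (default 0.25). Fractional multimapping
    weights are rounded to integer counts for the test. With zero
    piRNA-class reads, returns (nan, 1.0)."""
    n_w = sum(w for (l, _), w in profile.five_prime_counts.items()
              if 24 <= l <= 29)
    k_w = sum(w for (l, b), w in profile.five_prime_counts.items()
              if 24 <= l <= 29 and b == "T")
    n = int(round(n_w))
    k = min(int(round(k_w)), n)
    if n == 0:
        return float("nan"), 1.0
    res = binomtest(k, n, null_p, alternative="greater")
    return k / n, float(res.pvalue)


def classify_profile(profile: SmallRnaProfile,
                     thresholds: ClassifierThresholds | None = None,
                     ) -> tuple[ProfileClass, dict]:
    """Rule-based call with a rationale record of which rules fired.

    PIRNA_TARGET: enough reads, majority in the piRNA size class, strongly
    single-stranded. SIRNA_LIKE: enough reads, majority 20-22 nt, both
    strands. DEGRADATION: anything else with >0 aligned reads (low-abundance
    mixed-length signal). INSUFFICIENT: nothing aligned.
    """
    t = thresholds or ClassifierThresholds()
    total = profile.n_aligned
    if total == 0:
        return ProfileClass.INSUFFICIENT, {"n_aligned": 0.0}

    def frac_in(lo, hi):
        s = sum(w for l, w in profile.size_hist_plus.items() if lo <= l <= hi)
        s += sum(w for l, w in profile.size_hist_minus.items() if lo <= l <= hi)
        return s / total

    pirna_frac = frac_in(t.pirna_len_lo, t.pirna_len_hi)
    sirna_frac = frac_in(t.sirna_len_lo, t.sirna_len_hi)
    rationale = {
        "n_aligned": total,
        "pirna_fraction": pirna_frac,
        "sirna_fraction": sirna_frac,
        "major_strand_fraction": profile.major_strand_fraction,
        "enough_reads": total >= t.min_reads,
        "single_stranded": profile.major_strand_fraction >= t.min_strand_fraction,
    }
    if (total >= t.min_reads and pirna_frac >= t.min_pirna_fraction
            and profile.major_strand_fraction >= t.min_strand_fraction):
        return ProfileClass.PIRNA_TARGET, rationale
    if (total >= t.min_reads and sirna_frac >= t.min_sirna_fraction
            and profile.major_strand_fraction < t.min_strand_fraction):
        return ProfileClass.SIRNA_LIKE, rationale
    return ProfileClass.DEGRADATION, rationale


# ---------------------------------------------------------------------------
# output

def write_profile_summary(results: list[tuple[SmallRnaProfile, ProfileClass]],
                          path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tn_aligned\tpirna_fraction\t"
                 "major_strand_fraction\tu_fraction\tgini\tclass\n")
        for p, cls in results:
            u = "NA" if math.isnan(p.u_fraction_pirna) else f"{p.u_fraction_pirna:.4f}"
            fh.write(f"{p.locus_id}\t{p.n_aligned:.3f}\t{p.pirna_fraction:.4f}\t"
                     f"{p.major_strand_fraction:.4f}\t{u}\t{p.gini:.4f}\t"
                     f"{cls.value}\n")


def write_profile_json(profile: SmallRnaProfile, cls: ProfileClass,
                       path: str | os.PathLike) -> None:
    payload = {
        "locus_id": profile.locus_id,
        "locus_len": profile.locus_len,
        "n_aligned": profile.n_aligned,
        "pirna_fraction": profile.pirna_fraction,
        "major_strand_fraction": profile.major_strand_fraction,
        "u_fraction_pirna": (None if math.isnan(profile.u_fraction_pirna)
                             else profile.u_fraction_pirna),
        "gini": profile.gini,
        "hotspots": profile.hotspots,
        "size_hist_plus": {str(k): v for k, v in sorted(profile.size_hist_plus.items())},
        "size_hist_minus": {str(k): v for k, v in sorted(profile.size_hist_minus.items())},
        "class": cls.value,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_coverage_bedgraph(profile: SmallRnaProfile,
                            path: str | os.PathLike) -> None:
    """Pooled per-base coverage, BEDGRAPH (0-based half-open)."""
    pooled = profile.coverage_plus + profile.coverage_minus
    with open(path, "w") as fh:
        i = 0
        n = len(pooled)
        while i < n:
            j = i
            while j + 1 < n and pooled[j + 1] == pooled[i]:
                j += 1
            if pooled[i] > 0:
                fh.write(f"{profile.locus_id}\t{i}\t{j+1}\t{pooled[i]:.3f}\n")
            i = j + 1


def write_size_histogram(profile: SmallRnaProfile,
                         path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("length\tplus\tminus\n")
        for l in range(15, 36):
            fh.write(f"{l}\t{profile.size_hist_plus.get(l, 0.0):.3f}\t"
                     f"{profile.size_hist_minus.get(l, 0.0):.3f}\n")
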