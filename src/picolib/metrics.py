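"""Per-library sequence metrics: insert size, read GC, insertion-site logo.

Insert size is the number of bases from the leftmost mapped base of the
first read to the rightmost mapped base of its mate, i.e. the magnitude of
the SAM template length (TLEN), counted once per proper pair.  Summary
statistics use two-tail trimming: after sorting, floor(trim * n) values are
removed from each tail before the mean and (n-1 denominator) standard
deviation are taken.

The insertion-site composition matrix summarizes the first bases of each
read — the region immediately flanking the transposase insertion site — as
per-position base frequencies with Shannon information content, plus the
pooled GC fraction of the flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InsertSizeStats",
    "PositionCompositionMatrix",
    "insert_size_stats",
    "trimmed_mean_sd",
    "read_gc",
    "insertion_site_matrix",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class InsertSizeStats:
    trimmed_mean: float
    trimmed_sd: float
    n_used: int
    trim: float

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "trimmed_mean\ttrimmed_sd\tn_used\ttrim\n"
            f"{self.trimmed_mean:.4f}\t{self.trimmed_sd:.4f}\t{self.n_used}\t{self.trim:g}\n"
        )


def trimmed_mean_sd(values: np.ndarray, trim: float) -> tuple[float, float, int]:
    """Two-tail trimmed mean and sd: floor(trim*n) values cut from each end.

    trim=0 reproduces the untrimmed mean/sd exactly.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise ValueError("no values to summarize")
    cut = int(np.floor(trim * n))
    kept = values[cut : n - cut] if cut else values
    mean = float(kept.mean())
    sd = float(kept.std(ddof=1)) if len(kept) > 1 else 0.0
    return mean, sd, len(kept)


def insert_size_stats(
    alignments: Iterable,
    n_subsample: int = 1_000_000,
    trim: float = 0.01,
    seed=None,
) -> InsertSizeStats:
    """Trimmed insert-size statistics from alignment template lengths.

    One TLEN per pair (the positive-signed mate of a proper pair) is
    collected, uniformly subsampled to ``n_subsample``, trimmed and
    summarized.
    """
    tlens = []
    for rec in alignments:
        if getattr(rec, "is_unmapped", False):
            continue
        if not getattr(rec, "is_proper_pair", True):
            continue
        t = rec.tlen
        if t > 0:
            tlens.append(t)
    if not tlens:
        raise ValueError("no proper pairs with positive TLEN found")
    values = np.asarray(tlens, dtype=np.int64)
    if n_subsample < len(values):
        rng = np.random.default_rng(seed)
        values = rng.choice(values, size=n_subsample, replace=False)
    mean, sd, n_used = trimmed_mean_sd(values, trim)
    return InsertSizeStats(trimmed_mean=mean, trimmed_sd=sd, n_used=n_used, trim=trim)


def _forward_seq(read) -> str:
    seq = getattr(read, "fwd_seq", None)
    if seq is not None:
        return seq
    return read


def read_gc(reads: Iterable, n_reads: int = 10_000, pooled: bool = False) -> float:
    """Average %GC of the first ``n_reads`` forward reads.

    Per-read GC is (G+C)/(A+C+G+T), ignoring N; the default averages the
    per-read fractions, ``pooled=True`` instead pools all counted bases.
    Reads with no countable base are skipped.
    """
    fracs = []
    gc_total = 0
    at_total = 0
    taken = 0
    for read in reads:
        if taken >= n_reads:
            break
        seq = _forward_seq(read).upper()
        taken += 1
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        if gc + at == 0:
            continue
        fracs.append(gc / (gc + at))
        gc_total += gc
        at_total += at
    if not fracs:
        raise ValueError("no reads with countable bases")
    if pooled:
        return 100.0 * gc_total / (gc_total + at_total)
    return 100.0 * float(np.mean(fracs))


@dataclass(frozen=True)
class PositionCompositionMatrix:
    """Per-position base frequencies over the first k bases of reads."""

    freq: np.ndarray  # shape (k, 4), columns A C G T
    info_bits: np.ndarray  # shape (k,)
    flank_gc: float
    reads_used: int

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["position\tA\tC\tG\tT\tinfo_bits"]
        for i in range(self.length):
            f = "\t".join(f"{x:.6f}" for x in self.freq[i])
            lines.append(f"{i + 1}\t{f}\t{self.info_bits[i]:.6f}")
        lines.append(f"# flank_gc\t{self.flank_gc:.6f}\treads_used\t{self.reads_used}")
        Path(path).write_text("\n".join(lines) + "\n")


def insertion_site_matrix(
    reads: Sequence,
    n_reads: int = 1000,
    k: int = 10,
    seed=None,
) -> PositionCompositionMatrix:
    """Base composition of the first ``k`` bases of a read subsample.

    Information content per position is 2 - H bits, with H the Shannon
    entropy of the ACGT frequencies (no small-sample correction); a fixed
    base scores 2 bits, a uniform position ~0.  ``flank_gc`` pools G+C over
    all k * n bases, summarizing the sequence context flanking transposase
    insertion sites.
    """
    seqs = [_forward_seq(r) for r in reads]
    seqs = [s for s in seqs if len(s) >= k]
    if not seqs:
        raise ValueError(f"no reads of length >= {k}")
    if len(seqs) < n_reads:
        warnings.warn(
            f"only {len(seqs)} reads available, fewer than requested {n_reads}; using all",
            stacklevel=2,
        )
        chosen = seqs
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(seqs), size=n_reads, replace=False)
        chosen = [seqs[i] for i in idx]
    counts = np.zeros((k, 4), dtype=np.int64)
    lut = {b: j for j, b in enumerate(_BASES)}
    for s in chosen:
        for i, b in enumerate(s[:k].upper()):
            j = lut.get(b)
            if j is not None:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a position has no countable bases")
    freq = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    gc = counts[:, 1].sum() + counts[:, 2].sum()
    flank_gc = gc / counts.sum()
    return PositionCompositionMatrix(
        freq=freq,
        info_bits=np.clip(info, 0.0, 2.0),
        flank_gc=float(flank_gc),
        reads_used=len(chosen),
    )
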