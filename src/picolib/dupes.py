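"""Read-duplicate estimation and the occupancy model of library complexity.

PCR duplicates in tagmentation libraries are read pairs amplified from the
same template molecule.  They are estimated here in three ways:

1. *Signature*: the first 30 bp of the forward read concatenated with the
   first 30 bp of the reverse read; exact string identity of the 60-mer
   defines duplication (mapping-free, works on raw FASTQ).
2. *Reference*: identical mapped (reference, start, stop) of an aligned
   pair — the classical ``rmdup`` definition.
3. *Occupancy model*: with T unique amplifiable templates sampled uniformly
   n times, the expected number of distinct templates hit is
   T*(1 - (1 - 1/T)**n); inverting this links an observed duplicate
   fraction to an effective template complexity.

Duplicates are counted as total pairs minus unique pairs, so a cluster of
k identical pairs contributes k - 1 duplicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DedupResult",
    "DuplicateCurve",
    "PoolingResult",
    "pair_signature",
    "count_duplicates",
    "rarefaction",
    "expected_unique",
    "unique_count_sd",
    "invert_occupancy",
    "rmdup_reference",
    "pool_replicates",
]


@dataclass(frozen=True)
class DedupResult:
    """Outcome of a duplicate count.

    ``total_pairs`` counts pairs that entered the comparison; pairs whose
    reads were too short for the signature (or unmapped records on the
    reference route) are reported in ``skipped`` and excluded from
    ``total_pairs``.
    """

    total_pairs: int
    unique_pairs: int
    duplicates: int
    method: str
    skipped: int = 0

    def __post_init__(self):
        if self.duplicates != self.total_pairs - self.unique_pairs:
            raise ValueError("duplicates must equal total_pairs - unique_pairs")
        if self.duplicates < 0:
            raise ValueError("negative duplicate count")

    @property
    def duplicate_fraction(self) -> float:
        return self.duplicates / self.total_pairs if self.total_pairs else 0.0


@dataclass(frozen=True)
class DuplicateCurve:
    """Rarefaction of unique pairs over nested subsample depths."""

    depths: np.ndarray
    unique_counts: np.ndarray
    duplicate_fractions: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depths)
        u = np.asarray(self.unique_counts)
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(np.diff(u) < 0):
            raise ValueError("unique_counts must be non-decreasing")
        if np.any(u > d):
            raise ValueError("unique_counts cannot exceed depths")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["depth\tunique\tduplicate_fraction"]
        for d, u, f in zip(self.depths, self.unique_counts, self.duplicate_fractions):
            lines.append(f"{int(d)}\t{int(u)}\t{f:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def _seqs(pair) -> tuple[str, str]:
    """Forward/reverse sequences from a ReadPairRecord or a 2-tuple."""
    fwd = getattr(pair, "fwd_seq", None)
    if fwd is not None:
        return fwd, pair.rev_seq
    return pair[0], pair[1]


def pair_signature(pair, prefix_len: int = 30) -> str:
    """Concatenate the first ``prefix_len`` bases of each mate, case-folded.

    Exact identity of this string (60 bp at the default) defines a read
    duplicate.  Raises if either read is shorter than ``prefix_len``.
    """
    fwd, rev = _seqs(pair)
    if len(fwd) < prefix_len or len(rev) < prefix_len:
        raise ValueError(
            f"reads shorter than prefix_len={prefix_len} carry no signature"
        )
    return (fwd[:prefix_len] + rev[:prefix_len]).upper()


def _signatures(pairs: Iterable, prefix_len: int) -> list:
    """Signature per pair; None marks pairs too short to compare."""
    sigs = []
    append = sigs.append
    for pair in pairs:
        fwd, rev = _seqs(pair)
        if len(fwd) < prefix_len or len(rev) < prefix_len:
            append(None)
        else:
            append((fwd[:prefix_len] + rev[:prefix_len]).upper())
    return sigs


def count_duplicates(
    pairs: Iterable,
    n_sample: int | None = None,
    prefix_len: int = 30,
    seed=None,
) -> DedupResult:
    """Signature-based duplicate count on a uniform subsample of pairs.

    ``n_sample`` pairs are drawn without replacement (all pairs when None);
    duplicates = sampled pairs - distinct signatures.  Pairs with a read
    shorter than ``prefix_len`` are skipped and counted separately.
    """
    sigs = _signatures(pairs, prefix_len)
    available = len(sigs)
    if n_sample is None:
        n_sample = available
    if n_sample > available:
        raise ValueError(
            f"requested n_sample={n_sample} but only {available} pairs available"
        )
    if n_sample < available:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(available, size=n_sample, replace=False)
        sample = [sigs[i] for i in chosen]
    else:
        sample = sigs
    skipped = sum(1 for s in sample if s is None)
    counted = n_sample - skipped
    unique = len({s for s in sample if s is not None})
    return DedupResult(
        total_pairs=counted,
        unique_pairs=unique,
        duplicates=counted - unique,
        method="signature",
        skipped=skipped,
    )


def rarefaction(
    pairs: Iterable,
    increment: int = 100_000,
    seed=None,
    prefix_len: int = 30,
) -> DuplicateCurve:
    """Nested-subsample rarefaction of unique read pairs.

    Subsamples at depths increment, 2*increment, ... where each deeper
    sample extends the previous one (a single random permutation consumed
    prefix-wise), so the duplicate fraction is non-decreasing in depth by
    construction.  Pairs too short for the signature are excluded up front.
    """
    if increment < 1:
        raise ValueError("increment must be >= 1")
    sigs = [s for s in _signatures(pairs, prefix_len) if s is not None]
    n = len(sigs)
    if n < increment:
        raise ValueError(f"need at least {increment} usable pairs, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    depths, uniques = [], []
    seen: set = set()
    pos = 0
    for depth in range(increment, n + 1, increment):
        for i in order[pos:depth]:
            seen.add(sigs[i])
        pos = depth
        depths.append(depth)
        uniques.append(len(seen))
    depths_a = np.array(depths, dtype=np.int64)
    uniques_a = np.array(uniques, dtype=np.int64)
    fracs = (depths_a - uniques_a) / depths_a
    return DuplicateCurve(depths_a, uniques_a, fracs)


def expected_unique(T: float, n: int) -> float:
    """Expected distinct templates hit by n uniform draws (with replacement)
    from T templates: T*(1 - (1 - 1/T)**n)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 0.0
    if T == 1:
        return 1.0
    return float(T * -math.expm1(n * math.log1p(-1.0 / T)))


def unique_count_sd(T: float, n: int) -> float:
    """Exact standard deviation of the distinct-template count for n uniform
    draws from T templates (classical occupancy variance)."""
    if n == 0 or T == 1:
        return 0.0
    q1 = math.exp(n * math.log1p(-1.0 / T))  # (1-1/T)^n
    q2 = math.exp(n * math.log1p(-2.0 / T)) if T > 2 else 0.0  # (1-2/T)^n
    ET = T * (1 - q1)
    second = T * (1 - q1) + T * (T - 1) * (1 - 2 * q1 + q2)
    var = max(second - ET * ET, 0.0)
    return math.sqrt(var)


def invert_occupancy(duplicate_fraction: float, n: int) -> float:
    """Effective template complexity T implied by a duplicate fraction.

    Solves n - expected_unique(T, n) = duplicate_fraction * n for real T
    (monotone; bracketed root find to relative tolerance 1e-9).  A right
    inverse of the forward occupancy expectation.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < duplicate_fraction < 1.0 - 1.0 / n:
        raise ValueError(
            f"duplicate_fraction {duplicate_fraction} infeasible for n={n}: "
            f"must lie in (0, {1.0 - 1.0 / n:.6g})"
        )
    target_unique = (1.0 - duplicate_fraction) * n

    def f(T: float) -> float:
        return expected_unique(T, n) - target_unique

    lo = 1.0
    hi = max(10.0, 10.0 * n / duplicate_fraction)
    while f(hi) < 0:  # pragma: no cover - defensive bracket growth
        hi *= 10
    return float(brentq(f, lo, hi, rtol=1e-12))


def rmdup_reference(alignments: Iterable) -> DedupResult:
    """Reference-based duplicate removal over aligned pairs.

    A duplicate is a pair with the exact same (reference, start, stop) as an
    already seen pair; both coordinates must match.  One record per pair is
    consumed (the leftmost mate, TLEN > 0); unmapped records are skipped and
    counted.
    """
    seen: set = set()
    total = 0
    skipped = 0
    for rec in alignments:
        if getattr(rec, "is_unmapped", False):
            skipped += 1
            continue
        tlen = rec.tlen
        if tlen <= 0:  # count each pair once, via its leftmost mate
            continue
        total += 1
        seen.add((rec.reference_name, rec.pos, rec.pos + tlen))
    unique = len(seen)
    return DedupResult(
        total_pairs=total,
        unique_pairs=unique,
        duplicates=total - unique,
        method="reference",
        skipped=skipped,
    )


@dataclass(frozen=True)
class PoolingResult:
    depth: int
    replicate_fractions: tuple[float, ...]
    pooled_fraction: float

    @property
    def mean_replicate_fraction(self) -> float:
        return float(np.mean(self.replicate_fractions))


def pool_replicates(
    replicate_pair_sets: Sequence[Sequence],
    depth: int,
    seed=None,
    prefix_len: int = 30,
) -> PoolingResult:
    """Duplicate fractions per replicate and for the pooled union, at one depth.

    Replicate libraries carry library-specific template subsets, so pooling
    reads from independent replicates adds new unique templates and lowers
    the duplicate fraction relative to any single replicate at the same depth.
    """
    if len(replicate_pair_sets) < 2:
        raise ValueError("need at least 2 replicates")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(replicate_pair_sets) + 1)
    fracs = []
    pooled: list = []
    for reps, child in zip(replicate_pair_sets, seeds[:-1]):
        sigs = _signatures(reps, prefix_len)
        if len(sigs) < depth:
            raise ValueError(
                f"replicate has {len(sigs)} pairs, fewer than depth {depth}"
            )
        res = count_duplicates(sigs_to_pairs(sigs), n_sample=depth, prefix_len=prefix_len, seed=child)
        fracs.append(res.duplicate_fraction)
        pooled.extend(sigs)
    pooled_res = count_duplicates(
        sigs_to_pairs(pooled), n_sample=depth, prefix_len=prefix_len, seed=seeds[-1]
    )
    return PoolingResult(
        depth=depth,
        replicate_fractions=tuple(fracs),
        pooled_fraction=pooled_res.duplicate_fraction,
    )


def sigs_to_pairs(sigs: list) -> list[tuple[str, str]]:
    """Re-wrap precomputed signatures as minimal pair tuples.

    The forward half carries the whole signature and the reverse half pads to
    the prefix length, so re-signaturing reproduces the original keys.
    """
    out = []
    for s in sigs:
        if s is None:
            out.append(("", ""))
        else:
            half = len(s) // 2
            out.append((s[:half], s[half:]))
    return out
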