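"""Tagmentation / bottleneck / PCR / sequencing simulator.

The generative model mirrors how a transposase-based (Nextera-style)
library is made from a mock community:

1. *Tagmentation* cuts each member's genomic DNA into fragments whose
   length law depends on the transposase:DNA ratio (the ATM dilution),
   with a steric lower bound of 20 bp.  Per-member fragment bases follow
   the community's mass abundances; start positions are uniform on a
   circular genome unless an AT-preferring insertion bias is enabled.
2. A *bottleneck* keeps each fragment with probability ``retention``
   (library creation loses most of the input), leaving the unique
   amplifiable templates whose count fixes library complexity.
3. *Limited-cycle PCR* amplifies each surviving template by a
   Galton-Watson branching process: every copy duplicates per cycle with
   probability ``efficiency``.
4. *Sequencing* draws read pairs from templates proportionally to their
   copy numbers: 150 bp from each fragment end (reverse complement for
   the second mate), optional i.i.d. substitution errors, constant Q30
   qualities.

Preset-based simulation short-circuits steps 1-2 with the packaged
``effective_templates`` count, which is calibrated so analytic duplicate
levels reproduce the observed per-condition percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.stats import binom as _binom_dist

from .community import (
    BP_PER_FG,
    Contaminant,
    MockCommunitySpec,
    expected_abundances,
    simulate_genome,
    synthesize_genomes,
)
from .presets import (
    MIN_FRAGMENT_BP,
    LibraryPreset,
    draw_fragment_lengths,
    insert_size_for,
    preset as get_preset,
)

__all__ = [
    "ReadPairRecord",
    "TruthInfo",
    "FragmentSet",
    "FragmentPool",
    "SimulatedLibrary",
    "tagment",
    "bottleneck_and_amplify",
    "emit_reads",
    "simulate_preset_library",
    "simulate_atm_library",
    "spike_contaminants",
]

DEFAULT_READ_LEN = 150
_QUAL_CHAR = "?"  # phred33 Q30
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Above this template count the per-template amplification arrays are
#: replaced by the exact copy-number-class sampler (see _sample_hits_classes).
_MATERIALIZE_LIMIT = 20_000_000


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class TruthInfo:
    member_id: str
    fragment_start: int  # 0-based, on the circular source genome
    fragment_end: int  # exclusive; end - start = insert length
    template_id: int


@dataclass(frozen=True)
class ReadPairRecord:
    pair_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str
    rev_qual: str
    truth: TruthInfo | None = None

    def __post_init__(self):
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError("sequence and quality lengths must match")


@dataclass
class FragmentSet:
    """Tagmentation fragments as flat arrays (member index, start, length)."""

    member_ids: tuple[str, ...]
    member_idx: np.ndarray
    start: np.ndarray
    length: np.ndarray

    def __len__(self) -> int:
        return len(self.member_idx)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for m, s, ln in zip(self.member_idx, self.start, self.length):
            yield self.member_ids[m], int(s), int(s + ln)

    @property
    def total_bases(self) -> int:
        return int(self.length.sum())

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            self.member_ids, self.member_idx[mask], self.start[mask], self.length[mask]
        )


@dataclass
class FragmentPool:
    """Surviving templates with per-template post-PCR copy numbers."""

    fragments: FragmentSet
    copy_numbers: np.ndarray

    def __post_init__(self):
        if len(self.copy_numbers) != len(self.fragments):
            raise ValueError("copy_numbers must align with templates")
        if np.any(self.copy_numbers < 0):
            raise ValueError("copy numbers must be non-negative")

    def __len__(self) -> int:
        return len(self.fragments)


def _gc_window_cumsum(genome: str, k: int) -> np.ndarray:
    """Cumulative GC indicator over the genome extended by k bases (wrap)."""
    arr = np.frombuffer((genome + genome[:k]).encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    return np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])


def _draw_starts(
    n: int,
    genome_length: int,
    rng: np.random.Generator,
    at_bias: float = 0.0,
    genome: str | None = None,
    window: int = 10,
) -> np.ndarray:
    """Fragment start positions, uniform or AT-biased.

    With ``at_bias`` w in (0, 1], a candidate start is accepted with
    probability 1 - w * (GC fraction of its first ``window`` bases), giving
    insertion sites a GC content below the genome average.
    """
    if at_bias <= 0.0:
        return rng.integers(0, genome_length, size=n, dtype=np.int64)
    if genome is None:
        raise ValueError("insertion-site bias requires the genome sequence")
    cs = _gc_window_cumsum(genome, window)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        need = n - filled
        cand = rng.integers(0, genome_length, size=int(need * 1.6) + 8, dtype=np.int64)
        gcw = (cs[cand + window] - cs[cand]) / window
        keep = cand[rng.random(len(cand)) < 1.0 - at_bias * gcw]
        take = min(len(keep), need)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def tagment(
    spec: MockCommunitySpec,
    input_mass: float,
    atm_dilution: float,
    seed,
    at_bias: float = 0.0,
    genomes: Mapping[str, str] | None = None,
) -> FragmentSet:
    """Fragment the community's DNA according to the ATM-dilution calibration.

    ``input_mass`` is in femtograms; total fragment bases match the
    mass-to-bp conversion, split across members by mass abundance.
    """
    if input_mass <= 0:
        raise ValueError("input_mass must be > 0")
    if atm_dilution < 1:
        raise ValueError("atm_dilution must be >= 1")
    rng = np.random.default_rng(_as_seedseq(seed))
    mean, sd = insert_size_for(atm_dilution, input_mass)
    shares = expected_abundances(spec)["mass_abundance"].to_numpy()
    total_bases = input_mass * BP_PER_FG
    member_chunks, start_chunks, length_chunks = [], [], []
    for i, member in enumerate(spec.members):
        target = total_bases * shares[i]
        n_frags = max(1, int(round(target / mean)))
        lengths = draw_fragment_lengths(mean, sd, n_frags, rng)
        np.minimum(lengths, member.genome_length, out=lengths)
        starts = _draw_starts(
            n_frags,
            member.genome_length,
            rng,
            at_bias=at_bias,
            genome=genomes.get(member.member_id) if genomes else None,
        )
        member_chunks.append(np.full(n_frags, i, dtype=np.int32))
        start_chunks.append(starts)
        length_chunks.append(lengths)
    return FragmentSet(
        tuple(spec.member_ids),
        np.concatenate(member_chunks),
        np.concatenate(start_chunks),
        np.concatenate(length_chunks).astype(np.int64),
    )


def _gw_recursion(
    n: int, cycles: int, efficiency: float, rng: np.random.Generator,
    chunk: int = 5_000_000,
) -> np.ndarray:
    """Per-template Galton-Watson copy numbers after ``cycles`` doublings."""
    copies = np.ones(n, dtype=np.int64)
    if efficiency == 0.0 or cycles == 0:
        return copies
    if efficiency == 1.0:
        copies[:] = 2 ** cycles
        return copies
    for _ in range(cycles):
        for lo in range(0, n, chunk):
            sl = slice(lo, min(lo + chunk, n))
            copies[sl] += rng.binomial(copies[sl], efficiency)
    return copies


def _gw_copy_pmf(cycles: int, efficiency: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the copy number of one template after
    ``cycles`` PCR cycles (support within [1, 2**cycles])."""
    values = np.array([1], dtype=np.int64)
    probs = np.array([1.0])
    if efficiency == 0.0 or cycles == 0:
        return values, probs
    if efficiency == 1.0:
        return np.array([2 ** cycles], dtype=np.int64), np.array([1.0])
    for _ in range(cycles):
        dense = np.zeros(2 * int(values[-1]) + 1)
        for j, pj in zip(values.tolist(), probs.tolist()):
            dense[j : 2 * j + 1] += pj * _binom_dist.pmf(np.arange(j + 1), j, efficiency)
        keep = dense > 1e-18
        values = np.nonzero(keep)[0].astype(np.int64)
        probs = dense[keep]
    return values, probs / probs.sum()


def bottleneck_and_amplify(
    fragments: FragmentSet | Iterable,
    retention: float,
    cycles: int,
    efficiency: float,
    seed,
) -> FragmentPool:
    """Random template loss followed by limited-cycle PCR amplification.

    Each fragment survives independently with probability ``retention``;
    each surviving copy duplicates per cycle with probability
    ``efficiency`` (Galton-Watson branching), so the expected copy number
    is (1 + efficiency)**cycles.
    """
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must be in (0, 1]")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    if not isinstance(fragments, FragmentSet):
        fragments = _fragmentset_from_tuples(fragments)
    rng = np.random.default_rng(_as_seedseq(seed))
    if retention < 1.0:
        mask = rng.random(len(fragments)) < retention
        survivors = fragments.subset(mask)
    else:
        survivors = fragments
    copies = _gw_recursion(len(survivors), cycles, efficiency, rng)
    return FragmentPool(survivors, copies)


def _fragmentset_from_tuples(fragments: Iterable) -> FragmentSet:
    members, starts, lengths = [], [], []
    ids: list[str] = []
    index: dict[str, int] = {}
    for member_id, start, end in fragments:
        if member_id not in index:
            index[member_id] = len(ids)
            ids.append(member_id)
        members.append(index[member_id])
        starts.append(start)
        lengths.append(end - start)
    return FragmentSet(
        tuple(ids),
        np.array(members, dtype=np.int32),
        np.array(starts, dtype=np.int64),
        np.array(lengths, dtype=np.int64),
    )


def _qual(length: int, cache={}) -> str:
    q = cache.get(length)
    if q is None:
        q = cache[length] = _QUAL_CHAR * length
    return q


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        alternatives = "ACGT".replace(chars[p], "") or "ACGT"
        chars[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _reads_from_draws(
    member_ids: Sequence[str],
    member_idx: np.ndarray,
    starts: np.ndarray,
    lengths: np.ndarray,
    template_ids: np.ndarray,
    genomes: Mapping[str, str],
    read_len: int,
    error_rate: float,
    error_seed,
) -> Iterator[ReadPairRecord]:
    rng = np.random.default_rng(_as_seedseq(error_seed))
    seqs = [genomes[m] for m in member_ids]
    lens = [len(s) for s in seqs]
    for i, (m, s, ln, tid) in enumerate(
        zip(member_idx.tolist(), starts.tolist(), lengths.tolist(), template_ids.tolist())
    ):
        g = seqs[m]
        L = lens[m]
        e = s + ln
        frag = g[s:e] if e <= L else g[s:] + g[: e - L]
        fwd = frag[:read_len]
        rev = frag[-read_len:].translate(_COMPLEMENT)[::-1]
        if error_rate > 0.0:
            fwd = _apply_errors(fwd, error_rate, rng)
            rev = _apply_errors(rev, error_rate, rng)
        yield ReadPairRecord(
            pair_id=f"p{i:08d}",
            fwd_seq=fwd,
            rev_seq=rev,
            fwd_qual=_qual(len(fwd)),
            rev_qual=_qual(len(rev)),
            truth=TruthInfo(member_ids[m], s, e, tid),
        )


def emit_reads(
    pool: FragmentPool,
    genomes: Mapping[str, str],
    depth: int,
    read_len: int = DEFAULT_READ_LEN,
    error_rate: float = 0.0,
    seed=None,
) -> Iterator[ReadPairRecord]:
    """Draw ``depth`` read pairs from a fragment pool (with replacement,
    proportionally to copy numbers) and emit paired reads with truth labels.

    The forward read is the first ``read_len`` bases of the fragment and the
    reverse read is the reverse complement of the last ``read_len`` bases
    (the whole fragment when shorter); mates overlap when the insert is
    below 2x the read length.
    """
    if len(pool) == 0:
        raise ValueError("fragment pool is empty")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    ss = _as_seedseq(seed)
    draw_seed, err_seed = ss.spawn(2)
    rng = np.random.default_rng(draw_seed)
    weights = np.cumsum(pool.copy_numbers, dtype=np.float64)
    if weights[-1] <= 0:
        raise ValueError("all copy numbers are zero")
    idx = np.searchsorted(weights, rng.random(depth) * weights[-1], side="right")
    frags = pool.fragments
    return _reads_from_draws(
        frags.member_ids,
        frags.member_idx[idx],
        frags.start[idx],
        frags.length[idx],
        idx.astype(np.int64),
        genomes,
        read_len,
        error_rate,
        err_seed,
    )


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    raw = shares * total
    counts = np.floor(raw).astype(np.int64)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def _sample_hits_materialized(
    T: int, cycles: int, efficiency: float, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Template index per draw, materializing all T copy numbers."""
    copies = _gw_recursion(T, cycles, efficiency, rng)
    weights = np.cumsum(copies, dtype=np.float64)
    return np.searchsorted(weights, rng.random(depth) * weights[-1], side="right").astype(np.int64)


def _sample_hits_classes(
    T: int, cycles: int, efficiency: float, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Template key per draw via exact copy-number classes.

    Copy numbers after amplification are i.i.d. across templates with a
    discrete distribution of support <= 2**cycles; partitioning the T
    templates multinomially into copy-number classes and drawing
    (class, index-within-class) is distributionally identical to
    materializing every template, at a fraction of the memory and time.
    Returned keys are unique per template (class << 40 | index).
    """
    values, probs = _gw_copy_pmf(cycles, efficiency)
    class_counts = rng.multinomial(T, probs / probs.sum())
    class_weight = class_counts.astype(np.float64) * values
    cum = np.cumsum(class_weight)
    cls = np.searchsorted(cum, rng.random(depth) * cum[-1], side="right")
    within = np.floor(rng.random(depth) * class_counts[cls]).astype(np.int64)
    return (cls.astype(np.int64) << 40) | within


@dataclass
class SimulatedLibrary:
    """One simulated sequencing library, held as per-pair truth arrays.

    Read sequences are generated lazily (``read_pairs``) so that multi-
    million-pair libraries stay cheap to hold; two iterations over the same
    object yield byte-identical reads.
    """

    spec: MockCommunitySpec
    preset: LibraryPreset | None
    depth: int
    read_len: int
    error_rate: float
    member_idx: np.ndarray
    starts: np.ndarray
    lengths: np.ndarray
    template_ids: np.ndarray
    genomes: Mapping[str, str]
    _error_seed: object = field(repr=False, default=None)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(self.spec.member_ids)

    def read_pairs(self) -> Iterator[ReadPairRecord]:
        return _reads_from_draws(
            self.member_ids,
            self.member_idx,
            self.starts,
            self.lengths,
            self.template_ids,
            self.genomes,
            self.read_len,
            self.error_rate,
            self._error_seed,
        )

    def truth_labels(self) -> list[str]:
        ids = self.member_ids
        return [ids[m] for m in self.member_idx.tolist()]

    def tlens(self) -> np.ndarray:
        """Truth template lengths (signed-TLEN magnitudes), one per pair."""
        return self.lengths.copy()

    def truth_alignments(self):
        from .io import truth_alignments  # local import avoids a cycle

        return truth_alignments(self)

    def write_truth_sam(self, path) -> None:
        from .io import write_truth_sam

        write_truth_sam(path, self)

    def write_fastq(self, r1_path, r2_path) -> None:
        from .io import write_fastq_pairs

        write_fastq_pairs(self.read_pairs(), r1_path, r2_path)


def simulate_preset_library(
    spec: MockCommunitySpec,
    preset: LibraryPreset | str,
    depth: int,
    seed,
    error_rate: float | None = None,
    genomes: Mapping[str, str] | None = None,
    read_len: int = DEFAULT_READ_LEN,
    efficiency: float = 0.9,
) -> SimulatedLibrary:
    """Simulate a library from a named preset's calibrated parameters.

    The preset's ``effective_templates`` stands in for the tagmentation +
    bottleneck stages (it is the post-loss unique-template count those
    stages would produce); templates are assigned members by mass
    abundance, amplified by the Galton-Watson PCR model, and ``depth``
    read pairs are drawn proportionally to copy numbers.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if error_rate is None:
        error_rate = preset.error_rate
    ss = _as_seedseq(seed)
    s_hits, s_coords, s_genomes, s_errors = ss.spawn(4)
    rng = np.random.default_rng(s_hits)
    T = preset.effective_templates
    if T <= _MATERIALIZE_LIMIT:
        hits = _sample_hits_materialized(T, preset.pcr_cycles, efficiency, depth, rng)
    else:
        hits = _sample_hits_classes(T, preset.pcr_cycles, efficiency, depth, rng)

    uq, inverse = np.unique(hits, return_inverse=True)
    k = len(uq)
    crng = np.random.default_rng(s_coords)
    shares = expected_abundances(spec)["mass_abundance"].to_numpy()
    cum_share = np.cumsum(shares)
    member = np.searchsorted(cum_share, crng.random(k) * cum_share[-1], side="right").astype(np.int32)
    lengths_arr = np.array([m.genome_length for m in spec.members], dtype=np.int64)
    starts = np.floor(crng.random(k) * lengths_arr[member]).astype(np.int64)
    frag_len = draw_fragment_lengths(preset.insert_mean, preset.insert_sd, k, crng)
    np.minimum(frag_len, lengths_arr[member], out=frag_len)

    if genomes is None:
        genomes = synthesize_genomes(spec, s_genomes)
    return SimulatedLibrary(
        spec=spec,
        preset=preset,
        depth=depth,
        read_len=read_len,
        error_rate=error_rate,
        member_idx=member[inverse],
        starts=starts[inverse],
        lengths=frag_len[inverse],
        template_ids=uq[inverse],
        genomes=genomes,
        _error_seed=s_errors,
    )


def simulate_atm_library(
    spec: MockCommunitySpec,
    input_mass: float,
    atm_dilution: float,
    depth: int,
    seed,
    retention: float = 0.1,
    cycles: int = 20,
    efficiency: float = 0.9,
    error_rate: float = 0.0,
    genomes: Mapping[str, str] | None = None,
    read_len: int = DEFAULT_READ_LEN,
    at_bias: float = 0.0,
) -> SimulatedLibrary:
    """Simulate a library through the physical pipeline.

    Runs tagmentation at the given ATM dilution, the retention bottleneck,
    Galton-Watson PCR, and draws ``depth`` read pairs; unlike the preset
    path, template complexity emerges from input mass and retention rather
    than a calibrated constant.
    """
    ss = _as_seedseq(seed)
    s_tag, s_amp, s_draw, s_genomes, s_errors = ss.spawn(5)
    frags = tagment(
        spec, input_mass, atm_dilution, s_tag, at_bias=at_bias, genomes=genomes
    )
    pool = bottleneck_and_amplify(frags, retention, cycles, efficiency, s_amp)
    if len(pool) == 0:
        raise ValueError("no templates survived the bottleneck")
    rng = np.random.default_rng(s_draw)
    weights = np.cumsum(pool.copy_numbers, dtype=np.float64)
    idx = np.searchsorted(weights, rng.random(depth) * weights[-1], side="right")
    if genomes is None:
        genomes = synthesize_genomes(spec, s_genomes)
    frs = pool.fragments
    return SimulatedLibrary(
        spec=spec,
        preset=None,
        depth=depth,
        read_len=read_len,
        error_rate=error_rate,
        member_idx=frs.member_idx[idx],
        starts=frs.start[idx],
        lengths=frs.length[idx],
        template_ids=idx.astype(np.int64),
        genomes=genomes,
        _error_seed=s_errors,
    )


def spike_contaminants(
    pairs: Iterable[ReadPairRecord],
    contaminant_spec: Sequence[Contaminant],
    fractions: Sequence[float],
    seed,
    read_len: int = DEFAULT_READ_LEN,
    insert_mean: float = 250.0,
    insert_sd: float = 90.0,
    genomes: Mapping[str, str] | None = None,
) -> list[ReadPairRecord]:
    """Replace a fraction of pairs with reads from contaminant genomes.

    Each pair is independently replaced by contaminant j with probability
    ``fractions[j]`` (so observed contaminant counts are binomial around
    fraction * depth); replacements carry truth labels naming the
    contaminant.  Models reagent/operator contamination (e.g. human or
    Methylobacterium-like reads) in low-input libraries.
    """
    fractions = list(fractions)
    if len(fractions) != len(contaminant_spec):
        raise ValueError("one fraction per contaminant required")
    if any(f < 0 for f in fractions) or sum(fractions) >= 1.0:
        raise ValueError("fractions must be non-negative and sum to < 1")
    pairs = list(pairs)
    if not fractions or all(f == 0 for f in fractions):
        return pairs
    ss = _as_seedseq(seed)
    s_pick, s_frag, *s_genomes = ss.spawn(2 + len(contaminant_spec))
    if genomes is None:
        genomes = {
            c.contaminant_id: simulate_genome(c.genome_length, c.genomic_gc, sg)
            for c, sg in zip(contaminant_spec, s_genomes)
        }
    rng = np.random.default_rng(s_pick)
    frag_rng = np.random.default_rng(s_frag)
    cum = np.cumsum(fractions)
    pick = np.searchsorted(cum, rng.random(len(pairs)), side="right")
    out = list(pairs)
    replaced = np.nonzero(pick < len(contaminant_spec))[0]
    if len(replaced) == 0:
        return out
    lengths = draw_fragment_lengths(insert_mean, insert_sd, len(replaced), frag_rng)
    for j, (i, ln) in enumerate(zip(replaced.tolist(), lengths.tolist())):
        contam = contaminant_spec[pick[i]]
        g = genomes[contam.contaminant_id]
        L = len(g)
        ln = min(ln, L)
        s = int(frag_rng.integers(0, L))
        e = s + ln
        frag = g[s:e] if e <= L else g[s:] + g[: e - L]
        fwd = frag[:read_len]
        rev = frag[-read_len:].translate(_COMPLEMENT)[::-1]
        out[i] = ReadPairRecord(
            pair_id=f"contam{j:08d}",
            fwd_seq=fwd,
            rev_seq=rev,
            fwd_qual=_qual(len(fwd)),
            rev_qual=_qual(len(rev)),
            truth=TruthInfo(contam.contaminant_id, s, e, -(j + 1)),
        )
    return out
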