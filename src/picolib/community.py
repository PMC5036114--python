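"""Mock community construction and expected-abundance arithmetic.

A mock community is a defined mixture of genomic DNAs: each member
contributes a known mass of DNA from a genome of known length and GC
content, so its expected share of shotgun reads can be computed exactly.
Shotgun reads sample nucleotides in proportion to DNA mass, hence the
mass fraction of a member is its expected read-level relative abundance;
dividing mass by genome length instead gives genome-copy (cell-level)
abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CommunityMember",
    "Contaminant",
    "MockCommunitySpec",
    "build_mock_spec",
    "default_mock_spec",
    "expected_abundances",
    "simulate_genome",
    "synthesize_genomes",
    "cell_equivalents",
    "BP_PER_FG",
]

#: Base pairs of double-stranded DNA per femtogram (0.978e9 bp per pg).
BP_PER_FG = 0.978e6

#: Seed fixing the packaged default community (masses, GC assignment, lengths).
DEFAULT_SPEC_SEED = 20160922


@dataclass(frozen=True)
class CommunityMember:
    member_id: str
    genome_length: int
    genomic_gc: float
    dna_mass: float  # femtograms


@dataclass(frozen=True)
class Contaminant:
    """A non-community reference (reagent or operator contaminant)."""

    contaminant_id: str
    genome_length: int
    genomic_gc: float


@dataclass(frozen=True)
class MockCommunitySpec:
    members: tuple[CommunityMember, ...]
    contaminants: tuple[Contaminant, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.members:
            raise ValueError("community spec needs at least one member")
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("member_ids must be unique")
        for m in self.members:
            if m.dna_mass <= 0:
                raise ValueError(f"{m.member_id}: dna_mass must be > 0")
            if m.genome_length <= 0:
                raise ValueError(f"{m.member_id}: genome_length must be > 0")
            if not 0.0 <= m.genomic_gc <= 1.0:
                raise ValueError(f"{m.member_id}: genomic_gc must be in [0, 1]")
        for c in self.contaminants:
            if c.genome_length <= 0 or not 0.0 <= c.genomic_gc <= 1.0:
                raise ValueError(f"invalid contaminant {c.contaminant_id}")

    @property
    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member(self, member_id: str) -> CommunityMember:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    def to_tsv(self, path: str | Path) -> None:
        """Write the member table (member_id, genome_length, gc, mass_fg)."""
        rows = [
            f"{m.member_id}\t{m.genome_length}\t{m.genomic_gc:.6g}\t{m.dna_mass:.6g}"
            for m in self.members
        ]
        Path(path).write_text(
            "member_id\tgenome_length\tgc\tmass_fg\n" + "\n".join(rows) + "\n"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MockCommunitySpec":
        df = pd.read_csv(path, sep="\t")
        members = tuple(
            CommunityMember(str(r.member_id), int(r.genome_length), float(r.gc), float(r.mass_fg))
            for r in df.itertuples()
        )
        return cls(members)


def cell_equivalents(mass_fg: float, fg_per_cell: float = 1.0) -> float:
    """Number of microbial cell equivalents in ``mass_fg`` of DNA.

    Typical prokaryotic cells carry 1-10 fg of DNA, so 1 ng corresponds to
    1e5-1e6 cells and 1 pg to 1e2-1e3 cells.
    """
    if mass_fg < 0 or fg_per_cell <= 0:
        raise ValueError("mass must be >= 0 and fg_per_cell > 0")
    return mass_fg / fg_per_cell


def _ladder_shares(n: int, min_frac: float, max_frac: float) -> np.ndarray:
    """Relative-abundance ladder spanning exactly [min_frac, max_frac].

    Shares follow a warped geometric ladder s_i = min * (max/min)**((i/(n-1))**g)
    with the warp exponent g solved so the shares sum to one.  g = 1 is a plain
    geometric (log-spaced) ladder; warping preserves log spacing ordering while
    pinning both endpoints and the total.
    """
    if min_frac == max_frac:
        if abs(n * min_frac - 1.0) > 1e-9:
            raise ValueError(
                f"equal-abundance span {min_frac} infeasible for {n} members"
            )
        return np.full(n, min_frac)
    ratio = max_frac / min_frac
    lo_sum = (n - 1) * min_frac + max_frac  # warp -> inf limit
    hi_sum = min_frac + (n - 1) * max_frac  # warp -> 0 limit
    if not (lo_sum <= 1.0 <= hi_sum):
        raise ValueError(
            f"abundance span ({min_frac}, {max_frac}) infeasible for {n} members"
        )
    x = (np.arange(n) / (n - 1)).astype(float)

    def total(log_gamma: float) -> float:
        g = np.exp(log_gamma)
        return min_frac * np.power(ratio, np.power(x, g)).sum() - 1.0

    lg = brentq(total, -14.0, 14.0, xtol=1e-13)
    shares = min_frac * np.power(ratio, np.power(x, np.exp(lg)))
    return shares


def build_mock_spec(
    n_members: int,
    gc_range: tuple[float, float],
    abundance_span: tuple[float, float],
    seed: int,
    total_mass_fg: float = 1.0e6,
    genome_length_range: tuple[float, float] = (1.6e6, 6.0e6),
) -> MockCommunitySpec:
    """Construct a synthetic mock community specification.

    Masses are assigned on a log-spaced ladder and normalized so the
    expected mass abundances span exactly ``abundance_span``; genomic GC
    values evenly cover ``gc_range`` (shuffled so GC is uncorrelated with
    abundance); genome lengths are drawn uniformly from
    ``genome_length_range``.
    """
    low, high = gc_range
    min_frac, max_frac = abundance_span
    if n_members < 2:
        raise ValueError("n_members must be >= 2")
    if not (0.0 <= low <= high <= 1.0):
        raise ValueError("gc_range must satisfy 0 <= low <= high <= 1")
    if not (0.0 < min_frac <= max_frac < 1.0):
        raise ValueError("abundance_span must satisfy 0 < min <= max < 1")
    if min_frac * n_members > 1.0:
        raise ValueError(
            f"abundance span infeasible: {n_members} members at minimum "
            f"{min_frac} exceed a total of 1"
        )
    rng = np.random.default_rng(seed)
    shares = _ladder_shares(n_members, min_frac, max_frac)
    masses = shares * total_mass_fg
    gcs = rng.permutation(np.linspace(low, high, n_members))
    lengths = rng.uniform(*genome_length_range, size=n_members).astype(int)
    width = len(str(n_members))
    members = tuple(
        CommunityMember(f"m{i + 1:0{width}d}", int(lengths[i]), float(gcs[i]), float(masses[i]))
        for i in range(n_members)
    )
    return MockCommunitySpec(members)


@lru_cache(maxsize=1)
def default_mock_spec() -> MockCommunitySpec:
    """The packaged default: 54 members, genomic GC 0.28-0.70, expected
    relative abundances spanning 0.04%-25%."""
    return build_mock_spec(54, (0.28, 0.70), (0.0004, 0.25), seed=DEFAULT_SPEC_SEED)


def expected_abundances(spec: MockCommunitySpec) -> pd.DataFrame:
    """Expected relative abundances from DNA mass and genome length.

    Returns a DataFrame indexed by member_id with columns

    - ``mass_abundance``: m_i / sum(m) — the expected read-level share,
      since shotgun reads sample nucleotides proportionally to mass;
    - ``cell_abundance``: (m_i / L_i) normalized — genome-copy share.
    """
    masses = np.array([m.dna_mass for m in spec.members], dtype=float)
    lengths = np.array([m.genome_length for m in spec.members], dtype=float)
    mass_ab = masses / masses.sum()
    copies = masses / lengths
    cell_ab = copies / copies.sum()
    return pd.DataFrame(
        {"mass_abundance": mass_ab, "cell_abundance": cell_ab},
        index=pd.Index(spec.member_ids, name="member_id"),
    )


_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(length: int, gc: float, seed) -> str:
    """I.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random(length), side="right")
    return _BASE_LUT[idx].tobytes().decode("ascii")


def synthesize_genomes(spec: MockCommunitySpec, seed) -> dict[str, str]:
    """Generate one random genome per member (and contaminant) of ``spec``.

    Stand-in sequences for the community's reference genomes, matching each
    member's declared length and GC content.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    refs = list(spec.members) + list(spec.contaminants)
    children = ss.spawn(len(refs))
    out: dict[str, str] = {}
    for ref, child in zip(refs, children):
        name = getattr(ref, "member_id", None) or ref.contaminant_id
        out[name] = simulate_genome(ref.genome_length, ref.genomic_gc, child)
    return out
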