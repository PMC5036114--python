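"""Community-profile construction and composition-fidelity statistics.

A community profile counts mapped read pairs per reference, splitting
references into community members, known contaminants, a human reference
and phiX; relative abundances are computed over community members only,
while the contamination breakdown is over all pairs.  Fidelity between two
profiles (e.g. a low-input library against the standard-protocol baseline
or the expected mass abundances) is the Pearson correlation of relative
abundances, with Bonferroni-corrected p-values when several comparisons
form a family.  Replicate variability is summarized by the mean
coefficient of variation and GC-driven bias by comparing summed abundances
of low/medium/high genomic-GC member classes across libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import MockCommunitySpec, expected_abundances

__all__ = [
    "CATEGORIES",
    "CommunityProfile",
    "FidelityReport",
    "GCClassBias",
    "profile_from_alignments",
    "profile_from_truth",
    "expected_profile",
    "correlate_profiles",
    "mean_cv",
    "gc_class_bias",
]

CATEGORIES = ("community", "contaminant", "human", "phix")


@dataclass
class CommunityProfile:
    """Per-reference mapped-pair counts with a contamination breakdown."""

    counts: dict[str, int]
    unmapped: int
    manifest: Mapping[str, str]  # reference -> category

    def __post_init__(self):
        for ref in self.counts:
            if ref not in self.manifest:
                raise KeyError(f"reference {ref!r} missing from the manifest")
        bad = set(self.manifest.values()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown manifest categories: {sorted(bad)}")

    @property
    def community_members(self) -> list[str]:
        return sorted(r for r, c in self.manifest.items() if c == "community")

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values()) + self.unmapped

    @property
    def relative_abundance(self) -> pd.Series:
        """Relative abundances over community members only."""
        members = self.community_members
        vals = np.array([self.counts.get(m, 0) for m in members], dtype=float)
        total = vals.sum()
        if total > 0:
            vals = vals / total
        return pd.Series(vals, index=members, name="relative_abundance")

    @property
    def breakdown(self) -> dict[str, float]:
        """Fractions of all pairs by category (plus unmapped); sums to 1."""
        total = self.total_pairs
        sums = {cat: 0 for cat in CATEGORIES}
        for ref, n in self.counts.items():
            sums[self.manifest[ref]] += n
        out = {cat: (sums[cat] / total if total else 0.0) for cat in CATEGORIES}
        out["unmapped"] = self.unmapped / total if total else 0.0
        return out

    def to_tsv(self, path) -> None:
        ra = self.relative_abundance
        lines = ["reference\tcategory\tcount\trelative_abundance"]
        for ref in sorted(self.counts):
            cat = self.manifest[ref]
            rel = f"{ra[ref]:.8f}" if cat == "community" else ""
            lines.append(f"{ref}\t{cat}\t{self.counts[ref]}\t{rel}")
        lines.append(f"*\tunmapped\t{self.unmapped}\t")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "CommunityProfile":
        counts: dict[str, int] = {}
        manifest: dict[str, str] = {}
        unmapped = 0
        with open(path) as handle:
            header = handle.readline()
            if not header.startswith("reference\t"):
                raise ValueError(f"{path}: not a profile table")
            for line in handle:
                ref, cat, count, _rel = line.rstrip("\n").split("\t")
                if ref == "*":
                    unmapped = int(count)
                else:
                    counts[ref] = int(count)
                    manifest[ref] = cat
        return cls(counts=counts, unmapped=unmapped, manifest=manifest)


def _manifest_from_spec(spec: MockCommunitySpec) -> dict[str, str]:
    manifest = {m.member_id: "community" for m in spec.members}
    for c in spec.contaminants:
        guess = "human" if "human" in c.contaminant_id.lower() else "contaminant"
        manifest[c.contaminant_id] = guess
    return manifest


def profile_from_truth(
    labels: Iterable[str | None],
    manifest: Mapping[str, str] | MockCommunitySpec,
) -> CommunityProfile:
    """Profile from simulator truth labels (None or '*' marks unmapped)."""
    if isinstance(manifest, MockCommunitySpec):
        manifest = _manifest_from_spec(manifest)
    counts: dict[str, int] = {}
    unmapped = 0
    for lab in labels:
        if lab is None or lab == "*":
            unmapped += 1
        else:
            counts[lab] = counts.get(lab, 0) + 1
    return CommunityProfile(counts=counts, unmapped=unmapped, manifest=manifest)


def profile_from_alignments(
    alignments_or_truth: Iterable,
    manifest: Mapping[str, str] | MockCommunitySpec,
) -> CommunityProfile:
    """Profile from alignment records (or truth labels).

    Counts one record per pair: the primary alignment of the forward mate.
    Unmapped forward mates accrue to the unmapped pool.  A reference seen
    in the alignments but absent from the manifest raises, naming it.
    """
    if isinstance(manifest, MockCommunitySpec):
        manifest = _manifest_from_spec(manifest)
    it = iter(alignments_or_truth)
    try:
        first = next(it)
    except StopIteration:
        return CommunityProfile(counts={}, unmapped=0, manifest=manifest)
    import itertools

    stream = itertools.chain([first], it)
    if isinstance(first, str) or first is None:
        return profile_from_truth(stream, manifest)
    counts: dict[str, int] = {}
    unmapped = 0
    for rec in stream:
        if not getattr(rec, "is_read1", True):
            continue
        if getattr(rec, "is_secondary", False) or getattr(rec, "is_supplementary", False):
            continue
        if getattr(rec, "is_unmapped", False):
            unmapped += 1
            continue
        ref = rec.reference_name
        if ref not in manifest:
            raise KeyError(f"reference {ref!r} missing from the manifest")
        counts[ref] = counts.get(ref, 0) + 1
    return CommunityProfile(counts=counts, unmapped=unmapped, manifest=manifest)


def expected_profile(spec: MockCommunitySpec, scale: int = 1_000_000) -> CommunityProfile:
    """The expected (mass-abundance) profile as a pseudo-count profile."""
    ab = expected_abundances(spec)["mass_abundance"]
    counts = {m: int(round(scale * a)) for m, a in ab.items()}
    return CommunityProfile(counts=counts, unmapped=0, manifest=_manifest_from_spec(spec))


@dataclass(frozen=True)
class FidelityReport:
    r: float
    r_squared: float
    p_raw: float
    p_bonferroni: float
    n_members: int
    excluded_top: int
    mean_cv: float | None = None

    def to_tsv(self, path) -> None:
        from pathlib import Path

        cv = f"{self.mean_cv:.6f}" if self.mean_cv is not None else ""
        Path(path).write_text(
            "r\tr_squared\tp_raw\tp_bonferroni\tn_members\texcluded_top\tmean_cv\n"
            f"{self.r:.6f}\t{self.r_squared:.6f}\t{self.p_raw:.6g}\t"
            f"{self.p_bonferroni:.6g}\t{self.n_members}\t{self.excluded_top}\t{cv}\n"
        )


def _abundance_vector(profile) -> pd.Series:
    if isinstance(profile, CommunityProfile):
        return profile.relative_abundance
    s = pd.Series(profile, dtype=float).sort_index()
    total = s.sum()
    return s / total if total > 0 else s


def correlate_profiles(
    a,
    b,
    exclude_top: int = 0,
    family_size: int = 1,
) -> FidelityReport:
    """Pearson correlation between two community profiles.

    With ``exclude_top`` = t > 0 the t most abundant members of profile
    ``a`` (the comparison baseline; ties broken by member id) are dropped
    from both and the vectors renormalized — the check that fidelity is not
    carried by the dominant organisms alone.  The p-value is the two-sided
    t-test of r; Bonferroni multiplies by ``family_size``.
    """
    va = _abundance_vector(a)
    vb = _abundance_vector(b)
    if set(va.index) != set(vb.index):
        raise ValueError("profiles cover different member sets")
    vb = vb.reindex(va.index)
    if exclude_top < 0 or exclude_top >= len(va):
        raise ValueError("exclude_top must be in [0, n_members)")
    if exclude_top > 0:
        order = sorted(va.index, key=lambda m: (-va[m], m))
        keep = [m for m in order[exclude_top:]]
        va = va[keep]
        vb = vb[keep]
        if va.sum() > 0:
            va = va / va.sum()
        if vb.sum() > 0:
            vb = vb / vb.sum()
    if len(va) < 3:
        raise ValueError("need at least 3 members after exclusion")
    r, p = stats.pearsonr(va.to_numpy(), vb.to_numpy())
    return FidelityReport(
        r=float(r),
        r_squared=float(r) ** 2,
        p_raw=float(p),
        p_bonferroni=min(1.0, float(p) * family_size),
        n_members=len(va),
        excluded_top=exclude_top,
    )


def mean_cv(
    replicate_profiles: Sequence,
    min_count_threshold: float = 20.0,
) -> float:
    """Mean coefficient of variation (sd/mean) across replicate profiles.

    Computed per community member whose mean count across replicates
    exceeds ``min_count_threshold`` (low-count taxa are noise-dominated),
    then averaged over qualifying members.
    """
    if len(replicate_profiles) < 2:
        raise ValueError("need at least 2 replicates")
    cols = {}
    for i, prof in enumerate(replicate_profiles):
        if isinstance(prof, CommunityProfile):
            members = prof.community_members
            cols[i] = pd.Series({m: prof.counts.get(m, 0) for m in members}, dtype=float)
        else:
            cols[i] = pd.Series(prof, dtype=float)
    table = pd.DataFrame(cols).fillna(0.0)
    means = table.mean(axis=1)
    qualifying = table.loc[means > min_count_threshold]
    if qualifying.empty:
        raise ValueError("no member exceeds the count threshold")
    cvs = qualifying.std(axis=1, ddof=1) / qualifying.mean(axis=1)
    return float(cvs.mean())


@dataclass(frozen=True)
class GCClassBias:
    """Per-library summed abundances of low/medium/high-GC member classes."""

    table: pd.DataFrame  # columns: library, replicate, gc_class, abundance
    anova_p: dict[str, float]
    tukey: dict[str, object] = field(repr=False, default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)  # member -> class


def _gc_classes(spec: MockCommunitySpec) -> dict[str, str]:
    """Tertile partition of members by genomic GC (ties to the lower class)."""
    ordered = sorted(spec.members, key=lambda m: (m.genomic_gc, m.member_id))
    n = len(ordered)
    names = ("low", "medium", "high")
    return {m.member_id: names[(3 * rank) // n] for rank, m in enumerate(ordered)}


def gc_class_bias(
    profiles: Mapping[str, Sequence[CommunityProfile]],
    spec: MockCommunitySpec,
) -> GCClassBias:
    """Test for GC-dependent abundance bias across library conditions.

    Members are split into genomic-GC tertiles; per replicate the relative
    abundances of each class are summed; a one-way ANOVA across libraries
    (replicates as observations) is run within each class, with Tukey HSD
    pairwise follow-up when more than two libraries are compared.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 libraries")
    classes = _gc_classes(spec)
    class_names = ("low", "medium", "high")
    if any(name not in classes.values() for name in class_names):
        raise ValueError("every GC class needs at least one member")
    rows = []
    for lib, reps in profiles.items():
        if not reps:
            raise ValueError(f"library {lib!r} has no replicates")
        for j, prof in enumerate(reps):
            ra = prof.relative_abundance
            sums = {name: 0.0 for name in class_names}
            for member, value in ra.items():
                sums[classes[member]] += value
            for name in class_names:
                rows.append({"library": lib, "replicate": j, "gc_class": name,
                             "abundance": sums[name]})
    table = pd.DataFrame(rows)
    anova_p: dict[str, float] = {}
    tukey: dict[str, object] = {}
    for name in class_names:
        sub = table[table.gc_class == name]
        groups = [g.abundance.to_numpy() for _, g in sub.groupby("library")]
        if all(len(g) > 1 for g in groups) and len(groups) >= 2:
            if all(np.ptp(g) == 0 for g in groups) and np.ptp(sub.abundance.to_numpy()) == 0:
                anova_p[name] = 1.0  # identical groups: no effect to test
            else:
                anova_p[name] = float(stats.f_oneway(*groups).pvalue)
                tukey[name] = stats.tukey_hsd(*groups)
        else:
            anova_p[name] = float("nan")
    return GCClassBias(table=table, anova_p=anova_p, tukey=tukey, classes=classes)
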