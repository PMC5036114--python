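"""End-to-end validation workflow: simulate -> metrics -> duplicates -> fidelity.

Mirrors the per-condition summary a sequencing QC report prints: replicate
libraries are simulated from a preset, and for each replicate the mean
insert size, mean read %GC and duplicate percentage at a common sampling
depth are computed, together with a read classification breakdown
(community / human / contaminant / unmapped), a fidelity correlation
against the expected community profile, and the mean coefficient of
variation across replicates.  All tables are TSV; a machine-readable
summary.json records the configuration and replicate means.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from functools import lru_cache

from .community import Contaminant, MockCommunitySpec, default_mock_spec, synthesize_genomes
from .dupes import count_duplicates
from .fidelity import correlate_profiles, expected_profile, mean_cv, profile_from_truth
from .metrics import insert_size_stats, read_gc
from .presets import preset as get_preset
from .simulate import simulate_preset_library, spike_contaminants

__all__ = ["RunConfig", "run_validation_workflow", "DEFAULT_CONTAMINANTS"]

#: Synthetic stand-ins for the recurrent contaminant references: an
#: operator (human-like) genome and a reagent (Methylobacterium-like) one.
DEFAULT_CONTAMINANTS = (
    Contaminant("human_like", 3_000_000, 0.41),
    Contaminant("methylobacterium_like", 5_000_000, 0.686),
)


@dataclass
class RunConfig:
    seed: int
    preset: str = "sop"
    depth: int = 20_000
    replicates: int = 3
    out_dir: str = "picolib_run"
    human_fraction: float = 0.0
    contaminant_fraction: float = 0.0
    error_rate: float | None = None
    gc_reads: int = 10_000
    insert_subsample: int = 1_000_000
    insert_trim: float = 0.01
    cv_threshold: float = 20.0
    spec_seed: int | None = None  # None -> packaged default community

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _round(x: float, nd: int = 6) -> float:
    return float(round(x, nd))


#: Seed fixing the synthetic reference genomes; a property of the community,
#: not of the run, so replicates and libraries share one reference set.
_GENOME_SEED = 977


@lru_cache(maxsize=2)
def _reference_genomes(spec: MockCommunitySpec) -> dict[str, str]:
    return synthesize_genomes(spec, _GENOME_SEED)


def run_validation_workflow(config: RunConfig) -> Path:
    """Run the full simulation + QC workflow; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.spec_seed is None:
        spec = default_mock_spec()
    else:
        from .community import build_mock_spec

        spec = build_mock_spec(54, (0.28, 0.70), (0.0004, 0.25), seed=config.spec_seed)
    spec = MockCommunitySpec(spec.members, DEFAULT_CONTAMINANTS)
    pre = get_preset(config.preset)
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(config.replicates + 1)
    contam_fracs = [config.human_fraction, config.contaminant_fraction]

    rows = []
    profiles = []
    stage = "simulate"
    try:
        for r in range(config.replicates):
            stage = f"simulate replicate {r}"
            sim = simulate_preset_library(
                spec, pre, config.depth, rep_seeds[r],
                error_rate=config.error_rate, genomes=_reference_genomes(spec),
            )
            pairs = list(sim.read_pairs())
            if any(f > 0 for f in contam_fracs):
                pairs = spike_contaminants(
                    pairs, list(DEFAULT_CONTAMINANTS), contam_fracs, rep_seeds[r].spawn(1)[0]
                )
            stage = f"metrics replicate {r}"
            ins = insert_size_stats(
                sim.truth_alignments(),
                n_subsample=config.insert_subsample,
                trim=config.insert_trim,
                seed=config.seed,
            )
            gc_pct = read_gc(pairs, n_reads=config.gc_reads)
            stage = f"duplicates replicate {r}"
            dup = count_duplicates(pairs, n_sample=len(pairs), seed=config.seed)
            stage = f"profile replicate {r}"
            labels = [p.truth.member_id if p.truth else None for p in pairs]
            prof = profile_from_truth(labels, spec)
            profiles.append(prof)
            prof.to_tsv(out / f"profile_rep{r + 1}.tsv")
            br = prof.breakdown
            rows.append(
                {
                    "replicate": r + 1,
                    "pairs": len(pairs),
                    "insert_size_mean": _round(ins.trimmed_mean, 2),
                    "insert_size_sd": _round(ins.trimmed_sd, 2),
                    "pct_gc": _round(gc_pct, 3),
                    "pct_duplicates": _round(100.0 * dup.duplicate_fraction, 3),
                    "frac_community": _round(br["community"]),
                    "frac_human": _round(br["human"]),
                    "frac_contaminant": _round(br["contaminant"]),
                    "frac_phix": _round(br["phix"]),
                    "frac_unmapped": _round(br["unmapped"]),
                }
            )
        stage = "fidelity"
        mean_counts: dict[str, float] = {}
        for m in spec.member_ids:
            mean_counts[m] = float(np.mean([p.counts.get(m, 0) for p in profiles]))
        report = correlate_profiles(expected_profile(spec), mean_counts)
        report.to_tsv(out / "fidelity.tsv")
        stage = "cv"
        cv = mean_cv(profiles, min_count_threshold=config.cv_threshold)
    except Exception as exc:
        raise RuntimeError(
            f"workflow stage {stage!r} failed for config {config.to_dict()}"
        ) from exc

    header = list(rows[0].keys())
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(row[h]) for h in header))
    means = {
        h: _round(float(np.mean([row[h] for row in rows])), 4)
        for h in header
        if h != "replicate"
    }
    lines.append("\t".join(["mean"] + [str(means[h]) for h in header if h != "replicate"]))
    (out / "summary.tsv").write_text("\n".join(lines) + "\n")

    import numpy
    import scipy

    from . import __version__

    (out / "run_info.json").write_text(
        json.dumps(
            {
                "config": config.to_dict(),
                "versions": {
                    "picolib": __version__,
                    "numpy": numpy.__version__,
                    "scipy": scipy.__version__,
                },
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    summary = {
        "config": config.to_dict(),
        "replicates": rows,
        "replicate_means": means,
        "fidelity": {
            "r": _round(report.r),
            "r_squared": _round(report.r_squared),
            "p_raw": report.p_raw,
            "p_bonferroni": report.p_bonferroni,
            "n_members": report.n_members,
        },
        "mean_cv": _round(cv),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return out
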