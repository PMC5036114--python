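"""Estimate read duplicates three ways and link them to library complexity.

Duplicates are read pairs amplified from the same template.  The
signature estimator (first 30 bp of each mate, exact 60-mer identity)
needs only raw FASTQ; the reference estimator needs mapped start/stop
coordinates; the occupancy model T*(1-(1-1/T)**n) converts a duplicate
fraction into an effective number of unique templates.
"""

import numpy as np

import picolib as pl

spec = pl.build_mock_spec(6, (0.30, 0.65), (0.02, 0.40), seed=11,
                          genome_length_range=(400_000, 600_000))
genomes = pl.synthesize_genomes(spec, 12)
depth = 100_000
sim = pl.simulate_preset_library(spec, "1pg", depth, seed=29, error_rate=0.0,
                                 genomes=genomes)

sig = pl.count_duplicates(sim.read_pairs(), n_sample=depth, seed=0)
ref = pl.rmdup_reference(sim.truth_alignments())
print(f"signature duplicates: {sig.duplicates:,} of {sig.total_pairs:,} "
      f"({100 * sig.duplicate_fraction:.2f}%)")
print(f"reference duplicates: {ref.duplicates:,} ({100 * ref.duplicate_fraction:.2f}%)")
# On an error-free simulation both estimators count template collisions,
# so they agree up to pairs too short to carry a 30 bp signature (skipped
# by the signature route); sequencing errors perturb only the signature.

T_est = pl.invert_occupancy(sig.duplicate_fraction, depth)
print(f"implied effective templates: {T_est:,.0f} "
      f"(preset packages {sim.preset.effective_templates:,})")
# The inversion under-counts slightly because PCR gives templates unequal
# copy numbers, which inflates collisions relative to uniform sampling.

curve = pl.rarefaction(sim.read_pairs(), increment=20_000, seed=1)
print("\nrarefaction (depth, unique pairs, duplicate fraction):")
for d, u, f in zip(curve.depths, curve.unique_counts, curve.duplicate_fractions):
    print(f"  {d:>8,}  {u:>8,}  {f:.3f}")
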