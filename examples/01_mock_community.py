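"""Build the packaged mock community and inspect its expected composition.

The community mimics a defined pool of 54 bacterial/archaeal genomic DNAs:
genomic GC spans 28-70% and the mass-based expected relative abundances
span 0.04%-25%.  Mass abundance is the expected share of shotgun reads;
cell abundance divides mass by genome length (genome copies).
"""

import picolib as pl

spec = pl.default_mock_spec()
ab = pl.expected_abundances(spec)

print(f"members: {spec.n_members}")
print(f"expected mass abundance: {ab.mass_abundance.min():.4%} .. {ab.mass_abundance.max():.2%}")
gcs = [m.genomic_gc for m in spec.members]
print(f"genomic GC: {min(gcs):.0%} .. {max(gcs):.0%}")
print(f"1 ng of DNA at 1 fg/cell is {pl.cell_equivalents(1e6):.0f} cell equivalents;"
      f" 1 pg is {pl.cell_equivalents(1e3):.0f}")
print()
print("five most abundant members:")
print(ab.sort_values("mass_abundance", ascending=False).head().to_string(
    float_format=lambda x: f"{x:.4f}"))
# The top members dominate read counts, which is why fidelity checks are
# repeated with the five most dominant organisms excluded.
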