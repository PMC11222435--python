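"""Simulate nanopore squiggles over a CpG-island reference.

Builds a k-mer pore model with a methylation level shift, generates a
reference with planted CpG islands and per-site methylation truth, and
simulates one read with raw signal, move table and alignment.
"""

import numpy as np

import squigmeth as sq

config = sq.SimConfig(reference_length=8000, n_islands=2, island_length=500, seed=42)
reference, truth = sq.simulate_reference(config)
pore = sq.build_pore_model(k=6, mod_shift=1.0, seed=42)

n_cpg = sum(1 for _, strand, _ in truth.sites if strand == "+")
island_freqs = [f for _, _, f in truth.sites]
print(f"reference: {len(reference)} bp with {n_cpg} CpG dinucleotides")
print(f"mean truth methylation frequency: {np.mean(island_freqs):.3f}")
# islands are mostly unmethylated, background mostly methylated, so the mean
# sits between the two mixture modes

bundle = sq.simulate_read(reference, truth, pore, config, seed=7, length=1200)
print(f"\nread {bundle.read_id}: {len(bundle.sequence)} basecalls, "
      f"{len(bundle.signal)} raw samples, stride {bundle.stride}")
print(f"alignment: {bundle.alignment.strand} strand at {bundle.alignment.start}, "
      f"CIGAR {bundle.alignment.cigar[:40]}...")
print(f"move-table invariants hold: sum(moves)={int(bundle.moves.sum())} "
      f"== basecalls, signal == stride x steps: "
      f"{len(bundle.signal) == bundle.stride * len(bundle.moves)}")

wgbs = sq.simulate_wgbs(truth, config, seed=8)
print(f"\nsimulated bisulfite truth: {len(wgbs)} covered sites, "
      f"mean coverage {np.mean([r.coverage for r in wgbs]):.1f}x")
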