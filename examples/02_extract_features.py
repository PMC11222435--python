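"""Turn a read bundle into per-CpG site examples.

Each example is a 15-base token window centred on the assayed cytosine plus
the signal blocks whose anchoring base falls inside the window, with
window-relative reference and query indices for the positional encodings.
"""

import numpy as np

import squigmeth as sq
from squigmeth.features import FeatureConfig, extract_examples

config = sq.SimConfig(reference_length=8000, seed=42)
reference, truth = sq.simulate_reference(config)
pore = sq.build_pore_model(k=6, mod_shift=1.0, seed=42)
bundle = sq.simulate_read(reference, truth, pore, config, seed=7, length=1200)

fc = FeatureConfig(window=15, mode="reference")
stats = {}
examples = extract_examples(bundle, reference, fc, stats=stats)
print(f"extracted {stats['emitted']} examples "
      f"({stats['filtered_blocks']} failed the block-count filter, "
      f"{stats['window_overflow']} windows overflowed the read)")

e = examples[0]
print(f"\nfirst example: {e.contig}:{e.position}{e.strand}")
print(f"tokens ({len(e.tokens)}): "
      + "".join("ACGT?*"[t] for t in e.tokens)
      + "   <- C at the centre, G next")
print(f"signal blocks: {e.blocks.shape} (s blocks x b samples, normalized)")
print(f"reference indices span {e.ref_idx.min()}..{e.ref_idx.max()}, "
      f"query indices span {e.query_idx.min()}..{e.query_idx.max()}")
# both index vectors are nondecreasing: blocks walk left-to-right over the window
assert np.all(np.diff(e.ref_idx) >= 0) and np.all(np.diff(e.query_idx) >= 0)
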