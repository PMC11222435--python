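"""Call per-read methylation probabilities and aggregate them per site.

Loads no checkpoint: for speed this demo uses an untrained model with a
zeroed prediction head, so every probability is exactly 0.5 and the
aggregation bookkeeping is easy to follow.  Swap in a trained checkpoint
(see 03_train_tiny_model.py) for real calls.
"""

import squigmeth as sq
from squigmeth import io
from squigmeth.calling import aggregate_sites, call_reads
from squigmeth.features import FeatureConfig
from squigmeth.model import ModelConfig, init_params

config = sq.SimConfig(reference_length=6000, seed=3)
reference, truth = sq.simulate_reference(config)
pore = sq.build_pore_model(k=6, mod_shift=1.0, seed=3)
bundles = [sq.simulate_read(reference, truth, pore, config, seed=i,
                            length=800, read_id=f"read{i}") for i in range(20)]

mcfg = ModelConfig(latent=32, heads=4, n_enc=1, n_dec=1, d_ff=64,
                   window=15, block_width=5, codebook_size=16)
params = init_params(mcfg, seed=0)
params["mod_head.w"].data[:] = 0.0
params["mod_head.b"].data[:] = 0.0

fc = FeatureConfig(window=15, mode="reference")
calls = call_reads(params, mcfg, bundles, reference, fc)
sites = aggregate_sites(calls, threshold=0.5)
print(f"{len(calls)} read calls over {len(sites)} strand-specific sites")
print(f"total site coverage equals call count: "
      f"{sum(s.coverage for s in sites)} == {len(calls)}")
# probability exactly 0.5 is counted unmethylated (strict > threshold)
print(f"methylated calls at threshold 0.5: {sum(s.n_mod for s in sites)}")

io.write_read_calls(calls, "calls.tsv")
io.write_site_records(sites, "sites.tsv")
print("wrote calls.tsv and sites.tsv (headered, deterministically ordered)")
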