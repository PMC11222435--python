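"""Benchmark site calls against bisulfite truth.

Builds a synthetic "perfect caller" whose site frequencies equal the truth,
then runs the evaluation battery: truth filtering, confusion metrics,
Pearson correlation, coverage CCDF and the high-filtering classification.
"""

import numpy as np

import squigmeth as sq
from squigmeth import evaluation as E
from squigmeth.types import SiteRecord

config = sq.SimConfig(reference_length=10_000, seed=5, bisulfite_error=0.0)
reference, truth = sq.simulate_reference(config)
wgbs = sq.simulate_wgbs(truth, config, seed=6)

# a perfect caller: 20x coverage, frequency identical to the truth
sites = [SiteRecord(truth.contig, pos, strand, 20, int(round(20 * freq)))
         for pos, strand, freq in truth.sites]

eval_config = E.EvalConfig()
truth_sites = E.filter_truth(wgbs, eval_config, "classification")
labels = {(r.contig, r.position): int(r.frequency >= 0.99) for r in truth_sites}
paired = [(s.frequency, labels[(s.contig, s.position)]) for s in sites
          if (s.contig, s.position) in labels]
scores = np.array([p for p, _ in paired])
y = np.array([l for _, l in paired])
metrics = E.confusion_metrics(scores, y)
print(f"classification truth kept {len(truth_sites)}/{len(wgbs)} sites "
      f"(coverage >= max(P5, 5), partials removed)")
print(f"perfect caller: accuracy {metrics.accuracy:.3f}, F1 {metrics.f1:.3f}, "
      f"FPR {metrics.fpr:.3f}  <- all errors come from bisulfite sampling noise")

r, n = E.correlate_sites(sites, wgbs, eval_config)
print(f"Pearson r vs WGBS over {n} sites: {r:.4f}")

ccdf = E.coverage_ccdf(np.array([s.coverage for s in sites]))
print(f"coverage CCDF: ccdf(0)={ccdf[0]:.2f}, ccdf(20)={ccdf[20]:.2f} "
      f"(every site called at 20x)")

for overall, valid in [(20, 20), (20, 16), (10, 4), (4, 4)]:
    cls = E.high_filtering_analysis(overall, valid)
    print(f"overall {overall:2d}, valid {valid:2d} -> {cls}")
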