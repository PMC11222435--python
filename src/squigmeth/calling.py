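"""Inference over reads and unfiltered site-level aggregation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .features import FeatureConfig, extract_examples
from .model import ModelConfig
from .training import predict_probabilities
from .types import ReadBundle, ReadCall, SiteRecord

__all__ = ["CallingConfig", "call_reads", "aggregate_sites"]


@dataclass
class CallingConfig:
    batch_size: int = 256
    threshold: float = 0.5  # per-read binarization for aggregation

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def call_reads(
    params: dict,
    mconfig: ModelConfig,
    bundles: Iterable[ReadBundle],
    reference: str | None,
    feature_config: FeatureConfig,
    calling_config: CallingConfig | None = None,
    stats: dict | None = None,
) -> list[ReadCall]:
    """One modification probability per emitted CpG example.

    No confidence filtering is applied: every example that passes feature
    extraction produces a call, so site coverage reflects all usable reads.
    """
    if calling_config is None:
        calling_config = CallingConfig()
    if mconfig.window != feature_config.window or mconfig.block_width != feature_config.block_width:
        raise ValueError("model and feature configs disagree on window/block size")
    examples = []
    for bundle in bundles:
        examples.extend(extract_examples(bundle, reference, feature_config, stats=stats))
    if not examples:
        return []
    probs = predict_probabilities(params, mconfig, examples, calling_config.batch_size)
    return [
        ReadCall(e.read_id, e.contig, e.position, e.strand, float(p))
        for e, p in zip(examples, probs)
    ]


def aggregate_sites(calls: Iterable[ReadCall], threshold: float = 0.5) -> list[SiteRecord]:
    """Group calls by (contig, position, strand) into per-site frequencies.

    A call counts as methylated iff its probability is strictly above the
    threshold (ties go to unmethylated for determinism).  Every covered site
    is emitted; minimum-coverage filtering belongs to evaluation.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    for c in calls:
        key = (c.contig, c.position, c.strand)
        entry = counts.setdefault(key, [0, 0])
        entry[0] += 1
        if c.probability > threshold:
            entry[1] += 1
    return [
        SiteRecord(contig=k[0], position=k[1], strand=k[2], coverage=v[0], n_mod=v[1])
        for k, v in sorted(counts.items())
    ]
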