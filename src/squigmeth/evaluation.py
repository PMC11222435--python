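"""Benchmarking framework for methylation calls against bisulfite truth.

Implements the full evaluation battery used to compare nanopore callers with
WGBS: coverage/partial-methylation truth filtering, confusion metrics with
average precision, genomic-context stratification (genic, repeat, CpG
island/shore/shelf, GC content, singleton CpGs), TSS methylation profiles,
strand-specific coverage CCDF, highly-confident site comparison, and the
missing-position / high-filtering-position analysis of read-level filtering
bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .types import AnnotationTrack, SiteRecord, WgbsRecord

__all__ = [
    "EvalConfig",
    "ConfusionCounts",
    "MetricsReport",
    "SiteComparison",
    "filter_truth",
    "confusion_metrics",
    "annotate_contexts",
    "correlate_sites",
    "tss_profile",
    "coverage_ccdf",
    "strand_specific_coverage",
    "confident_site_comparison",
    "site_status",
    "high_filtering_analysis",
]


@dataclass
class EvalConfig:
    """Evaluation thresholds; defaults follow the benchmarking protocol."""

    min_ont_coverage: int = 5        # site-level/correlation keep ONT coverage > this
    min_wgbs_coverage: int = 5       # lower bound is max(P5, this)
    partial_band: tuple[float, float] = (0.01, 0.99)
    read_threshold: float = 0.5
    site_threshold: float = 0.5
    tss_bin_size: int = 50           # 125 for CTCF-style anchor tracks
    tss_min_ont_coverage: int = 3
    tss_min_wgbs_coverage: int = 5
    promoter_halo: int = 2000
    shore_width: int = 2000
    shelf_width: int = 2000
    gc_window: int = 5
    singleton_halo: int = 10
    confident_min_coverage: int = 5


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    fpr: float
    f1: float
    average_precision: float
    counts: ConfusionCounts


@dataclass
class SiteComparison:
    """Highly-confident site categories between two methods (A vs B).

    Per class (methylated positive / unmethylated negative): concordant
    calls; discordant calls where exactly one side is backed by at least one
    support call set; unique calls where the other method is uncalled; plus
    sites uncalled by both and discordant sites with no (or ambiguous)
    support.  The categories partition the evaluated site universe.
    """

    concordant: dict = field(default_factory=lambda: {"positive": 0, "negative": 0})
    discordant_a_supported: int = 0
    discordant_b_supported: int = 0
    discordant_unresolved: int = 0
    unique_a: dict = field(default_factory=lambda: {"positive": 0, "negative": 0})
    unique_b: dict = field(default_factory=lambda: {"positive": 0, "negative": 0})
    uncalled_both: int = 0

    @property
    def total(self) -> int:
        return (
            sum(self.concordant.values())
            + self.discordant_a_supported
            + self.discordant_b_supported
            + self.discordant_unresolved
            + sum(self.unique_a.values())
            + sum(self.unique_b.values())
            + self.uncalled_both
        )


# ---------------------------------------------------------------------------
# truth filtering


def _nearest_rank(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile (deterministic, no interpolation)."""
    v = np.sort(np.asarray(values))
    if len(v) == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(pct / 100.0 * len(v)))
    return float(v[rank - 1])


def filter_truth(
    records: list[WgbsRecord], config: EvalConfig, purpose: str = "classification"
) -> list[WgbsRecord]:
    """Coverage- and methylation-filter bisulfite truth.

    Classification: keep coverage >= max(P5, 5) and drop partially
    methylated sites (frequency strictly inside the partial band); surviving
    sites are positives (>= 0.99) or negatives (<= 0.01).  Correlation: same
    lower bound, additionally drop coverage > P95, keep partials.
    """
    if purpose not in ("classification", "correlation"):
        raise ValueError(f"unknown purpose {purpose!r}")
    covered = [r for r in records if r.coverage > 0]
    if not covered:
        return []
    coverages = np.array([r.coverage for r in covered])
    lower = max(_nearest_rank(coverages, 5), config.min_wgbs_coverage)
    upper = _nearest_rank(coverages, 95) if purpose == "correlation" else np.inf
    lo_band, hi_band = config.partial_band
    out = []
    for r in covered:
        if r.coverage < lower or r.coverage > upper:
            continue
        if purpose == "classification" and lo_band < r.frequency < hi_band:
            continue
        out.append(r)
    return out


def truth_labels(records: list[WgbsRecord], config: EvalConfig) -> dict[tuple[str, int], int]:
    """Binary labels for classification-filtered truth records."""
    lo, hi = config.partial_band
    return {
        (r.contig, r.position): int(r.frequency >= hi)
        for r in records
        if not (lo < r.frequency < hi)
    }


# ---------------------------------------------------------------------------
# metrics


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Standard confusion-derived metrics, methylated = positive.

    ``scores`` may be read-level probabilities or site-level frequencies; the
    prediction is positive iff the score is strictly above the threshold.
    Average precision uses the full ranking and is threshold-free.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0:
        raise ValueError("no overlapping sites to evaluate")
    pred = scores > threshold
    pos = labels == 1
    c = ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else float("nan")
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")
    fpr = c.fp / (c.fp + c.tn) if c.fp + c.tn else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    if len(np.unique(labels)) == 2:
        ap = float(average_precision_score(labels, scores))
    else:
        ap = float("nan")
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        fpr=fpr,
        f1=f1,
        average_precision=ap,
        counts=c,
    )


# ---------------------------------------------------------------------------
# genomic context annotation


def _distance_to_track(track: AnnotationTrack | None, contig: str, position: int) -> float:
    """0 inside an interval, else distance to the closest interval edge."""
    if track is None:
        return float("inf")
    ivs = track.intervals.get(contig)
    if ivs is None or len(ivs) == 0:
        return float("inf")
    starts, ends = ivs[:, 0], ivs[:, 1]
    d = np.where(
        (starts <= position) & (position < ends),
        0,
        np.minimum(np.abs(starts - position), np.abs(ends - 1 - position)),
    )
    return float(d.min())


def _gc_bucket(fraction: float) -> int:
    """Smallest bucket >= 100*g among {20, 40, 60, 80, 100}."""
    for bucket in (20, 40, 60, 80, 100):
        if 100.0 * fraction <= bucket:
            return bucket
    return 100


def annotate_contexts(
    sites: list[SiteRecord],
    tracks: dict[str, AnnotationTrack],
    reference: dict[str, str] | None,
    config: EvalConfig | None = None,
) -> list[dict[str, str | int | None]]:
    """Per-site context labels for stratified evaluation.

    ``tracks`` may provide: ``tss`` (BED6 anchor points), ``gene``, ``exon``,
    ``island`` and repeat classes ``SINE``/``LINE``/``LTR``/``DNA``/``Other``.
    Genic precedence is promoter > exon > intron > intergenic with promoters
    as TSS +/- 2000; island overlap wins over shore (2 kb flank) over shelf
    (next 2 kb); repeats resolve in the fixed class order.  GC content is the
    G+C fraction of the 5-base window around the cytosine; a site is a
    singleton iff no other CpG lies within +/-10 bp.  Missing tracks or
    reference mark the context ``None`` rather than fabricating one.
    """
    if config is None:
        config = EvalConfig()
    tss = tracks.get("tss")
    gene = tracks.get("gene")
    exon = tracks.get("exon")
    island = tracks.get("island")
    repeat_order = ("SINE", "LINE", "LTR", "DNA", "Other")

    out = []
    for site in sites:
        ctx: dict[str, str | int | None] = {}
        # genic category with promoter > exon > intron > intergenic
        if tss is None and gene is None and exon is None:
            ctx["genic"] = None
        elif tss is not None and _tss_distance(tss, site.contig, site.position) <= config.promoter_halo:
            ctx["genic"] = "promoter"
        elif exon is not None and exon.overlaps(site.contig, site.position):
            ctx["genic"] = "exon"
        elif gene is not None and gene.overlaps(site.contig, site.position):
            ctx["genic"] = "intron"  # gene minus exon
        else:
            ctx["genic"] = "intergenic"

        # repeat class, fixed priority on overlap
        ctx["repeat"] = None
        if any(r in tracks for r in repeat_order):
            ctx["repeat"] = "none"
            for r in repeat_order:
                t = tracks.get(r)
                if t is not None and t.overlaps(site.contig, site.position):
                    ctx["repeat"] = r
                    break

        # island / shore / shelf
        if island is None:
            ctx["island_zone"] = None
        else:
            d = _distance_to_track(island, site.contig, site.position)
            if d == 0:
                ctx["island_zone"] = "island"
            elif d <= config.shore_width:
                ctx["island_zone"] = "shore"
            elif d <= config.shore_width + config.shelf_width:
                ctx["island_zone"] = "shelf"
            else:
                ctx["island_zone"] = "open_sea"

        # sequence-derived contexts
        seq = None if reference is None else reference.get(site.contig)
        if seq is None:
            ctx["gc_bucket"] = None
            ctx["singleton"] = None
        else:
            half = config.gc_window // 2
            window = seq[max(0, site.position - half) : site.position + half + 1]
            gc = sum(ch in "GCgc" for ch in window) / max(1, len(window))
            ctx["gc_bucket"] = _gc_bucket(gc)
            ctx["singleton"] = _is_singleton(seq, site, config.singleton_halo)
        out.append(ctx)
    return out


def _tss_distance(tss: AnnotationTrack, contig: str, position: int) -> float:
    ivs = tss.intervals.get(contig)
    if ivs is None or len(ivs) == 0:
        return float("inf")
    strands = tss.strands.get(contig, ["."] * len(ivs))
    anchors = np.where(
        np.array(strands) == "-", ivs[:, 1] - 1, ivs[:, 0]
    )
    return float(np.min(np.abs(anchors - position)))


def _is_singleton(seq: str, site: SiteRecord, halo: int) -> bool:
    own_cg = site.position if site.strand == "+" else site.position - 1
    lo = max(0, site.position - halo - 1)
    hi = min(len(seq), site.position + halo + 2)
    window = seq[lo:hi].upper()
    pos = window.find("CG")
    while pos != -1:
        p = lo + pos
        if p != own_cg and (
            abs(p - site.position) <= halo or abs(p + 1 - site.position) <= halo
        ):
            return False
        pos = window.find("CG", pos + 1)
    return True


# ---------------------------------------------------------------------------
# correlation, profiles, coverage


def correlate_sites(
    ont_sites: list[SiteRecord],
    wgbs: list[WgbsRecord],
    config: EvalConfig | None = None,
) -> tuple[float, int]:
    """Pearson r between ONT and bisulfite frequencies on shared sites.

    ONT sites need coverage above the minimum; WGBS sites are filtered with
    the correlation-purpose bounds (lower max(P5, 5), upper P95), partials
    retained.  Matching is by (contig, position); the position of a CpG
    cytosine identifies its strand.
    """
    if config is None:
        config = EvalConfig()
    truth = {
        (r.contig, r.position): r.frequency
        for r in filter_truth(wgbs, config, "correlation")
    }
    pairs = [
        (s.frequency, truth[(s.contig, s.position)])
        for s in ont_sites
        if s.coverage > config.min_ont_coverage and (s.contig, s.position) in truth
    ]
    if len(pairs) < 2:
        return float("nan"), len(pairs)
    x, y = np.array(pairs).T
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), len(pairs)
    return float(np.corrcoef(x, y)[0, 1]), len(pairs)


def tss_profile(
    sites: list[SiteRecord],
    anchors: list[tuple[str, int, str]],
    bin_size: int = 50,
    max_offset: int = 2000,
    min_ont_coverage: int = 3,
    wgbs: list[WgbsRecord] | None = None,
    min_wgbs_coverage: int = 5,
) -> dict[int, float]:
    """Mean methylation frequency binned by signed distance to the TSS.

    ``bin = floor((pos - P + floor(B/2)) / B)`` with minus-strand offsets
    negated so upstream is negative.  Sites below the ONT coverage floor (or
    the WGBS floor, when truth is supplied for joint filtering) are dropped.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    wgbs_cov = None
    if wgbs is not None:
        wgbs_cov = {(r.contig, r.position): r.coverage for r in wgbs}
    anchor_by_contig: dict[str, list[tuple[int, str]]] = {}
    for contig, position, strand in anchors:
        anchor_by_contig.setdefault(contig, []).append((position, strand))
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for s in sites:
        if s.coverage < min_ont_coverage:
            continue
        if wgbs_cov is not None and wgbs_cov.get((s.contig, s.position), 0) < min_wgbs_coverage:
            continue
        for P, strand in anchor_by_contig.get(s.contig, []):
            offset = s.position - P
            if strand == "-":
                offset = -offset
            if abs(offset) > max_offset:
                continue
            b = math.floor((offset + bin_size // 2) / bin_size)
            sums[b] = sums.get(b, 0.0) + s.frequency
            counts[b] = counts.get(b, 0) + 1
    return {b: sums[b] / counts[b] for b in sorted(sums)}


def coverage_ccdf(coverages: np.ndarray, n_sites: int | None = None) -> dict[int, float]:
    """ccdf(cov) = N_{>=cov} / N_sites for every integer cov >= 0.

    ``n_sites`` defaults to the number of covered sites supplied; pass the
    full CpG universe size to account for entirely uncovered sites (which
    contribute coverage 0).
    """
    coverages = np.asarray(coverages, dtype=np.int64)
    if n_sites is None:
        n_sites = len(coverages)
    if n_sites == 0:
        raise ValueError("ccdf undefined for zero sites")
    out = {}
    for cov in range(int(coverages.max(initial=0)) + 1):
        out[cov] = float(np.sum(coverages >= cov)) / n_sites if cov > 0 else 1.0
    return out


def strand_specific_coverage(n_bases: int, genome_size: int) -> float:
    """Total sequenced bases over twice the genome size (two strands)."""
    return n_bases / (2.0 * genome_size)


# ---------------------------------------------------------------------------
# confident-site comparison


def site_status(
    site: SiteRecord | WgbsRecord | None, min_coverage: int = 5, threshold: float = 0.5
) -> str:
    """positive / negative / uncalled per the confident-site rules.

    Positive needs coverage >= 5 and frequency strictly above 50%; frequency
    exactly 50% with sufficient coverage is negative; coverage below 5 (or no
    record at all) is uncalled.
    """
    if site is None or site.coverage < min_coverage:
        return "uncalled"
    return "positive" if site.frequency > threshold else "negative"


def confident_site_comparison(
    a_sites: list[SiteRecord] | list[WgbsRecord],
    b_sites: list[SiteRecord] | list[WgbsRecord],
    support_sets: list[list[SiteRecord]] | None = None,
    config: EvalConfig | None = None,
) -> SiteComparison:
    """Categorize every site of the A/B universe into confident-call classes.

    Concordant: both methods call the same class.  Discordant: calls differ;
    the side whose call is backed by at least one support call set claims the
    site (ambiguous or unsupported discordance is counted separately).
    Unique: one method calls, the other is uncalled.
    """
    if config is None:
        config = EvalConfig()
    min_cov, thr = config.confident_min_coverage, config.site_threshold

    def index(sites):
        return {(s.contig, s.position): s for s in sites}

    a_map, b_map = index(a_sites), index(b_sites)
    support_maps = [index(s) for s in (support_sets or [])]
    result = SiteComparison()
    for key in sorted(set(a_map) | set(b_map)):
        sa = site_status(a_map.get(key), min_cov, thr)
        sb = site_status(b_map.get(key), min_cov, thr)
        if sa == "uncalled" and sb == "uncalled":
            result.uncalled_both += 1
        elif sa == sb:
            result.concordant[sa] += 1
        elif sa == "uncalled":
            result.unique_b[sb] += 1
        elif sb == "uncalled":
            result.unique_a[sa] += 1
        else:
            statuses = [site_status(m.get(key), min_cov, thr) for m in support_maps]
            a_ok = sa in statuses
            b_ok = sb in statuses
            if a_ok and not b_ok:
                result.discordant_a_supported += 1
            elif b_ok and not a_ok:
                result.discordant_b_supported += 1
            else:
                result.discordant_unresolved += 1
    return result


# ---------------------------------------------------------------------------
# filtering-bias analysis


def high_filtering_analysis(
    overall_coverage: int, valid_coverage: int, expected_filter_rate: float = 0.10
) -> str:
    """Classify a site by how read-level confidence filtering affected it.

    ``overall`` counts all read calls including filtered ones; ``valid``
    counts only the calls surviving the filter.  A missing position has
    valid coverage < 5; it is attributed to filtering when the overall
    coverage would have sufficed.  A high-filtering position retains enough
    valid coverage but lost more than the expected fraction of its calls.
    """
    if valid_coverage > overall_coverage:
        raise ValueError("valid coverage cannot exceed overall coverage")
    if overall_coverage < 5:
        return "missing-low-overall"
    if valid_coverage < 5:
        return "missing-due-to-filtering"
    if overall_coverage - valid_coverage > expected_filter_rate * overall_coverage:
        return "high-filtering"
    return "ok"
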