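"""Synthetic nanopore squiggle simulator with CpG methylation.

Emulates the data a basecaller hands to a modification caller: a raw current
trace whose level depends on the k-mer in the pore (with an additive shift
when the k-mer overlaps a methylated CpG cytosine), a stride-based move table
aligning signal to basecalls, basecalling errors with a consistent CIGAR, and
matched bisulfite (Bismark-coverage style) ground truth.

Signal is in arbitrary normalized units; there is no pA calibration.  Dwell
times are shifted-geometric in units of the stride (minimum one step per
base), which produces realistically variable block counts per base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import Alignment, ReadBundle, WgbsRecord

__all__ = [
    "PoreModel",
    "MethylationTruth",
    "SimConfig",
    "build_pore_model",
    "simulate_reference",
    "simulate_read",
    "simulate_wgbs",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _kmer_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _BASE_TO_INT.get(ch, 0)
    return idx


@dataclass
class PoreModel:
    """k-mer current-level table with a methylation-induced level shift."""

    k: int
    level_mean: np.ndarray  # (4**k,)
    level_sd: np.ndarray    # (4**k,)
    mod_shift: float
    dwell_mean: float       # mean raw samples per base
    stride: int             # raw samples per move-table step

    def __post_init__(self) -> None:
        if np.any(self.level_sd <= 0):
            raise ValueError("level_sd must be positive for every k-mer")
        if self.dwell_mean < self.stride:
            raise ValueError("dwell_mean must be at least one stride")

    def level(self, kmer: str, methylated: bool = False) -> float:
        base = float(self.level_mean[_kmer_index(kmer)])
        return base + self.mod_shift if methylated else base

    def sd(self, kmer: str) -> float:
        return float(self.level_sd[_kmer_index(kmer)])


def build_pore_model(
    k: int = 6,
    mod_shift: float = 1.0,
    seed: int = 0,
    *,
    dwell_mean: float = 10.0,
    stride: int = 5,
    sd_range: tuple[float, float] = (0.35, 0.65),
    levels: str = "normal",
) -> PoreModel:
    """Draw a reproducible random pore model.

    With ``levels="normal"`` current levels are standard-normal per k-mer, so
    distinct k-mers may collide (as they do in real pores); ``levels="spaced"``
    places them on an even grid over [-2, 2], guaranteeing every k-mer is
    resolvable from its mean level.  Noise scales are uniform in ``sd_range``.
    The default ``mod_shift`` of 1.0 is twice the mean noise scale, i.e. a
    clearly but not trivially separable modification effect.
    """
    if k < 1:
        raise ValueError(f"k-mer length must be >= 1, got {k}")
    if levels not in ("normal", "spaced"):
        raise ValueError(f"unknown level mode {levels!r}")
    rng = np.random.default_rng(seed)
    n = 4**k
    if levels == "spaced":
        level_mean = np.linspace(-2.0, 2.0, n)
    else:
        level_mean = rng.normal(0.0, 1.0, size=n)
    return PoreModel(
        k=k,
        level_mean=level_mean,
        level_sd=rng.uniform(*sd_range, size=n),
        mod_shift=mod_shift,
        dwell_mean=dwell_mean,
        stride=stride,
    )


@dataclass
class MethylationTruth:
    """Ground-truth methylation frequency per CpG cytosine, per strand."""

    contig: str
    sites: list[tuple[int, str, float]] = field(default_factory=list)
    _lookup: dict[tuple[int, str], float] = field(default_factory=dict, repr=False)

    def add(self, position: int, strand: str, frequency: float) -> None:
        if not 0.0 <= frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")
        self.sites.append((position, strand, frequency))
        self._lookup[(position, strand)] = frequency

    def frequency(self, position: int, strand: str) -> float | None:
        return self._lookup.get((position, strand))


@dataclass
class SimConfig:
    """All knobs of a simulation run; the seed fixes every random draw."""

    contig: str = "sim1"
    reference_length: int = 20_000
    n_islands: int = 4
    island_length: int = 600
    island_obs_exp: float = 0.8     # CpG observed/expected inside islands
    background_obs_exp: float = 0.2
    island_gc: float = 0.6
    read_count: int = 200
    read_length_mean: float = 2_000.0
    read_length_sd: float = 400.0
    p_substitution: float = 0.01
    p_insertion: float = 0.005
    p_deletion: float = 0.005
    wgbs_mean_coverage: float = 30.0
    bisulfite_error: float = 0.005
    # mixture weights over {frequency 0, frequency 1, partial} per CpG
    truth_weights: tuple[float, float, float] = (0.2, 0.7, 0.1)
    island_truth_weights: tuple[float, float, float] = (0.8, 0.1, 0.1)
    partial_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_substitution", "p_insertion", "p_deletion", "bisulfite_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("truth_weights", "island_truth_weights"):
            w = getattr(self, name)
            if any(x < 0 for x in w) or not np.isclose(sum(w), 1.0):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if self.reference_length < 64:
            raise ValueError("reference too short to be useful")


def _sample_base(rng: np.random.Generator, prev: str, gc: float, p_g_after_c: float) -> str:
    """One Markov step: GC content `gc`, CG dinucleotide rate via p_g_after_c."""
    p_at = (1.0 - gc) / 2.0
    p_cg = gc / 2.0
    probs = np.array([p_at, p_cg, p_cg, p_at])
    if prev == "C":
        # reassign G mass to hit the requested P(G | C)
        others = probs.copy()
        others[2] = 0.0
        others = others / others.sum() * (1.0 - p_g_after_c)
        probs = others
        probs[2] = p_g_after_c
    return _BASES[rng.choice(4, p=probs)]


def simulate_reference(config: SimConfig) -> tuple[str, MethylationTruth]:
    """Generate a reference with planted CpG islands and per-CpG truth.

    Island CpGs default to mostly-unmethylated, background CpGs to
    mostly-methylated, mirroring vertebrate methylomes.  Both strands of each
    CpG receive the same frequency (symmetric maintenance methylation).
    """
    rng = np.random.default_rng(config.seed)
    n = config.reference_length

    island_mask = np.zeros(n, dtype=bool)
    if config.n_islands > 0 and config.island_length < n:
        gap = n // (config.n_islands + 1)
        for i in range(config.n_islands):
            start = gap * (i + 1) - config.island_length // 2
            start = max(0, min(start, n - config.island_length))
            island_mask[start : start + config.island_length] = True

    # with uniform-ish base composition, expected CG freq per position is
    # (gc/2)^2 / ... ; the Markov P(G|C) that realises obs/exp t is t * gc/2
    bases = []
    prev = "A"
    for i in range(n):
        if island_mask[i]:
            gc, oe = config.island_gc, config.island_obs_exp
        else:
            gc, oe = 0.5, config.background_obs_exp
        p_g_after_c = min(1.0, oe * gc / 2.0)
        prev = _sample_base(rng, prev, gc, p_g_after_c)
        bases.append(prev)
    sequence = "".join(bases)

    truth = MethylationTruth(contig=config.contig)
    pos = sequence.find("CG")
    while pos != -1:
        weights = config.island_truth_weights if island_mask[pos] else config.truth_weights
        comp = rng.choice(3, p=np.asarray(weights))
        if comp == 0:
            freq = 0.0
        elif comp == 1:
            freq = 1.0
        else:
            freq = float(rng.uniform(*config.partial_range))
        truth.add(pos, "+", freq)
        truth.add(pos + 1, "-", freq)
        pos = sequence.find("CG", pos + 1)
    return sequence, truth


def _context_kmer(seq: str, center: int, k: int) -> str:
    """k-mer around `center` (left-biased for even k), padded with A at edges."""
    start = center - (k - 1) // 2
    chars = []
    for j in range(start, start + k):
        chars.append(seq[j] if 0 <= j < len(seq) else "A")
    return "".join(chars)


def simulate_read(
    reference: str,
    truth: MethylationTruth,
    pore: PoreModel,
    config: SimConfig,
    seed: int,
    *,
    read_id: str | None = None,
    start: int | None = None,
    length: int | None = None,
    strand: str | None = None,
) -> ReadBundle:
    """Simulate one read over a reference interval.

    Per-CpG methylation state is Bernoulli in the truth frequency; the level
    shift is applied to every k-mer overlapping a methylated cytosine, making
    the surrounding sequence context informative.  Basecalling errors
    (substitutions and single-base indels) are injected at the configured
    rates and the emitted CIGAR reflects them exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(reference)
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    if length is None:
        length = int(np.clip(rng.normal(config.read_length_mean, config.read_length_sd), 50, n))
    if start is None:
        start = int(rng.integers(0, max(1, n - length + 1)))
    end = min(n, start + length)
    if end <= start:
        raise ValueError("empty read interval")

    ref_span = reference[start:end]
    template = ref_span if strand == "+" else revcomp(ref_span)
    tlen = len(template)

    # methylation state per template (read-orientation) position
    meth = np.zeros(tlen, dtype=bool)
    for i in range(tlen):
        if template[i] != "C":
            continue
        ref_pos = start + i if strand == "+" else end - 1 - i
        freq = truth.frequency(ref_pos, strand)
        if freq is not None:
            meth[i] = rng.random() < freq

    # basecalls with errors; each emitted base keeps a template anchor index
    calls: list[str] = []
    anchors: list[int] = []          # template index; -1 for insertions
    ops: list[str] = []              # read-orientation CIGAR ops
    for j in range(tlen):
        if rng.random() < config.p_deletion and tlen > 1:
            ops.append("D")
            continue
        base = template[j]
        if rng.random() < config.p_substitution:
            base = _BASES[(_BASE_TO_INT[base] + int(rng.integers(1, 4))) % 4]
        calls.append(base)
        anchors.append(j)
        ops.append("M")
        if rng.random() < config.p_insertion:
            calls.append(_BASES[int(rng.integers(0, 4))])
            anchors.append(-1)
            ops.append("I")
    if not calls:  # degenerate all-deleted read
        calls, anchors, ops = [template[0]], [0], ["M"]

    basecalls = "".join(calls)
    n_bases = len(basecalls)

    # dwell in strides: shifted geometric with mean dwell_mean / stride
    mean_strides = max(1.0, pore.dwell_mean / pore.stride)
    dwell = rng.geometric(1.0 / mean_strides, size=n_bases)

    # signal: per emitted base, dwell*stride Gaussian samples around the level
    # of the anchoring template k-mer (insertions reuse the previous anchor)
    moves = np.zeros(int(dwell.sum()), dtype=np.int8)
    signal = np.empty(int(dwell.sum()) * pore.stride, dtype=np.float64)
    step = 0
    prev_anchor = 0
    for i in range(n_bases):
        anchor = anchors[i] if anchors[i] >= 0 else prev_anchor
        prev_anchor = anchor
        kmer = _context_kmer(template, anchor, pore.k)
        k_start = anchor - (pore.k - 1) // 2
        methylated = bool(meth[max(0, k_start) : min(tlen, k_start + pore.k)].any())
        level = pore.level(kmer, methylated)
        sd = pore.sd(kmer)
        n_samp = int(dwell[i]) * pore.stride
        signal[step * pore.stride : step * pore.stride + n_samp] = rng.normal(level, sd, n_samp)
        moves[step] = 1
        step += int(dwell[i])

    cigar = _collapse_cigar(ops if strand == "+" else ops[::-1])
    alignment = Alignment(contig=truth.contig, start=start, strand=strand, cigar=cigar, mapq=60)
    return ReadBundle(
        read_id=read_id or f"read_{seed}",
        signal=signal,
        stride=pore.stride,
        moves=moves,
        sequence=basecalls,
        alignment=alignment,
    )


def _collapse_cigar(ops: list[str]) -> str:
    parts = []
    run, prev = 0, None
    for op in ops:
        if op == prev:
            run += 1
        else:
            if prev is not None:
                parts.append(f"{run}{prev}")
            run, prev = 1, op
    parts.append(f"{run}{prev}")
    return "".join(parts)


def simulate_wgbs(
    truth: MethylationTruth, config: SimConfig, seed: int
) -> list[WgbsRecord]:
    """Binomially sampled bisulfite coverage matching the truth.

    Coverage is Poisson around the configured mean; methylated counts are
    binomial with the conversion-error-adjusted probability
    ``f (1 - eps) + (1 - f) eps``.  Sites drawing zero coverage produce no
    record, as in real Bismark coverage output.
    """
    if config.wgbs_mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    rng = np.random.default_rng(seed)
    eps = config.bisulfite_error
    records = []
    for position, strand, freq in truth.sites:
        cov = int(rng.poisson(config.wgbs_mean_coverage))
        if cov == 0:
            continue
        p = float(np.clip(freq * (1.0 - eps) + (1.0 - freq) * eps, 0.0, 1.0))
        n_meth = int(rng.binomial(cov, p))
        records.append(
            WgbsRecord(
                contig=truth.contig,
                position=position,
                n_meth=n_meth,
                n_unmeth=cov - n_meth,
                strand=strand,
            )
        )
    return records
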