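"""Per-CpG feature extraction from read bundles.

Each CpG instance becomes a :class:`~squigmeth.types.SiteExample`: a length-l
token window centred on the assayed cytosine, the signal blocks whose
anchoring base falls inside that window, and window-relative reference/query
indices used as positional encodings.

Two anchoring modes exist.  *Reference-anchored* (R9-style) windows are cut
from the aligned reference via the CIGAR string; *basecall-anchored*
(R10-style) windows come straight from the basecalled sequence and need no
alignment.  Features are always built in read orientation: for a
minus-strand site the window is the reverse complement of the forward
reference, so the assayed C sits at index l//2 followed by G.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from math import ceil

import numpy as np

from .simulator import revcomp
from .types import ReadBundle, SiteExample

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "TOKEN_IDS",
    "UNK",
    "MASK",
    "encode_tokens",
    "signal_to_base_index",
    "reference_query_mapping",
    "find_cpg_sites",
    "normalize_signal",
    "extract_examples",
]

# token vocabulary: four bases, [UNK] for non-canonical, [MASK] for training
TOKEN_IDS = {"A": 0, "C": 1, "G": 2, "T": 3}
UNK = 4
MASK = 5


def encode_tokens(window: str) -> np.ndarray:
    return np.array([TOKEN_IDS.get(ch, UNK) for ch in window.upper()], dtype=np.int64)


@dataclass
class FeatureConfig:
    """Extraction parameters.

    ``window`` is the subsequence length l (odd, default 31); ``block_width``
    b is fixed by the basecaller stride (5 for 4 kHz super-accurate models,
    6 for 5 kHz).  Examples whose block count falls outside
    ``[ceil(min_blocks_per_base * l), max_blocks_per_base * l]`` are
    discarded, interpreting the block-count quality filter per window base.
    """

    window: int = 31
    block_width: int = 5
    min_blocks_per_base: float = 0.5
    max_blocks_per_base: float = 5.0
    mode: str = "reference"  # "reference" (R9-style) or "basecall" (R10-style)
    min_mapq: int = 60

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window length must be odd and >= 3")
        if self.block_width < 1:
            raise ValueError("block width must be >= 1")
        if self.mode not in ("reference", "basecall"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def min_blocks(self) -> int:
        return ceil(self.min_blocks_per_base * self.window)

    @property
    def max_blocks(self) -> int:
        return int(self.max_blocks_per_base * self.window)


def signal_to_base_index(moves: np.ndarray, stride: int | None = None) -> np.ndarray:
    """Index of the basecalled base each move-table step belongs to.

    The move table marks, per ``stride`` raw samples, whether a new base
    begins; a step's samples belong to the most recent base started, i.e.
    ``cumsum(moves) - 1``.
    """
    moves = np.asarray(moves)
    if len(moves) == 0 or moves[0] != 1:
        raise ValueError("move table must start with 1")
    return np.cumsum(moves, dtype=np.int64) - 1


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def reference_query_mapping(cigar: str, ref_start: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-query-base reference coordinates from a CIGAR string.

    Returns ``(ref_coord, unaligned)`` arrays over the full query (SAM
    orientation).  Aligned bases (M/=/X) get their reference coordinate;
    inserted and soft-clipped bases carry the previous aligned coordinate and
    are flagged in ``unaligned``; deletions advance the reference only.
    """
    consumed = sum(len(m.group(0)) for m in _CIGAR_RE.finditer(cigar))
    if consumed != len(cigar) or not cigar:
        raise ValueError(f"invalid CIGAR string {cigar!r}")
    ref_coords: list[int] = []
    flags: list[bool] = []
    ref = ref_start
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in "M=X":
            ref_coords.extend(range(ref, ref + n))
            flags.extend([False] * n)
            ref += n
        elif op in "IS":
            prev = ref_coords[-1] if ref_coords else ref - 1
            ref_coords.extend([prev] * n)
            flags.extend([True] * n)
        elif op in "DN":
            ref += n
        # H and P consume nothing on the query
    return np.asarray(ref_coords, dtype=np.int64), np.asarray(flags, dtype=bool)


def find_cpg_sites(sequence: str) -> list[tuple[int, str]]:
    """All CpG cytosines in ``sequence``, both strands.

    Forward hits are the C of each ``CG``; the reverse-strand C of the same
    dinucleotide is reported at the G's index with strand ``"-"``.
    """
    seq = sequence.upper()
    sites = []
    pos = seq.find("CG")
    while pos != -1:
        sites.append((pos, "+"))
        sites.append((pos + 1, "-"))
        pos = seq.find("CG", pos + 1)
    return sites


def normalize_signal(signal: np.ndarray) -> np.ndarray:
    """Per-read robust normalization: (x - median) / (1.4826 * MAD).

    Falls back to the standard deviation when the MAD is zero; a constant
    signal normalizes to all zeros.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("cannot normalize an empty signal")
    med = np.median(signal)
    scale = 1.4826 * np.median(np.abs(signal - med))
    if scale == 0.0:
        scale = float(np.std(signal))
    if scale == 0.0:
        return np.zeros_like(signal)
    return (signal - med) / scale


def _clip_window(idx: np.ndarray, window: int) -> np.ndarray:
    return np.clip(idx, 0, window - 1)


def extract_examples(
    bundle: ReadBundle,
    reference: str | None,
    config: FeatureConfig,
    *,
    stats: dict | None = None,
) -> list[SiteExample]:
    """All CpG site examples of one read.

    Windows overlapping the ends of the anchoring sequence are dropped, as
    are examples failing the block-count filter (counted in
    ``stats["filtered_blocks"]``).  Reference-anchored mode skips reads
    without an alignment of sufficient mapping quality.
    """
    if stats is None:
        stats = {}
    for key in ("emitted", "filtered_blocks", "window_overflow", "skipped_reads"):
        stats.setdefault(key, 0)

    l = config.window
    half = l // 2
    aln = bundle.alignment

    if config.mode == "reference":
        if aln is None or reference is None:
            logger.warning("read %s: no alignment/reference for reference-anchored mode", bundle.read_id)
            stats["skipped_reads"] += 1
            return []
        if aln.mapq < config.min_mapq:
            stats["skipped_reads"] += 1
            return []

    norm = normalize_signal(bundle.signal)
    base_index = signal_to_base_index(bundle.moves)  # per-step query base, read orientation
    n_steps = len(base_index)
    blocks_all = norm[: n_steps * bundle.stride].reshape(n_steps, bundle.stride)
    n_query = len(bundle.sequence)

    sam_ref = sam_flags = None
    ref_span = (0, 0)
    if aln is not None:
        sam_ref, sam_flags = reference_query_mapping(aln.cigar, aln.start)
        if len(sam_ref):
            ref_span = (aln.start, int(sam_ref.max()) + 1)

    def to_sam_query(q: int) -> int:
        return q if aln.strand == "+" else n_query - 1 - q

    examples: list[SiteExample] = []

    if config.mode == "basecall":
        anchoring = bundle.sequence
        # a read assays the CpGs of its own strand: forward hits only
        site_positions = [p for p, strand in find_cpg_sites(anchoring) if strand == "+"]
        step_anchor = base_index  # anchor steps by query base
        for c in site_positions:
            if c - half < 0 or c + half >= len(anchoring):
                stats["window_overflow"] += 1
                continue
            lo = int(np.searchsorted(step_anchor, c - half, side="left"))
            hi = int(np.searchsorted(step_anchor, c + half, side="right"))
            s = hi - lo
            if not (config.min_blocks <= s <= config.max_blocks):
                stats["filtered_blocks"] += 1
                continue
            q_rel = _clip_window(step_anchor[lo:hi] - (c - half), l)
            contig, position, strand = "*", c, "+"
            if aln is not None and sam_ref is not None:
                sq = to_sam_query(c)
                if sam_flags[sq]:
                    stats["window_overflow"] += 1
                    continue  # inserted base: no genomic anchor
                contig = aln.contig
                position = int(sam_ref[sq])
                strand = aln.strand
            examples.append(
                SiteExample(
                    read_id=bundle.read_id,
                    contig=contig,
                    position=position,
                    strand=strand,
                    tokens=encode_tokens(anchoring[c - half : c + half + 1]),
                    blocks=blocks_all[lo:hi].copy(),
                    ref_idx=q_rel.copy(),
                    query_idx=q_rel,
                )
            )
            stats["emitted"] += 1
        return examples

    # reference-anchored mode -------------------------------------------------
    start, end = aln.start, ref_span[1]
    if end <= start:
        stats["skipped_reads"] += 1
        return []
    ref_fwd = reference[start:end]
    read_ref = ref_fwd if aln.strand == "+" else revcomp(ref_fwd)
    span = end - start

    # per-step anchor in read-oriented reference offsets (nondecreasing)
    q_of_step = base_index
    if aln.strand == "+":
        t_of_step = sam_ref[q_of_step] - start
    else:
        t_of_step = (end - 1) - sam_ref[n_query - 1 - q_of_step]

    site_positions = [p for p, strand in find_cpg_sites(read_ref) if strand == "+"]
    for c in site_positions:
        if c - half < 0 or c + half >= span:
            stats["window_overflow"] += 1
            continue
        lo = int(np.searchsorted(t_of_step, c - half, side="left"))
        hi = int(np.searchsorted(t_of_step, c + half, side="right"))
        s = hi - lo
        if not (config.min_blocks <= s <= config.max_blocks):
            stats["filtered_blocks"] += 1
            continue
        r_rel = _clip_window(t_of_step[lo:hi] - (c - half), l)
        q_window = q_of_step[lo:hi]
        q_rel = _clip_window(q_window - int(q_window[0]), l)
        position = start + c if aln.strand == "+" else end - 1 - c
        examples.append(
            SiteExample(
                read_id=bundle.read_id,
                contig=aln.contig,
                position=position,
                strand=aln.strand,
                tokens=encode_tokens(read_ref[c - half : c + half + 1]),
                blocks=blocks_all[lo:hi].copy(),
                ref_idx=r_rel,
                query_idx=q_rel,
            )
        )
        stats["emitted"] += 1
    return examples
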