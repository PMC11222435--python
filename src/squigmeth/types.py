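"""Core domain objects shared across the pipeline.

Coordinate convention: internally everything is 0-based, half-open, on the
forward strand of the reference.  A minus-strand CpG call is reported at the
forward-strand coordinate of its own cytosine (the G position of the forward
CpG) with strand ``"-"``.  The only 1-based boundary is Bismark coverage I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alignment",
    "ReadBundle",
    "SiteExample",
    "ReadCall",
    "SiteRecord",
    "WgbsRecord",
    "AnnotationTrack",
]


@dataclass
class Alignment:
    """Reference placement of a read (SAM conventions, 0-based start)."""

    contig: str
    start: int
    strand: str  # "+" or "-"
    cigar: str
    mapq: int = 60


@dataclass
class ReadBundle:
    """One sequenced read: raw signal, move table and basecalls.

    ``sequence`` is stored in read (signal) orientation.  The move table has
    one 0/1 entry per ``stride`` raw samples; entry ``1`` marks the first
    stride of a new base, so ``sum(moves) == len(sequence)`` and
    ``len(signal) == stride * len(moves)``.
    """

    read_id: str
    signal: np.ndarray
    stride: int
    moves: np.ndarray
    sequence: str
    alignment: Alignment | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if the bundle is sound)."""
        problems = []
        if len(self.moves) == 0 or self.moves[0] != 1:
            problems.append("moves[0] must be 1")
        if int(np.sum(self.moves)) != len(self.sequence):
            problems.append(
                f"sum(moves)={int(np.sum(self.moves))} != basecall length {len(self.sequence)}"
            )
        if len(self.signal) != self.stride * len(self.moves):
            problems.append(
                f"signal length {len(self.signal)} != stride*moves {self.stride * len(self.moves)}"
            )
        return problems


@dataclass
class SiteExample:
    """One CpG instance ready for the model.

    ``tokens`` is the length-``l`` window in read orientation with the assayed
    cytosine at index ``l // 2`` (followed by G).  ``blocks`` is the ``s x b``
    matrix of normalized signal samples; ``ref_idx`` / ``query_idx`` are the
    window-relative positional indices of each block (reference-anchored mode
    fills both, basecall-anchored mode duplicates the query index).
    """

    read_id: str
    contig: str
    position: int
    strand: str
    tokens: np.ndarray          # (l,) int token ids
    blocks: np.ndarray          # (s, b) float
    ref_idx: np.ndarray         # (s,) int
    query_idx: np.ndarray       # (s,) int
    label: float | None = None  # hard {0,1} or soft in [0,1]


@dataclass
class ReadCall:
    """Per-read, per-site modification probability."""

    read_id: str
    contig: str
    position: int
    strand: str
    probability: float


@dataclass
class SiteRecord:
    """Strand-specific per-site aggregate over read calls."""

    contig: str
    position: int
    strand: str
    coverage: int
    n_mod: int

    @property
    def frequency(self) -> float:
        return self.n_mod / self.coverage if self.coverage else float("nan")


@dataclass
class WgbsRecord:
    """One bisulfite site (Bismark coverage dialect, converted to 0-based)."""

    contig: str
    position: int
    n_meth: int
    n_unmeth: int
    strand: str | None = None

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def frequency(self) -> float:
        total = self.coverage
        return self.n_meth / total if total else float("nan")


@dataclass
class AnnotationTrack:
    """Named interval set, 0-based half-open, sorted per contig."""

    label: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    # intervals[contig] is an (n, 2) int array of [start, end) pairs
    strands: dict[str, list[str]] = field(default_factory=dict)

    def overlaps(self, contig: str, position: int) -> bool:
        ivs = self.intervals.get(contig)
        if ivs is None or len(ivs) == 0:
            return False
        i = int(np.searchsorted(ivs[:, 0], position, side="right")) - 1
        # sorted by start; earlier intervals may still cover `position`, so
        # scan back until starts drop below position - longest interval
        max_len = int(np.max(ivs[:, 1] - ivs[:, 0]))
        while i >= 0 and ivs[i, 0] > position - max_len:
            if ivs[i, 1] > position:
                return True
            i -= 1
        return False
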