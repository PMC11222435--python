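"""Readers and writers for every on-disk artifact the pipeline touches.

Two read-ingestion dialects are supported: a JSON-lines fixture format (one
read per line) and SAM text with the basecaller move table in an ``mv`` tag
plus a JSON-lines signal side file.  Coordinates are 0-based half-open
internally; Bismark coverage files are the single 1-based boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .simulator import revcomp
from .types import Alignment, AnnotationTrack, ReadBundle, ReadCall, SiteRecord, WgbsRecord

logger = logging.getLogger(__name__)

__all__ = [
    "load_read_bundles",
    "write_read_bundles_jsonl",
    "write_read_bundles_sam",
    "load_bismark_coverage",
    "write_bismark_coverage",
    "load_bed_track",
    "write_read_calls",
    "load_read_calls",
    "write_site_records",
    "load_site_records",
]


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# read bundles


def _bundle_to_json(bundle: ReadBundle) -> dict:
    d = {
        "id": bundle.read_id,
        "stride": bundle.stride,
        "moves": "".join(str(int(m)) for m in bundle.moves),
        "sequence": bundle.sequence,
        "signal": [float(x) for x in bundle.signal],
    }
    if bundle.alignment is not None:
        a = bundle.alignment
        d.update(contig=a.contig, start=a.start, strand=a.strand, cigar=a.cigar, mapq=a.mapq)
    return d


def _bundle_from_json(d: dict) -> ReadBundle:
    alignment = None
    if "contig" in d:
        alignment = Alignment(
            contig=d["contig"],
            start=int(d["start"]),
            strand=d["strand"],
            cigar=d["cigar"],
            mapq=int(d.get("mapq", 60)),
        )
    return ReadBundle(
        read_id=d["id"],
        signal=np.asarray(d["signal"], dtype=np.float64),
        stride=int(d["stride"]),
        moves=np.frombuffer(d["moves"].encode(), dtype=np.uint8) - ord("0"),
        sequence=d["sequence"],
        alignment=alignment,
    )


def write_read_bundles_jsonl(bundles: Iterable[ReadBundle], path: str | Path) -> None:
    with open(path, "w") as fh:
        for bundle in bundles:
            fh.write(json.dumps(_bundle_to_json(bundle)) + "\n")


def write_read_bundles_sam(
    bundles: Iterable[ReadBundle], sam_path: str | Path, signal_path: str | Path
) -> None:
    """SAM text dialect: move table in ``mv:B:c`` (stride first, basecaller
    convention), raw signal in a JSON-lines side file keyed by read id."""
    bundles = list(bundles)
    contigs: dict[str, int] = {}
    for b in bundles:
        if b.alignment is not None:
            # reference length unknown here; use a generous bound
            end = b.alignment.start + len(b.sequence) * 2
            contigs[b.alignment.contig] = max(contigs.get(b.alignment.contig, 0), end)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in sorted(contigs.items())],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam, open(
        signal_path, "w"
    ) as side:
        for b in bundles:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = b.read_id
            if b.alignment is None:
                rec.is_unmapped = True
                rec.query_sequence = b.sequence
            else:
                rec.reference_id = sam.header.get_tid(b.alignment.contig)
                rec.reference_start = b.alignment.start
                rec.cigarstring = b.alignment.cigar
                rec.mapping_quality = b.alignment.mapq
                rec.is_reverse = b.alignment.strand == "-"
                # SAM stores the query in reference orientation
                rec.query_sequence = (
                    b.sequence if b.alignment.strand == "+" else revcomp(b.sequence)
                )
            rec.set_tag("mv", [b.stride] + [int(m) for m in b.moves])
            sam.write(rec)
            side.write(
                json.dumps({"id": b.read_id, "signal": [float(x) for x in b.signal]})
                + "\n"
            )


def _iter_sam_bundles(sam_path: Path, signal_path: Path) -> Iterator[ReadBundle]:
    signals: dict[str, np.ndarray] = {}
    with open(signal_path) as fh:
        for line in fh:
            d = json.loads(line)
            signals[d["id"]] = np.asarray(d["signal"], dtype=np.float64)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            mv = rec.get_tag("mv")
            stride, moves = int(mv[0]), np.asarray(mv[1:], dtype=np.int8)
            if rec.is_unmapped:
                alignment, seq = None, rec.query_sequence
            else:
                strand = "-" if rec.is_reverse else "+"
                alignment = Alignment(
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    strand=strand,
                    cigar=rec.cigarstring,
                    mapq=rec.mapping_quality,
                )
                seq = rec.query_sequence if strand == "+" else revcomp(rec.query_sequence)
            yield ReadBundle(
                read_id=rec.query_name,
                signal=signals.get(rec.query_name, np.empty(0)),
                stride=stride,
                moves=moves,
                sequence=seq,
                alignment=alignment,
            )


def load_read_bundles(
    path: str | Path,
    dialect: str | None = None,
    *,
    signal_path: str | Path | None = None,
    strict: bool = False,
    stats: dict | None = None,
) -> Iterator[ReadBundle]:
    """Stream validated :class:`ReadBundle` objects from disk.

    Bundles violating the move-table invariants are skipped with a warning
    (``stats["skipped"]`` counts them) unless ``strict`` upgrades to an error.
    Dialect is sniffed from the extension when not given (.sam vs .jsonl).
    """
    path = Path(path)
    if dialect is None:
        dialect = "sam+signal" if path.suffix == ".sam" else "jsonl"
    if stats is None:
        stats = {}
    stats.setdefault("skipped", 0)
    stats.setdefault("loaded", 0)

    if dialect == "jsonl":
        def _iter() -> Iterator[ReadBundle]:
            with open(path) as fh:
                for lineno, line in enumerate(fh, 1):
                    if not line.strip():
                        continue
                    try:
                        yield _bundle_from_json(json.loads(line))
                    except (json.JSONDecodeError, KeyError) as exc:
                        raise FormatError(f"{path}:{lineno}: unparseable record: {exc}") from exc
        source = _iter()
    elif dialect == "sam+signal":
        side = Path(signal_path) if signal_path else path.with_suffix(".signal.jsonl")
        source = _iter_sam_bundles(path, side)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for bundle in source:
        problems = bundle.validate()
        if problems:
            if strict:
                raise FormatError(f"read {bundle.read_id}: {'; '.join(problems)}")
            logger.warning("skipping read %s: %s", bundle.read_id, "; ".join(problems))
            stats["skipped"] += 1
            continue
        stats["loaded"] += 1
        yield bundle


# ---------------------------------------------------------------------------
# Bismark coverage


def load_bismark_coverage(path: str | Path) -> list[WgbsRecord]:
    """Read a Bismark coverage file (6-column TSV, 1-based inclusive).

    The methylation-percentage column is ignored for arithmetic; frequency is
    always recomputed from the counts.  Zero-coverage records are retained
    (their frequency is NaN) and excluded by downstream filters.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            contig, start, _end, _pct, n_meth, n_unmeth = fields
            records.append(
                WgbsRecord(
                    contig=contig,
                    position=int(start) - 1,
                    n_meth=int(n_meth),
                    n_unmeth=int(n_unmeth),
                )
            )
    return records


def write_bismark_coverage(records: Iterable[WgbsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            total = r.coverage
            pct = 100.0 * r.n_meth / total if total else 0.0
            fh.write(
                f"{r.contig}\t{r.position + 1}\t{r.position + 1}\t{pct:.6g}\t{r.n_meth}\t{r.n_unmeth}\n"
            )


# ---------------------------------------------------------------------------
# BED tracks


def load_bed_track(path: str | Path, label: str) -> AnnotationTrack:
    """Load BED3/BED6 intervals; output is per-contig sorted by start."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            per_contig.setdefault(contig, []).append((start, end))
            strands.setdefault(contig, []).append(fields[5] if len(fields) >= 6 else ".")
    track = AnnotationTrack(label=label)
    for contig, ivs in per_contig.items():
        order = np.argsort([s for s, _ in ivs], kind="stable")
        track.intervals[contig] = np.asarray(ivs, dtype=np.int64)[order]
        track.strands[contig] = [strands[contig][i] for i in order]
    return track


# ---------------------------------------------------------------------------
# calls and sites (headered TSV, deterministic order)


def write_read_calls(calls: Iterable[ReadCall], path: str | Path) -> None:
    ordered = sorted(calls, key=lambda c: (c.contig, c.position, c.strand, c.read_id))
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tpos\tstrand\tprob\n")
        for c in ordered:
            fh.write(f"{c.read_id}\t{c.contig}\t{c.position}\t{c.strand}\t{c.probability:.6f}\n")


def load_read_calls(path: str | Path) -> list[ReadCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise FormatError(f"{path}: missing read-call header")
        for line in fh:
            read_id, contig, pos, strand, prob = line.rstrip("\n").split("\t")
            calls.append(ReadCall(read_id, contig, int(pos), strand, float(prob)))
    return calls


def write_site_records(sites: Iterable[SiteRecord], path: str | Path) -> None:
    ordered = sorted(sites, key=lambda s: (s.contig, s.position, s.strand))
    with open(path, "w") as fh:
        fh.write("contig\tpos\tstrand\tcoverage\tn_mod\tfrequency\n")
        for s in ordered:
            fh.write(
                f"{s.contig}\t{s.position}\t{s.strand}\t{s.coverage}\t{s.n_mod}\t{s.frequency:.6f}\n"
            )


def load_site_records(path: str | Path) -> list[SiteRecord]:
    sites = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise FormatError(f"{path}: missing site-record header")
        for line in fh:
            contig, pos, strand, cov, n_mod, _freq = line.rstrip("\n").split("\t")
            sites.append(SiteRecord(contig, int(pos), strand, int(cov), int(n_mod)))
    return sites
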