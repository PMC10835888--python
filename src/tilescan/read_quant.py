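"""Protospacer extraction from FASTQ and per-sample sgRNA quantification.

Reads from a pooled-screen amplicon run carry the guide cassette as
5'-flank + CACCG + 20-nt protospacer + GTTT + 3'-flank (the hU6 vector
backbone); the 20-mer between the anchors identifies the guide. Extraction
scans each read for the first anchor pair enclosing exactly 20 nt and
emits that 20-mer; quantification assigns emitted 20-mers to library
guides by exact match (optionally Hamming distance <= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import pysam

from .library_io import LibraryTable, LibraryValidationError, revcomp

FIVE_PRIME_ANCHOR = "CACCG"
THREE_PRIME_ANCHOR = "GTTT"


class FastqParseError(ValueError):
    pass


@dataclass
class ExtractionSummary:
    reads_seen: int = 0
    reads_extracted: int = 0
    reads_too_short: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_seen": self.reads_seen,
            "reads_extracted": self.reads_extracted,
            "reads_too_short": self.reads_too_short,
        }


@dataclass
class QuantSummary:
    assigned: int = 0
    ambiguous: int = 0
    unmatched: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"assigned": self.assigned, "ambiguous": self.ambiguous, "unmatched": self.unmatched}


def extract_from_sequence(
    seq: str,
    five_prime_anchor: str = FIVE_PRIME_ANCHOR,
    three_prime_anchor: str = THREE_PRIME_ANCHOR,
) -> Optional[str]:
    """Return the first 20-mer enclosed by the anchor pair, or None.

    Scans every occurrence of the 5' anchor and accepts the first one whose
    following 20 nt are immediately followed by the 3' anchor.
    """
    n5, n3 = len(five_prime_anchor), len(three_prime_anchor)
    start = 0
    while True:
        i = seq.find(five_prime_anchor, start)
        if i < 0:
            return None
        lo = i + n5
        hi = lo + 20
        if hi + n3 <= len(seq) and seq[hi : hi + n3] == three_prime_anchor:
            return seq[lo:hi]
        start = i + 1


def extract_protospacers(
    reads,
    five_prime_anchor: str = FIVE_PRIME_ANCHOR,
    three_prime_anchor: str = THREE_PRIME_ANCHOR,
    scan_revcomp: bool = False,
    summary: Optional[ExtractionSummary] = None,
) -> Iterator[str]:
    """Yield candidate 20-nt protospacers from FASTQ reads.

    `reads` is a path to a FASTQ/FASTQ.gz file or an iterable of sequence
    strings. At most one 20-mer is emitted per read (first valid anchor
    window wins). When `scan_revcomp` is set, the reverse complement is
    scanned if the forward orientation has no valid window. Pass an
    ExtractionSummary to collect reads_seen / reads_extracted tallies.
    """
    if not five_prime_anchor or not three_prime_anchor:
        raise ValueError("anchors must be nonempty")
    if summary is None:
        summary = ExtractionSummary()
    min_len = len(five_prime_anchor) + 20 + len(three_prime_anchor)
    for seq in _iter_sequences(reads):
        summary.reads_seen += 1
        if len(seq) < min_len:
            summary.reads_too_short += 1
            continue
        hit = extract_from_sequence(seq, five_prime_anchor, three_prime_anchor)
        if hit is None and scan_revcomp:
            hit = extract_from_sequence(revcomp(seq), five_prime_anchor, three_prime_anchor)
        if hit is not None:
            summary.reads_extracted += 1
            yield hit


def _iter_sequences(reads) -> Iterator[str]:
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        try:
            with pysam.FastxFile(str(reads)) as fh:
                for idx, rec in enumerate(fh):
                    if rec.sequence is None:
                        raise FastqParseError(f"record {idx}: missing sequence")
                    yield rec.sequence.upper()
        except OSError as exc:
            raise FastqParseError(f"cannot read FASTQ {reads}: {exc}") from exc
        return
    for seq in reads:
        yield str(seq).upper()


def _hamming1_neighbors(seq: str) -> Iterator[str]:
    for i, base in enumerate(seq):
        for alt in "ACGT":
            if alt != base:
                yield seq[:i] + alt + seq[i + 1 :]


def quantify(
    protospacers: Iterable[str],
    lib: LibraryTable,
    max_mismatch: int = 0,
    summary: Optional[QuantSummary] = None,
) -> pd.Series:
    """Assign extracted 20-mers to library guides; return per-guide counts.

    A 20-mer is assigned iff exactly one (unambiguous) library protospacer
    lies within `max_mismatch` of it; 20-mers matching zero or more than one
    guide are discarded and tallied. Returns a Series indexed by guide_id
    covering the full library (ambiguous guides get 0).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    matchable = lib.matchable_records()
    if not lib.records:
        raise LibraryValidationError("empty library")
    index = {r.protospacer: r.guide_id for r in matchable}
    counts = {r.guide_id: 0 for r in lib.records}
    if summary is None:
        summary = QuantSummary()
    for mer in protospacers:
        hits = set()
        gid = index.get(mer)
        if gid is not None:
            hits.add(gid)
        if max_mismatch == 1:
            for nb in _hamming1_neighbors(mer):
                g = index.get(nb)
                if g is not None:
                    hits.add(g)
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
            summary.assigned += 1
        elif len(hits) > 1:
            summary.ambiguous += 1
        else:
            summary.unmatched += 1
    return pd.Series(counts, name="count").reindex(lib.guide_ids())


def count_samples(
    fastq_by_sample: dict[str, object],
    lib: LibraryTable,
    max_mismatch: int = 0,
    scan_revcomp: bool = False,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Quantify several FASTQ files into a counts matrix (guides x samples).

    Returns (counts, per-sample summary dict with extraction and assignment
    tallies). Column sums equal each sample's total matched reads.
    """
    columns = {}
    summaries: dict[str, dict[str, int]] = {}
    for sample, path in fastq_by_sample.items():
        ext = ExtractionSummary()
        q = QuantSummary()
        stream = extract_protospacers(path, scan_revcomp=scan_revcomp, summary=ext)
        columns[sample] = quantify(stream, lib, max_mismatch=max_mismatch, summary=q)
        summaries[sample] = {**ext.as_dict(), **q.as_dict()}
    counts = pd.DataFrame(columns)
    counts.index.name = "guide_id"
    return counts, summaries


def total_matched(counts: pd.DataFrame) -> pd.Series:
    return counts.sum(axis=0)


def frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample guide frequencies: counts divided by total matched reads.

    Every column of the result sums to 1. A sample with zero matched reads
    is an error (frequency undefined).
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero matched reads: {list(zero.index)}")
    return counts / totals
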