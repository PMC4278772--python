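"""Demultiplexing and trimming of multiplexed PAT-seq reads.

Each raw read carries, in order: a sample barcode, a fixed 5' adapter, the
tag proper (the sequence that will be aligned to the extended-UTR database,
ending at the mRNA-poly(A) junction), a residual oligo-dT remnant that
appears as a terminal homopolymer A-run, and a fragment of the 3' sequencing
adapter.  Demultiplexing assigns reads to samples by their barcode and strips
it; trimming removes both adapters and the A-run remnant, leaving the bare
tag.

Trimming rules (declared defaults; no particular
trimming software or thresholds are assumed):

* 5' adapter: removed by prefix match, tolerating ``adapter_mismatch``
  substitutions (default 1).
* 3' adapter: the leftmost full occurrence is removed, or failing that a
  read-terminal prefix of the adapter of length >= 4.
* oligo-dT remnant: the maximal terminal run of ``A`` with at most one non-A
  interruption is stripped, but only if it contains at least ``a_min`` = 5
  A's; this separates the remnant from genuinely A-rich 3' sequence.
* results shorter than ``min_len`` (default 20 nt) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError

UNASSIGNED = "unassigned"


@dataclass
class TagRead:
    """A read (or trimmed tag) with its sample assignment."""

    read_id: str
    sample: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ConfigurationError(
                f"{self.read_id}: sequence and qualities differ in length"
            )


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count between equal-length strings, early exit past limit."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    barcode_table: Mapping[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[TagRead]], list[TagRead]]:
    """Split reads by barcode; the barcode is removed from assigned reads.

    A read is assigned to the *unique* sample whose barcode is within
    ``max_mismatch`` of the read's leading bases; equidistant ties and reads
    matching no barcode go to the unassigned set (barcode retained there).
    Every input read appears in exactly one output set.
    """
    barcodes = dict(barcode_table)
    if not barcodes:
        raise ConfigurationError("empty barcode table")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ConfigurationError("barcodes must be equal length")
    if len(set(barcodes.values())) != len(barcodes):
        raise ConfigurationError("duplicate barcodes")
    blen = lengths.pop()
    if max_mismatch >= blen:
        raise ConfigurationError("max_mismatch must be < barcode length")

    exact = {b: s for s, b in barcodes.items()}
    assigned: dict[str, list[TagRead]] = {s: [] for s in barcodes}
    unassigned: list[TagRead] = []
    items = list(barcodes.items())

    for read_id, seq, qual in reads:
        lead = seq[:blen]
        sample = exact.get(lead)
        if sample is None and max_mismatch > 0 and len(lead) == blen:
            best, best_d, ties = None, max_mismatch + 1, 0
            for s, b in items:
                d = _hamming(lead, b, max_mismatch)
                if d < best_d:
                    best, best_d, ties = s, d, 1
                elif d == best_d:
                    ties += 1
            if best_d <= max_mismatch and ties == 1:
                sample = best
        if sample is None:
            unassigned.append(TagRead(read_id, UNASSIGNED, seq, qual))
        else:
            assigned[sample].append(TagRead(read_id, sample, seq[blen:], qual[blen:]))
    return assigned, unassigned


def _strip_terminal_a_run(seq: str, a_min: int) -> str:
    """Strip the maximal terminal A-run with <= 1 non-A interruption.

    The contiguous terminal A block may be extended through a single non-A
    base (a sequencing error inside the remnant), but only when at least two
    A's flank the interruption on its 5' side — a lone A there is treated as
    genuine tag sequence.  The run is removed only if it contains at least
    ``a_min`` A's in total.
    """
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    terminal = n - i
    if terminal == 0:
        return seq
    cut = i
    total = terminal
    if i >= 3 and seq[i - 1] != "A":
        j = i - 1
        k = 0
        while j - 1 - k >= 0 and seq[j - 1 - k] == "A":
            k += 1
        if k >= 2:
            cut = j - k
            total += k
    if total >= a_min:
        return seq[:cut]
    return seq


def trim_tag(
    sequence: str,
    adapter_5p: str,
    adapter_3p: str,
    min_len: int = 20,
    a_min: int = 5,
    adapter_mismatch: int = 1,
    min_3p_overlap: int = 4,
) -> str | None:
    """Trim a demultiplexed read down to the bare tag.

    Returns the trimmed tag, or ``None`` if the result is shorter than
    ``min_len`` (the read is discarded).
    """
    if not adapter_5p or not adapter_3p:
        raise ConfigurationError("adapters must be non-empty")
    seq = sequence
    if len(seq) >= len(adapter_5p) and (
        _hamming(seq[: len(adapter_5p)], adapter_5p, adapter_mismatch)
        <= adapter_mismatch
    ):
        seq = seq[len(adapter_5p):]
    pos = seq.find(adapter_3p)
    if pos >= 0:
        seq = seq[:pos]
    else:
        # read-terminal partial adapter
        max_k = min(len(adapter_3p) - 1, len(seq))
        for k in range(max_k, min_3p_overlap - 1, -1):
            if seq.endswith(adapter_3p[:k]):
                seq = seq[: len(seq) - k]
                break
    seq = _strip_terminal_a_run(seq, a_min)
    if len(seq) < min_len:
        return None
    return seq


def trim_reads(
    reads: Iterable[TagRead],
    adapter_5p: str,
    adapter_3p: str,
    min_len: int = 20,
    a_min: int = 5,
    adapter_mismatch: int = 1,
) -> tuple[list[TagRead], int]:
    """Trim a batch of reads; returns (kept tags, number discarded)."""
    kept: list[TagRead] = []
    discarded = 0
    for read in reads:
        tag = trim_tag(
            read.sequence,
            adapter_5p,
            adapter_3p,
            min_len=min_len,
            a_min=a_min,
            adapter_mismatch=adapter_mismatch,
        )
        if tag is None:
            discarded += 1
        else:
            kept.append(
                TagRead(read.read_id, read.sample, tag, read.qualities[: len(tag)])
            )
    return kept, discarded


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(reads: Iterable[TagRead | tuple[str, str, str]], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            if isinstance(read, TagRead):
                rid, seq, qual = read.read_id, read.sequence, read.qualities
            else:
                rid, seq, qual = read
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_demux_report(
    counts: Mapping[str, int], n_unassigned: int, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tread_count\n")
        for sample in sorted(counts):
            fh.write(f"{sample}\t{counts[sample]}\n")
        fh.write(f"{UNASSIGNED}\t{n_unassigned}\n")
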