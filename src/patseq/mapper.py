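"""Tag alignment against the extended-UTR database and site profiling.

Alignment is an exact k-mer seed (k = 16) followed by full-length,
ungapped verification allowing at most ``max_mismatch`` substitutions
(default 2).  Seeds are taken at offsets 0, k, 2k, ... so that any alignment
with <= max_mismatch substitutions is guaranteed to share at least one exact
seed with the reference (pigeonhole).  A tag maps if it has a unique
lowest-mismatch location; ties across distinct locations are reported as
multimapped and excluded from profiles, which also resolves tags falling in
regions where two extended records overlap.

The cleavage (junction) coordinate of a mapped tag is the database position
of the tag base adjacent to the removed poly(A) remnant, i.e. the *last*
aligned base; :class:`TagHit` carries both the database position and the
genomic coordinate obtained through the record's coordinate map.

Per-gene, per-sample site profiles cluster raw junction positions by
single-linkage with a window ``w`` (default 24 nt, the typical scale of
cleavage microheterogeneity): positions within ``w`` of any cluster member
join that cluster.  Each cluster is represented by its modal position and the
usage vector is the vector of cluster counts divided by the gene total.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .errors import ConfigurationError
from .refdb import ExtendedUtrRecord

MAPPED = "mapped"
UNMAPPED = "unmapped"
MULTIMAPPED = "multimapped"


@dataclass(frozen=True)
class TagHit:
    """A uniquely mapped tag and its junction coordinate."""

    read_id: str
    gene_id: str
    db_start: int
    db_junction: int
    length: int
    mismatches: int
    chromosome: str
    genomic_junction: int
    strand: str


class TagIndex:
    """Exact k-mer index over database records, with mismatch verification."""

    def __init__(self, records: Sequence[ExtendedUtrRecord], k: int = 16):
        if k < 4:
            raise ConfigurationError("seed length k must be >= 4")
        self.k = k
        self.records = list(records)
        index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ridx, rec in enumerate(self.records):
            seq = rec.db_sequence
            for pos in range(len(seq) - k + 1):
                index[seq[pos: pos + k]].append((ridx, pos))
        self._index = dict(index)

    def _verify(self, tag: str, ridx: int, start: int, limit: int) -> int:
        """Hamming distance of tag vs record slice, early exit past limit."""
        seq = self.records[ridx].db_sequence
        window = seq[start: start + len(tag)]
        if window == tag:
            return 0
        d = 0
        for a, b in zip(window, tag):
            if a != b:
                d += 1
                if d > limit:
                    return d
        return d

    def map_tag(
        self, tag: str, max_mismatch: int = 2, read_id: str = ""
    ) -> tuple[str, TagHit | None]:
        """Map one tag; returns (status, hit) with hit only when mapped."""
        k = self.k
        if len(tag) < k:
            return UNMAPPED, None

        # fast path: an exact alignment must share the first seed exactly
        first = self._index.get(tag[:k])
        if first:
            exact = [
                (ridx, pos)
                for ridx, pos in first
                if self.records[ridx].db_sequence[pos: pos + len(tag)] == tag
            ]
            if len(exact) == 1:
                return MAPPED, self._make_hit(read_id, tag, *exact[0], 0)
            if len(exact) > 1:
                return MULTIMAPPED, None

        # slow path: seeds at non-overlapping offsets cover <= max_mismatch errors
        candidates: set[tuple[int, int]] = set()
        n_seeds = max_mismatch + 1
        for i in range(n_seeds):
            off = i * k
            if off + k > len(tag):
                break
            for ridx, pos in self._index.get(tag[off: off + k], ()):
                start = pos - off
                rec_len = len(self.records[ridx].db_sequence)
                if start >= 0 and start + len(tag) <= rec_len:
                    candidates.add((ridx, start))
        best_d = max_mismatch + 1
        best: list[tuple[int, int]] = []
        for ridx, start in candidates:
            d = self._verify(tag, ridx, start, max_mismatch)
            if d < best_d:
                best_d, best = d, [(ridx, start)]
            elif d == best_d:
                best.append((ridx, start))
        if best_d > max_mismatch or not best:
            return UNMAPPED, None
        if len(best) > 1:
            return MULTIMAPPED, None
        return MAPPED, self._make_hit(read_id, tag, *best[0], best_d)

    def _make_hit(
        self, read_id: str, tag: str, ridx: int, start: int, mismatches: int
    ) -> TagHit:
        rec = self.records[ridx]
        junction = start + len(tag) - 1
        chrom, gpos, strand = rec.db_to_genome(junction)
        return TagHit(
            read_id=read_id,
            gene_id=rec.gene_id,
            db_start=start,
            db_junction=junction,
            length=len(tag),
            mismatches=mismatches,
            chromosome=chrom,
            genomic_junction=gpos,
            strand=strand,
        )

    def map_tags(
        self, tags: Iterable[tuple[str, str]], max_mismatch: int = 2
    ) -> tuple[list[TagHit], Counter]:
        """Map a batch of (read_id, tag); returns hits and a status tally."""
        hits: list[TagHit] = []
        stats: Counter = Counter()
        for read_id, tag in tags:
            status, hit = self.map_tag(tag, max_mismatch=max_mismatch, read_id=read_id)
            stats[status] += 1
            if hit is not None:
                hits.append(hit)
        return hits, stats


# ---------------------------------------------------------------------------
# Site profiles


def cluster_positions(
    counts: dict[int, int], window: int = 24
) -> list[tuple[int, int]]:
    """Single-linkage clustering of position->count maps.

    Positions within ``window`` of any member of a cluster join it; on the
    sorted position list this is equivalent to splitting at gaps > window.
    Returns [(representative, cluster count)] sorted by position, where the
    representative is the modal position (smallest position on count ties).
    """
    if not counts:
        return []
    positions = sorted(counts)
    clusters: list[list[int]] = [[positions[0]]]
    for pos in positions[1:]:
        if pos - clusters[-1][-1] <= window:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    out = []
    for members in clusters:
        total = sum(counts[p] for p in members)
        rep = max(members, key=lambda p: (counts[p], -p))
        out.append((rep, total))
    return out


@dataclass
class SiteProfile:
    """Per gene x sample poly(A)-site profile."""

    gene_id: str
    sample: str
    counts: dict[int, int]
    clusters: list[tuple[int, int]] = field(default_factory=list)
    usage: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_counts(
        cls, gene_id: str, sample: str, counts: dict[int, int], window: int = 24
    ) -> "SiteProfile":
        clusters = cluster_positions(counts, window)
        total = sum(c for _, c in clusters)
        usage = (
            np.array([c for _, c in clusters], dtype=float) / total
            if total
            else np.zeros(0)
        )
        return cls(gene_id, sample, dict(counts), clusters, usage)


def build_site_profiles(
    hits: Iterable[TagHit], sample: str, window: int = 24
) -> dict[str, SiteProfile]:
    """Aggregate one sample's hits into per-gene site profiles.

    Junction positions are kept in database coordinates (genomic coordinates
    remain recoverable through the record map).
    """
    per_gene: dict[str, Counter] = defaultdict(Counter)
    for hit in hits:
        per_gene[hit.gene_id][hit.db_junction] += 1
    return {
        gene: SiteProfile.from_counts(gene, sample, dict(counter), window)
        for gene, counter in per_gene.items()
    }


def mask_internal_priming(
    profiles: dict[str, SiteProfile],
    records: Sequence[ExtendedUtrRecord],
    min_a: int = 8,
    window: int = 10,
    cluster_window: int = 24,
) -> dict[str, SiteProfile]:
    """Optionally drop clusters that look like oligo-dT internal priming.

    A cluster is masked when the ``window`` database bases immediately past
    its representative junction (the direction the poly(A) remnant continues
    in read orientation) contain at least ``min_a`` A's — a genomic A-stretch
    where oligo-dT could have annealed.  Off by default; provided as an
    opt-in flag only.
    """
    by_gene = {r.gene_id: r for r in records}
    out: dict[str, SiteProfile] = {}
    for gene, prof in profiles.items():
        seq = by_gene[gene].db_sequence
        bad_spans: list[tuple[int, int]] = []
        for rep, _ in prof.clusters:
            tail = seq[rep + 1: rep + 1 + window]
            if tail and tail.count("A") >= min_a:
                bad_spans.append((rep - cluster_window, rep + cluster_window))
        if not bad_spans:
            out[gene] = prof
            continue
        kept = {
            pos: c
            for pos, c in prof.counts.items()
            if not any(lo <= pos <= hi for lo, hi in bad_spans)
        }
        out[gene] = SiteProfile.from_counts(gene, prof.sample, kept, cluster_window)
    return out


# ---------------------------------------------------------------------------
# Output


def write_sam(
    path: str | Path,
    records: Sequence[ExtendedUtrRecord],
    hits_with_seq: Iterable[tuple[TagHit, str]],
) -> int:
    """Write one SAM record per mapped tag, against database sequences."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.gene_id, "LN": r.db_length} for r in records],
    }
    ref_ids = {r.gene_id: i for i, r in enumerate(records)}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for hit, seq in hits_with_seq:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = hit.read_id
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = ref_ids[hit.gene_id]
            a.reference_start = hit.db_start
            a.mapping_quality = 255
            a.cigartuples = [(0, hit.length)]
            a.set_tag("NM", hit.mismatches)
            sam.write(a)
            n += 1
    return n


def write_site_counts(
    profiles: dict[str, SiteProfile], path: str | Path
) -> None:
    """Per-gene position->count TSV (database coordinates)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tsample\tdb_position\tcount\n")
        for gene in sorted(profiles):
            prof = profiles[gene]
            for pos in sorted(prof.counts):
                fh.write(f"{gene}\t{prof.sample}\t{pos}\t{prof.counts[pos]}\n")
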