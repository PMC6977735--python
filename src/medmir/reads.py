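"""MeD-seq read filtering and per-site read counting.

Reads produced by digestion with a methylation-dependent restriction enzyme
carry the recognition site at a characteristic distance from the fragment
end.  A read is kept only when the recognition motif (the CpG dinucleotide
by default) occurs at a 1-based offset of 13-17 bp from the 5' end (offset
of the motif's first base) or from the 3' end (offset of the motif's last
base, counted from the 3' terminus).  Retained reads are assigned to the
genomic CpG site they originate from, yielding one count track per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO

from .errors import InputError, ParseError
from .genome import ReferenceGenome, revcomp

logger = logging.getLogger(__name__)


@dataclass
class Read:
    read_id: str
    sequence: str
    quality: str | None = None


@dataclass
class ReadSet:
    """An ordered collection of single-end reads."""

    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        reads = []
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(Read(rec.id, str(rec.seq).upper(), qual))
        return cls(reads)

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                qual = r.quality or "I" * len(r.sequence)
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


@dataclass
class FilterStats:
    retained: int = 0
    discarded: int = 0

    @property
    def total(self) -> int:
        return self.retained + self.discarded


def motif_occurrences(sequence: str, motif: str) -> list[int]:
    """0-based start offsets of every (possibly overlapping) motif occurrence.

    N bases never match.
    """
    out = []
    i = sequence.find(motif)
    while i != -1:
        out.append(i)
        i = sequence.find(motif, i + 1)
    return out


def in_window_offsets(
    sequence: str, motif: str = "CG", window_min: int = 13, window_max: int = 17
) -> list[int]:
    """All 0-based motif start offsets satisfying the positional rule.

    The rule: the motif's first base lies at 1-based offset d in
    [window_min, window_max] from the 5' end, or its last base lies at
    offset d in the same window counted from the 3' terminus.  5'-side
    matches are listed first; within a side, smallest offset first.
    """
    L = len(sequence)
    m = len(motif)
    occ = motif_occurrences(sequence, motif)
    out = []
    for i in occ:  # 5' side: first base at d = i + 1
        if window_min <= i + 1 <= window_max:
            out.append(i)
    for i in occ:  # 3' side: last base at d = L - (i + m - 1)
        if window_min <= L - (i + m - 1) <= window_max and i not in out:
            out.append(i)
    return out


def in_window_offset(
    sequence: str, motif: str = "CG", window_min: int = 13, window_max: int = 17
) -> int | None:
    """First in-window motif offset (5'-side preferred), or None when the
    read fails the positional filter."""
    offsets = in_window_offsets(sequence, motif, window_min, window_max)
    return offsets[0] if offsets else None


def filter_reads(
    reads: ReadSet,
    motif: str = "CG",
    window_min: int = 13,
    window_max: int = 17,
) -> tuple[ReadSet, FilterStats]:
    """Retain reads whose recognition motif sits in the positional window.

    Reads shorter than ``window_max + len(motif)`` can never satisfy the
    5'-side rule but may still pass on the 3' side; reads with no in-window
    occurrence are discarded and counted, never an error.
    """
    if window_min > window_max:
        raise InputError("window_min must be <= window_max")
    if not motif:
        raise InputError("motif must be non-empty")
    stats = FilterStats()
    kept = []
    for r in reads:
        if in_window_offset(r.sequence, motif, window_min, window_max) is not None:
            kept.append(r)
            stats.retained += 1
        else:
            stats.discarded += 1
    return ReadSet(kept), stats


@dataclass
class SiteCountTrack:
    """Per-sample read counts at genomic recognition sites.

    ``sites[contig]`` is a pair of parallel arrays (positions, counts) with
    strictly increasing positions.  ``library_total`` is the number of
    retained reads behind the track.
    """

    sample_id: str
    sites: dict[str, tuple[np.ndarray, np.ndarray]]
    library_total: int

    def __post_init__(self):
        for contig, (pos, cnt) in self.sites.items():
            pos = np.asarray(pos, dtype=np.int64)
            cnt = np.asarray(cnt, dtype=np.int64)
            if len(pos) != len(cnt):
                raise InputError(f"ragged site arrays on {contig}")
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise InputError(f"site positions not strictly increasing on {contig}")
            if (cnt < 0).any():
                raise InputError("negative site count")
            self.sites[contig] = (pos, cnt)

    def total_count(self) -> int:
        return int(sum(cnt.sum() for _, cnt in self.sites.values()))

    def counts_in(self, contig: str, start: int, end: int) -> int:
        """Summed counts at sites in the half-open interval [start, end)."""
        if contig not in self.sites:
            return 0
        pos, cnt = self.sites[contig]
        lo, hi = np.searchsorted(pos, [start, end])
        return int(cnt[lo:hi].sum())

    def to_bedgraph(self, path: str | Path) -> None:
        """bedGraph-style TSV: contig, start, end, count (one row per site)."""
        with open(path, "w") as fh:
            fh.write(f"#sample={self.sample_id}\tlibrary_total={self.library_total}\n")
            for contig in sorted(self.sites):
                pos, cnt = self.sites[contig]
                for p, c in zip(pos, cnt):
                    fh.write(f"{contig}\t{int(p)}\t{int(p) + 2}\t{int(c)}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SiteCountTrack":
        sample_id = Path(path).stem
        library_total = None
        per_contig: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#"):
                    for token in line[1:].strip().split("\t"):
                        k, _, v = token.partition("=")
                        if k == "sample":
                            sample_id = v
                        elif k == "library_total":
                            library_total = int(v)
                    continue
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 4:
                    raise ParseError("bedGraph record with <4 fields", lineno)
                per_contig.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[3]))
                )
        sites = {}
        for contig, rows in per_contig.items():
            rows.sort()
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            cnt = np.array([r[1] for r in rows], dtype=np.int64)
            sites[contig] = (pos, cnt)
        track = cls(sample_id=sample_id, sites=sites, library_total=0)
        track.library_total = (
            library_total if library_total is not None else track.total_count()
        )
        return track

    def to_bed(self, path: str | Path) -> None:
        """One BED record per counted read at its site (for round-tripping)."""
        with open(path, "w") as fh:
            for contig in sorted(self.sites):
                pos, cnt = self.sites[contig]
                for p, c in zip(pos, cnt):
                    for _ in range(int(c)):
                        fh.write(f"{contig}\t{int(p)}\t{int(p) + 2}\n")


@dataclass
class AssignStats:
    assigned: int = 0
    multi_mapped: int = 0
    unmatched: int = 0
    ambiguous_site: int = 0
    off_site: int = 0


class ExactMatcher:
    """Exact read placement against a small reference.

    Indexes every read-length substring of the forward strand; a read maps
    to the forward strand where the index contains the read itself, and to
    the reverse strand where it contains the read's reverse complement.
    Intended for desk-scale references, not a general aligner.
    """

    def __init__(self, reference: ReferenceGenome, read_length: int):
        self.reference = reference
        self.read_length = read_length
        self._index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in reference.contigs.items():
            for pos in range(len(seq) - read_length + 1):
                kmer = seq[pos : pos + read_length]
                self._index.setdefault(kmer, []).append((contig, pos))

    def locate(self, sequence: str) -> list[tuple[str, int, str]]:
        """All (contig, start, strand) placements of ``sequence``."""
        hits = [(c, p, "+") for c, p in self._index.get(sequence, ())]
        rc = revcomp(sequence)
        hits += [(c, p, "-") for c, p in self._index.get(rc, ())]
        return hits


def assign_sites(
    reads: ReadSet,
    reference: ReferenceGenome,
    sample_id: str = "sample",
    motif: str = "CG",
    window_min: int = 13,
    window_max: int = 17,
    matcher: ExactMatcher | None = None,
) -> tuple[SiteCountTrack, AssignStats]:
    """Assign filtered reads to genomic CpG sites by exact matching.

    Each read is matched exactly against both strands of the reference;
    uniquely placed reads increment the count of the CpG site at their
    in-window motif offset.  Multi-mapping or unmatched reads are dropped
    and tallied in the returned stats.  All reads must share one length
    (per-length matchers are built lazily otherwise).
    """
    if not reference.contigs:
        raise InputError("empty reference")
    site_index = {
        contig: {int(p): i for i, p in enumerate(pos)}
        for contig, pos in reference.cpg_sites.items()
    }
    counts = {
        contig: np.zeros(len(pos), dtype=np.int64)
        for contig, pos in reference.cpg_sites.items()
    }
    matchers: dict[int, ExactMatcher] = {}
    if matcher is not None:
        matchers[matcher.read_length] = matcher
    stats = AssignStats()
    for r in reads:
        L = len(r.sequence)
        if L not in matchers:
            matchers[L] = ExactMatcher(reference, L)
        hits = matchers[L].locate(r.sequence)
        if not hits:
            stats.unmatched += 1
            continue
        if len(hits) > 1:
            stats.multi_mapped += 1
            continue
        contig, start, strand = hits[0]
        offsets = in_window_offsets(r.sequence, motif, window_min, window_max)
        if not offsets:
            stats.off_site += 1
            continue
        candidates = set()
        for offset in offsets:
            if strand == "+":
                candidates.add(start + offset)
            else:
                # read position i maps to genome position start + L - 1 - i;
                # the motif spans [offset, offset+len) in read coordinates,
                # so its genomic start is start + L - len(motif) - offset.
                candidates.add(start + L - len(motif) - offset)
        if len(candidates) > 1:
            # two CpG sites both sit at a legal distance from an end; the
            # true fragment origin cannot be told apart, so drop the read
            stats.ambiguous_site += 1
            continue
        site = candidates.pop()
        idx = site_index.get(contig, {}).get(site)
        if idx is None:
            stats.off_site += 1
            continue
        counts[contig][idx] += 1
        stats.assigned += 1
    sites = {
        contig: (reference.cpg_sites[contig].copy(), counts[contig])
        for contig in reference.cpg_sites
    }
    return (
        SiteCountTrack(sample_id=sample_id, sites=sites, library_total=stats.assigned),
        stats,
    )


def load_alignments(
    path: str | Path,
    format: str,
    sample_id: str | None = None,
    motif: str = "CG",
    window_min: int = 13,
    window_max: int = 17,
) -> SiteCountTrack:
    """Build a site count track from externally aligned data.

    SAM: unmapped/secondary/supplementary records are skipped; the site is
    the aligned start plus the in-read motif offset (records without an
    in-window motif are skipped).  BED: each record is one pre-assigned site
    hit at its start coordinate.
    """
    fmt = format.upper()
    sample_id = sample_id or Path(path).stem
    per_contig: dict[str, dict[int, int]] = {}
    retained = 0
    if fmt == "SAM":
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                seq = (rec.query_sequence or "").upper()
                offset = in_window_offset(seq, motif, window_min, window_max)
                if offset is None:
                    continue
                site = rec.reference_start + offset
                per_contig.setdefault(rec.reference_name, {})
                per_contig[rec.reference_name][site] = (
                    per_contig[rec.reference_name].get(site, 0) + 1
                )
                retained += 1
    elif fmt == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ParseError("BED record with <3 fields", lineno)
                try:
                    site = int(parts[1])
                    int(parts[2])
                except ValueError as exc:
                    raise ParseError(f"non-integer coordinate: {exc}", lineno) from exc
                per_contig.setdefault(parts[0], {})
                per_contig[parts[0]][site] = per_contig[parts[0]].get(site, 0) + 1
                retained += 1
    else:
        raise InputError(f"unsupported alignment format: {format}")
    sites = {}
    for contig, d in per_contig.items():
        pos = np.array(sorted(d), dtype=np.int64)
        cnt = np.array([d[int(p)] for p in pos], dtype=np.int64)
        sites[contig] = (pos, cnt)
    return SiteCountTrack(sample_id=sample_id, sites=sites, library_total=retained)
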