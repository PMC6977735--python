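"""Annotated region classes and region-level read counting.

Three region classes are scored: TSS regions (1 kb before to 1 kb after the
transcription start site), CpG islands, and gene bodies (from 1 kb past the
TSS, in the direction of transcription, to the transcription end site).
A CpG site falling in several overlapping regions contributes its full
count to each of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError, InputError, ParseError
from .genome import GeneAnnotation, ReferenceGenome
from .reads import SiteCountTrack

logger = logging.getLogger(__name__)

REGION_CLASSES = ("TSS", "CpG-island", "gene-body")

_COLUMNS = ["region_id", "region_class", "contig", "start", "end", "strand", "parent"]


@dataclass
class RegionSet:
    """A table of scored regions (columns: region_id, region_class, contig,
    start, end, strand, parent)."""

    regions: pd.DataFrame

    def __post_init__(self):
        self.regions = pd.DataFrame(self.regions, columns=_COLUMNS)
        if (self.regions["start"] >= self.regions["end"]).any():
            raise AnnotationError("region with start >= end")
        unknown = ~self.regions["region_class"].isin(REGION_CLASSES)
        if unknown.any():
            raise AnnotationError(
                f"unknown region class: {self.regions.loc[unknown, 'region_class'].unique()}"
            )

    def __len__(self) -> int:
        return len(self.regions)

    def by_class(self, region_class: str) -> pd.DataFrame:
        return self.regions[self.regions["region_class"] == region_class]

    def to_bed(self, path: str | Path) -> None:
        """BED6; region_id and class packed into the name field."""
        with open(path, "w") as fh:
            for _, r in self.regions.iterrows():
                name = f"{r.region_id}|{r.region_class}|{r.parent}"
                fh.write(
                    f"{r.contig}\t{int(r.start)}\t{int(r.end)}\t{name}\t0\t{r.strand}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ParseError("region BED record with <6 fields", lineno)
                try:
                    region_id, region_class, parent = parts[3].split("|")
                except ValueError as exc:
                    raise ParseError("malformed region name field", lineno) from exc
                rows.append(
                    (
                        region_id,
                        region_class,
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        parts[5],
                        parent,
                    )
                )
        return cls(pd.DataFrame(rows, columns=_COLUMNS))


def build_regions(
    annotation: GeneAnnotation,
    reference: ReferenceGenome | None = None,
    tss_flank: int = 1000,
    body_offset: int = 1000,
) -> RegionSet:
    """Materialize TSS, gene-body and CpG-island regions from an annotation.

    Per gene: a TSS region [tss - tss_flank, tss + tss_flank) and a body
    from ``body_offset`` past the TSS (strand-aware) to the TES.  Genes whose
    body would be empty yield no body region (logged).  Regions are clipped,
    not dropped, at contig edges when a reference is supplied.
    """
    contig_len = (
        {c: reference.contig_length(c) for c in reference.contigs}
        if reference is not None
        else None
    )

    def clip(contig: str, start: int, end: int) -> tuple[int, int]:
        if contig_len is not None:
            n = contig_len.get(contig)
            if n is None:
                raise AnnotationError(f"contig {contig} absent from reference")
            start, end = max(0, start), min(n, end)
        else:
            start = max(0, start)
        return start, end

    rows = []
    for _, g in annotation.genes.iterrows():
        tss, tes = int(g.tss), int(g.tes)
        if contig_len is not None and not (0 <= tss <= contig_len[g.contig]):
            raise AnnotationError(f"gene {g.gene_id}: tss outside contig")
        s, e = clip(g.contig, tss - tss_flank, tss + tss_flank)
        rows.append((f"{g.gene_id}:TSS", "TSS", g.contig, s, e, g.strand, g.gene_id))
        if g.strand == "+":
            body = (tss + body_offset, tes)
        else:
            body = (tes, tss - body_offset)
        if body[0] >= body[1]:
            logger.info("gene %s: empty gene body, skipped", g.gene_id)
            continue
        s, e = clip(g.contig, *body)
        if s < e:
            rows.append(
                (f"{g.gene_id}:body", "gene-body", g.contig, s, e, g.strand, g.gene_id)
            )
    for _, isl in annotation.cpg_islands.iterrows():
        s, e = clip(isl.contig, int(isl.start), int(isl.end))
        rows.append(
            (str(isl.island_id), "CpG-island", isl.contig, s, e, ".", isl.island_id)
        )
    return RegionSet(pd.DataFrame(rows, columns=_COLUMNS))


@dataclass
class RegionCountMatrix:
    """Integer read counts per region (rows) and sample (columns).

    ``library_totals`` maps sample id to its retained-read total;
    ``region_sites`` counts distinct CpG sites observed per region (union
    over samples), used downstream as the DMR site count.
    """

    counts: pd.DataFrame
    library_totals: pd.Series
    regions: RegionSet
    region_sites: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "region_id"
        with open(path, "w") as fh:
            totals = "\t".join(str(int(t)) for t in self.library_totals)
            fh.write(f"#library_totals\t{totals}\n")
            out.to_csv(fh, sep="\t")


def count_regions(
    tracks: list[SiteCountTrack], regions: RegionSet
) -> RegionCountMatrix:
    """Aggregate site count tracks into a region x sample count matrix.

    Overlapping regions each receive the full count of a shared site.
    """
    if not tracks:
        raise InputError("no tracks supplied")
    ids = [t.sample_id for t in tracks]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sample ids among tracks")
    reg = regions.regions
    mat = np.zeros((len(reg), len(tracks)), dtype=np.int64)
    n_sites = np.zeros(len(reg), dtype=np.int64)
    union_sites: dict[str, np.ndarray] = {}
    for t in tracks:
        for contig, (pos, _) in t.sites.items():
            if contig in union_sites:
                union_sites[contig] = np.union1d(union_sites[contig], pos)
            else:
                union_sites[contig] = np.asarray(pos)
    for i, (_, r) in enumerate(reg.iterrows()):
        for j, t in enumerate(tracks):
            mat[i, j] = t.counts_in(r.contig, int(r.start), int(r.end))
        pos = union_sites.get(r.contig)
        if pos is not None:
            lo, hi = np.searchsorted(pos, [int(r.start), int(r.end)])
            n_sites[i] = hi - lo
    counts = pd.DataFrame(mat, index=reg["region_id"].values, columns=ids)
    totals = pd.Series([t.library_total for t in tracks], index=ids, dtype=np.int64)
    return RegionCountMatrix(
        counts=counts,
        library_totals=totals,
        regions=regions,
        region_sites=pd.Series(n_sites, index=reg["region_id"].values),
    )
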