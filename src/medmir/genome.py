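"""Reference sequences and gene/CpG-island annotations.

Coordinates are 0-based, half-open everywhere in memory.  FASTA is written
1-based by construction of the format; BED stays 0-based half-open; the
minimal GTF dialect used for genes converts to 1-based inclusive on write
and back on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, InputError, ParseError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_motif_sites(sequence: str, motif: str = "CG") -> np.ndarray:
    """All 0-based start positions of ``motif`` in ``sequence``, sorted.

    Overlapping occurrences are reported; for the CpG dinucleotide this is
    the position of the C.
    """
    sites = []
    i = sequence.find(motif)
    while i != -1:
        sites.append(i)
        i = sequence.find(motif, i + 1)
    return np.asarray(sites, dtype=np.int64)


@dataclass
class ReferenceGenome:
    """A small reference: contig sequences plus the positions of their CpG
    (more generally, recognition-motif) sites.

    ``cpg_sites[contig]`` holds sorted 0-based positions of the C of each
    CpG dinucleotide on the forward strand.
    """

    contigs: dict[str, str]
    cpg_sites: dict[str, np.ndarray] = field(default_factory=dict)
    motif: str = "CG"

    def __post_init__(self):
        if not self.contigs:
            raise InputError("reference has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise InputError(f"contig {name!r} is empty")
        if not self.cpg_sites:
            self.cpg_sites = {
                name: find_motif_sites(seq, self.motif)
                for name, seq in self.contigs.items()
            }
        for name, sites in self.cpg_sites.items():
            seq = self.contigs[name]
            for p in sites[:50]:  # spot-check the invariant cheaply
                if seq[p : p + len(self.motif)] != self.motif:
                    raise AnnotationError(
                        f"site {int(p)} on {name} does not carry motif {self.motif}"
                    )

    @classmethod
    def from_fasta(cls, path: str | Path, motif: str = "CG") -> "ReferenceGenome":
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(contigs=contigs, motif=motif)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def contig_length(self, contig: str) -> int:
        return len(self.contigs[contig])


@dataclass
class GeneAnnotation:
    """Single-transcript gene models plus CpG-island intervals.

    ``genes`` columns: gene_id, contig, strand (+/-), tss, tes.  For a minus
    strand gene tss > tes; transcription runs from tss toward tes.
    ``cpg_islands`` columns: island_id, contig, start, end (half-open).
    """

    genes: pd.DataFrame
    cpg_islands: pd.DataFrame

    GENE_COLUMNS = ("gene_id", "contig", "strand", "tss", "tes")
    ISLAND_COLUMNS = ("island_id", "contig", "start", "end")

    def __post_init__(self):
        self.genes = pd.DataFrame(self.genes, columns=list(self.GENE_COLUMNS))
        self.cpg_islands = pd.DataFrame(
            self.cpg_islands, columns=list(self.ISLAND_COLUMNS)
        )
        if (self.genes["tss"] == self.genes["tes"]).any():
            raise AnnotationError("gene with tss == tes")
        bad = ~self.genes["strand"].isin(["+", "-"])
        if bad.any():
            raise AnnotationError(
                f"invalid strand for gene(s) {self.genes.loc[bad, 'gene_id'].tolist()}"
            )
        if (self.cpg_islands["start"] >= self.cpg_islands["end"]).any():
            raise AnnotationError("CpG island with start >= end")

    def validate_against(self, reference: ReferenceGenome) -> None:
        """Check every coordinate lies on a reference contig."""
        for _, g in self.genes.iterrows():
            if g.contig not in reference.contigs:
                raise AnnotationError(f"gene {g.gene_id} on unknown contig {g.contig}")
            n = reference.contig_length(g.contig)
            if not (0 <= g.tss <= n and 0 <= g.tes <= n):
                raise AnnotationError(f"gene {g.gene_id} outside contig bounds")
        for _, isl in self.cpg_islands.iterrows():
            if isl.contig not in reference.contigs:
                raise AnnotationError(
                    f"island {isl.island_id} on unknown contig {isl.contig}"
                )
            if not (0 <= isl.start < isl.end <= reference.contig_length(isl.contig)):
                raise AnnotationError(f"island {isl.island_id} outside contig bounds")

    # -- GTF / BED round trip -------------------------------------------------

    def to_gtf(self, path: str | Path) -> None:
        """Write genes as minimal GTF `gene` features (1-based inclusive)."""
        with open(path, "w") as fh:
            for _, g in self.genes.iterrows():
                start, end = sorted((int(g.tss), int(g.tes)))
                fh.write(
                    "\t".join(
                        [
                            str(g.contig),
                            "medmir",
                            "gene",
                            str(start + 1),
                            str(end),
                            ".",
                            g.strand,
                            ".",
                            f'gene_id "{g.gene_id}";',
                        ]
                    )
                    + "\n"
                )

    @staticmethod
    def genes_from_gtf(path: str | Path) -> pd.DataFrame:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ParseError("GTF record with <9 fields", lineno)
                contig, _, feature, start, end, _, strand, _, attrs = parts[:9]
                if feature != "gene":
                    continue
                gene_id = None
                for token in attrs.split(";"):
                    token = token.strip()
                    if token.startswith("gene_id"):
                        gene_id = token.split(None, 1)[1].strip('"')
                if gene_id is None:
                    raise ParseError("GTF gene without gene_id", lineno)
                s0, e0 = int(start) - 1, int(end)  # back to half-open
                tss, tes = (s0, e0) if strand == "+" else (e0, s0)
                rows.append((gene_id, contig, strand, tss, tes))
        return pd.DataFrame(rows, columns=list(GeneAnnotation.GENE_COLUMNS))

    def islands_to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, isl in self.cpg_islands.iterrows():
                fh.write(
                    f"{isl.contig}\t{int(isl.start)}\t{int(isl.end)}\t{isl.island_id}\n"
                )

    @staticmethod
    def islands_from_bed(path: str | Path) -> pd.DataFrame:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ParseError("BED record with <3 fields", lineno)
                name = parts[3] if len(parts) > 3 else f"island{lineno}"
                rows.append((name, parts[0], int(parts[1]), int(parts[2])))
        return pd.DataFrame(rows, columns=list(GeneAnnotation.ISLAND_COLUMNS))

    @classmethod
    def from_files(cls, gtf_path: str | Path, bed_path: str | Path) -> "GeneAnnotation":
        return cls(
            genes=cls.genes_from_gtf(gtf_path),
            cpg_islands=cls.islands_from_bed(bed_path),
        )
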