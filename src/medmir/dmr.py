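"""Differentially methylated region (DMR) calling.

Methylation differences between the primary and recurrent groups are tested
on pooled read counts with a Pearson chi-square on a 2x2 table (region or
site count vs the remainder of the library, one row per group), corrected
for multiple testing by Bonferroni or Benjamini-Hochberg.  Two callers are
provided: per annotated region, and a genome-wide per-site scan in which
neighboring significant sites of a common direction are binned into DMRs
and filtered on site count, span and fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .reads import SiteCountTrack
from .regions import RegionCountMatrix, RegionSet

try:  # intervaltree is a light, pure-python dependency
    from intervaltree import IntervalTree
except ImportError:  # pragma: no cover
    IntervalTree = None


def chi2_counts_test(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> tuple[float, float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [[count_a, total_a - count_a], [count_b, total_b - count_b]].

    Returns (chi2, p, fold_change) where fold_change is the pseudocounted
    rate ratio ((count_b + 1)/total_b) / ((count_a + 1)/total_a), i.e. group
    b (recurrent) over group a (primary).  Degenerate tables with an empty
    row margin (all counts equal to 0 or to their totals) give chi2 = 0,
    p = 1.
    """
    if total_a <= 0 or total_b <= 0:
        raise InputError("chi2_counts_test: totals must be positive")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise InputError("chi2_counts_test: counts must lie in [0, total]")
    fold = ((count_b + 1) / total_b) / ((count_a + 1) / total_a)
    a, b = count_a, total_a - count_a
    c, d = count_b, total_b - count_b
    n = total_a + total_b
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0, fold
    chi2 = n * float(a * d - b * c) ** 2 / (
        float(total_a) * float(total_b) * float(col1) * float(col2)
    )
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p, float(fold)


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment; ``method`` is 'bonferroni' or 'bh'.

    Output order matches input order.  Bonferroni: min(1, m*p);
    Benjamini-Hochberg: step-up adjusted p-values with monotone enforcement.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    key = method.lower()
    if key in ("bh", "fdr_bh", "benjamini-hochberg"):
        sm_method = "fdr_bh"
    elif key == "bonferroni":
        sm_method = "bonferroni"
    else:
        raise InputError(f"unknown adjustment method: {method}")
    return multipletests(p, method=sm_method)[1]


@dataclass
class DMR:
    """A called differentially methylated region."""

    contig: str
    start: int
    end: int
    n_sites: int
    fold_change: float
    chi2_stat: float
    p_raw: float
    p_adj: float
    adjust_method: str
    direction: str  # 'hyper' (higher in recurrent) or 'hypo'
    region_id: str | None = None
    region_class: str | None = None
    overlaps: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    rows = []
    for d in dmrs:
        rows.append(
            {
                "contig": d.contig,
                "start": d.start,
                "end": d.end,
                "id": d.region_id or f"{d.contig}:{d.start}-{d.end}",
                "score": float(-np.log10(max(d.p_adj, 1e-300))),
                "strand": ".",
                "n_sites": d.n_sites,
                "size_bp": d.size_bp,
                "fold_change": d.fold_change,
                "chi2": d.chi2_stat,
                "p_raw": d.p_raw,
                "p_adj": d.p_adj,
                "direction": d.direction,
                "overlaps": ";".join(f"{cls}:{pid}" for cls, pid in d.overlaps),
            }
        )
    columns = [
        "contig", "start", "end", "id", "score", "strand", "n_sites",
        "size_bp", "fold_change", "chi2", "p_raw", "p_adj", "direction",
        "overlaps",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_dmrs(dmrs: list[DMR], path: str | Path) -> None:
    """BED-compatible TSV (first six columns form valid BED6)."""
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _two_groups(group_labels: dict[str, str], samples) -> tuple[str, str, list, list]:
    labels = {group_labels[s] for s in samples}
    if len(labels) != 2:
        raise InputError(f"exactly two groups required, got {sorted(labels)}")
    if labels == {"primary", "recurrent"}:
        ga, gb = "primary", "recurrent"
    else:
        ga, gb = sorted(labels)
    sa = [s for s in samples if group_labels[s] == ga]
    sb = [s for s in samples if group_labels[s] == gb]
    return ga, gb, sa, sb


def _passes_fc(fold: float, min_fc: float) -> bool:
    """Fold-change threshold: outside the band (1/min_fc, min_fc), inclusive."""
    return fold >= min_fc or fold <= 1.0 / min_fc


def call_region_dmrs(
    region_matrix: RegionCountMatrix,
    group_labels: dict[str, str],
    method: str = "bh",
    alpha: float = 0.05,
    min_fc: float = 1.0,
) -> list[DMR]:
    """Test every annotated region for differential methylation.

    Group read counts are pooled by summation across samples; each region's
    pooled counts are tested against the pooled library totals; p-values are
    adjusted across all tested regions.  Regions passing p_adj < alpha and
    the fold-change band are returned.
    """
    samples = list(region_matrix.counts.columns)
    _, _, sa, sb = _two_groups(group_labels, samples)
    total_a = int(region_matrix.library_totals[sa].sum())
    total_b = int(region_matrix.library_totals[sb].sum())
    if total_a == 0 or total_b == 0:
        raise InputError("a group has zero pooled library total")
    pooled_a = region_matrix.counts[sa].sum(axis=1).to_numpy()
    pooled_b = region_matrix.counts[sb].sum(axis=1).to_numpy()
    results = [
        chi2_counts_test(int(ca), total_a, int(cb), total_b)
        for ca, cb in zip(pooled_a, pooled_b)
    ]
    p_raw = np.array([r[1] for r in results])
    p_adj = adjust_pvalues(p_raw, method)
    reg = region_matrix.regions.regions
    out = []
    for i, (_, r) in enumerate(reg.iterrows()):
        chi2, p, fold = results[i]
        if p_adj[i] < alpha and fold != 1.0 and _passes_fc(fold, min_fc):
            out.append(
                DMR(
                    contig=r.contig,
                    start=int(r.start),
                    end=int(r.end),
                    n_sites=max(1, int(region_matrix.region_sites.iloc[i])),
                    fold_change=fold,
                    chi2_stat=chi2,
                    p_raw=p,
                    p_adj=float(p_adj[i]),
                    adjust_method=method,
                    direction="hyper" if fold > 1 else "hypo",
                    region_id=r.region_id,
                    region_class=r.region_class,
                    overlaps=[(r.region_class, str(r.parent))],
                )
            )
    return out


def _pooled_site_table(
    tracks: list[SiteCountTrack], group_labels: dict[str, str]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray], int, int]:
    """Union site positions per contig with per-group pooled counts."""
    _, _, sa, sb = _two_groups(group_labels, [t.sample_id for t in tracks])
    by_id = {t.sample_id: t for t in tracks}
    contigs: dict[str, np.ndarray] = {}
    for t in tracks:
        for contig, (pos, _) in t.sites.items():
            contigs[contig] = (
                np.union1d(contigs[contig], pos) if contig in contigs else np.asarray(pos)
            )
    pooled_a, pooled_b = {}, {}
    for contig, pos in contigs.items():
        ca = np.zeros(len(pos), dtype=np.int64)
        cb = np.zeros(len(pos), dtype=np.int64)
        for sid in sa:
            t = by_id[sid]
            if contig in t.sites:
                tp, tc = t.sites[contig]
                ca[np.searchsorted(pos, tp)] += tc
        for sid in sb:
            t = by_id[sid]
            if contig in t.sites:
                tp, tc = t.sites[contig]
                cb[np.searchsorted(pos, tp)] += tc
        pooled_a[contig], pooled_b[contig] = ca, cb
    total_a = sum(by_id[s].library_total for s in sa)
    total_b = sum(by_id[s].library_total for s in sb)
    return contigs, pooled_a, pooled_b, total_a, total_b


def sliding_window_dmrs(
    tracks: list[SiteCountTrack],
    group_labels: dict[str, str],
    alpha: float = 0.05,
    method: str = "bh",
    min_sites: int = 4,
    min_size_bp: int = 100,
    min_fc: float = 1.5,
    max_gap: int = 0,
    regions: RegionSet | None = None,
) -> list[DMR]:
    """Genome-wide per-site scan with binning of neighboring significant sites.

    Every site present in any track is tested on pooled group counts against
    the pooled library totals; per-site p-values are adjusted across all
    sites.  Runs of significant sites sharing a direction, allowing at most
    ``max_gap`` intervening non-significant sites, are binned into a DMR
    spanning the first to the last significant site; the bin's fold change
    and chi-square are recomputed on counts pooled over the whole span, its
    p_adj is the smallest member-site p_adj.  Bins failing min_sites,
    min_size_bp or the fold-change band are discarded; survivors are
    annotated for overlap with TSS, CpG-island and gene-body regions when a
    region set is supplied.
    """
    if not tracks:
        return []
    contigs, pooled_a, pooled_b, total_a, total_b = _pooled_site_table(
        tracks, group_labels
    )
    if total_a == 0 or total_b == 0:
        raise InputError("a group has zero pooled library total")
    # flat per-site test across all contigs, then one global adjustment
    flat_stats, flat_keys = [], []
    for contig, pos in contigs.items():
        ca, cb = pooled_a[contig], pooled_b[contig]
        for i in range(len(pos)):
            flat_keys.append((contig, i))
            flat_stats.append(chi2_counts_test(int(ca[i]), total_a, int(cb[i]), total_b))
    if not flat_stats:
        return []
    p_adj = adjust_pvalues(np.array([s[1] for s in flat_stats]), method)
    site_info: dict[str, list[tuple]] = {c: [] for c in contigs}
    for (contig, i), (chi2, p, fold), padj in zip(flat_keys, flat_stats, p_adj):
        site_info[contig].append((i, chi2, p, fold, float(padj)))

    dmrs: list[DMR] = []
    motif_len = 2  # span end covers the CpG dinucleotide of the last site

    def flush(contig: str, members: list[tuple]) -> None:
        if not members:
            return
        pos = contigs[contig]
        first, last = members[0][0], members[-1][0]
        start, end = int(pos[first]), int(pos[last]) + motif_len
        lo, hi = first, last + 1  # every site in the span, significant or not
        ca = int(pooled_a[contig][lo:hi].sum())
        cb = int(pooled_b[contig][lo:hi].sum())
        chi2, p, fold = chi2_counts_test(ca, total_a, cb, total_b)
        best_padj = min(m[4] for m in members)
        if len(members) < min_sites or (end - start) < min_size_bp:
            return
        if fold == 1.0 or not _passes_fc(fold, min_fc):
            return
        dmrs.append(
            DMR(
                contig=contig,
                start=start,
                end=end,
                n_sites=len(members),
                fold_change=fold,
                chi2_stat=chi2,
                p_raw=p,
                p_adj=best_padj,
                adjust_method=method,
                direction="hyper" if fold > 1 else "hypo",
            )
        )

    for contig, infos in site_info.items():
        current: list[tuple] = []
        cur_dir: str | None = None
        gap = 0
        for info in infos:
            _, _, _, fold, padj = info
            significant = padj < alpha and fold != 1.0
            direction = "hyper" if fold > 1 else "hypo"
            if significant:
                if cur_dir is None:
                    current, cur_dir, gap = [info], direction, 0
                elif direction == cur_dir and gap <= max_gap:
                    current.append(info)
                    gap = 0
                else:
                    flush(contig, current)
                    current, cur_dir, gap = [info], direction, 0
            else:
                if cur_dir is not None:
                    gap += 1
                    if gap > max_gap:
                        flush(contig, current)
                        current, cur_dir, gap = [], None, 0
        flush(contig, current)

    if regions is not None:
        dmrs = annotate_dmrs(dmrs, regions)
    return dmrs


def annotate_dmrs(dmrs: list[DMR], regions: RegionSet) -> list[DMR]:
    """Record, per DMR, every region class and parent id with >= 1 bp overlap
    (half-open intervals: touching at an endpoint is not overlap)."""
    trees: dict[str, IntervalTree] = {}
    for _, r in regions.regions.iterrows():
        trees.setdefault(r.contig, IntervalTree()).addi(
            int(r.start), int(r.end), (r.region_class, str(r.parent))
        )
    for d in dmrs:
        hits = trees[d.contig].overlap(d.start, d.end) if d.contig in trees else ()
        d.overlaps = sorted({iv.data for iv in hits})
    return dmrs
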