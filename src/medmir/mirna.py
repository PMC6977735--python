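"""TLDA microRNA Ct processing and paired differential expression.

The processing chain mirrors standard TLDA practice: censor undetected
wells (Ct above a detectability cutoff), normalize each sample to the
median Ct of its detectable miRNAs (so -dCt is log2 relative expression),
drop miRNAs detected in fewer than half the samples, adjust additive batch
effects, and run a paired t-test (recurrent minus primary) per miRNA with
Benjamini-Hochberg FDR.  Significance uses the dual threshold p < alpha and
q < fdr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dmr import adjust_pvalues
from .errors import InputError, SampleQualityError

logger = logging.getLogger(__name__)

SAMPLE_FIELDS = ("pair_id", "role", "batch")


@dataclass
class CtMatrix:
    """Raw Ct values (miRNA x sample) plus per-sample metadata.

    ``samples`` is indexed by sample id with columns pair_id, role
    ('primary'/'recurrent') and batch.  Missing / undetected wells are NaN.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.samples = pd.DataFrame(self.samples)
        missing = [c for c in SAMPLE_FIELDS if c not in self.samples.columns]
        if missing:
            raise InputError(f"sample table lacks columns: {missing}")
        if list(self.values.columns) != list(self.samples.index):
            raise InputError("sample table index does not match matrix columns")
        for pair_id, grp in self.samples.groupby("pair_id"):
            roles = sorted(grp["role"])
            if roles != ["primary", "recurrent"]:
                raise InputError(
                    f"pair {pair_id}: expected one primary and one recurrent, got {roles}"
                )
            if grp["batch"].nunique() != 1:
                raise InputError(f"pair {pair_id}: samples split across batches")

    def drop_samples(self, sample_ids: list[str]) -> "CtMatrix":
        """Explicit sample exclusion (whole pairs are removed so the pairing
        invariant survives)."""
        pairs = set(self.samples.loc[self.samples.index.isin(sample_ids), "pair_id"])
        keep = ~self.samples["pair_id"].isin(pairs)
        return CtMatrix(
            values=self.values.loc[:, keep.values],
            samples=self.samples.loc[keep.values],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for field in SAMPLE_FIELDS:
                vals = "\t".join(str(v) for v in self.samples[field])
                fh.write(f"#{field}\t{vals}\n")
            self.values.to_csv(fh, sep="\t", index_label="mirna", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CtMatrix":
        meta: dict[str, list[str]] = {}
        header_lines = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                header_lines += 1
                parts = line[1:].rstrip("\n").split("\t")
                meta[parts[0]] = parts[1:]
        values = pd.read_csv(
            path, sep="\t", skiprows=header_lines, index_col=0, na_values=["NA"]
        )
        missing = [f for f in SAMPLE_FIELDS if f not in meta]
        if missing:
            raise InputError(f"Ct TSV lacks metadata lines: {missing}")
        samples = pd.DataFrame(
            {f: meta[f] for f in SAMPLE_FIELDS}, index=values.columns
        )
        return cls(values=values, samples=samples)


@dataclass
class ExpressionMatrix:
    """Normalized log2 relative expression (miRNA x sample); NaN preserved."""

    values: pd.DataFrame
    samples: pd.DataFrame


def normalize_ct(ct: CtMatrix, detect_ct_max: float = 35.0) -> ExpressionMatrix:
    """Median-Ct normalization.

    Wells with Ct > detect_ct_max (or already missing) become NaN; every
    remaining value becomes -(Ct - median Ct of that sample's detectable
    miRNAs), i.e. log2 relative expression with per-sample median 0.
    """
    censored = ct.values.where(ct.values <= detect_ct_max)
    dead = censored.notna().sum(axis=0) == 0
    if dead.any():
        bad = list(censored.columns[dead])
        raise SampleQualityError(f"no detectable miRNAs in sample(s): {bad}")
    medians = censored.median(axis=0, skipna=True)
    values = -(censored - medians)
    return ExpressionMatrix(values=values, samples=ct.samples.copy())


def detection_filter(
    expr: ExpressionMatrix, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep miRNAs detected (non-missing) in at least ``min_fraction`` of all
    samples; the boundary is inclusive."""
    if not (0 < min_fraction <= 1):
        raise InputError("min_fraction must lie in (0, 1]")
    frac = expr.values.notna().mean(axis=1)
    return ExpressionMatrix(
        values=expr.values.loc[frac >= min_fraction], samples=expr.samples
    )


def batch_adjust(expr: ExpressionMatrix, mode: str = "location_scale") -> ExpressionMatrix:
    """Remove additive/multiplicative batch effects.

    Default mode is a deterministic per-miRNA location-scale adjustment:
    within each batch the available values are standardized, then rescaled
    to the miRNA's overall mean and pooled (within-batch) standard
    deviation.  Batches contributing a single value to a miRNA are left
    unadjusted (logged); zero-variance batches are recentered only.  The
    'eb' mode applies parametric empirical-Bayes shrinkage of the per-batch
    location/scale estimates across miRNAs (the ComBat model).
    """
    if mode not in ("location_scale", "eb"):
        raise InputError(f"unknown batch adjustment mode: {mode}")
    batches = expr.samples["batch"]
    X = expr.values.to_numpy(dtype=float).copy()
    batch_levels = list(pd.unique(batches))
    if len(batch_levels) < 2:
        return ExpressionMatrix(values=expr.values.copy(), samples=expr.samples)
    cols = {b: np.where(batches.values == b)[0] for b in batch_levels}
    if mode == "eb":
        X = _combat_eb(X, cols)
    else:
        for g in range(X.shape[0]):
            row = X[g]
            obs = ~np.isnan(row)
            stats = {}
            for b, idx in cols.items():
                v = row[idx][obs[idx]]
                if len(v) >= 2:
                    stats[b] = (v.mean(), v.std(ddof=1), len(v))
            if not stats:
                continue
            mu = np.nanmean(row)
            dfs = np.array([n - 1 for (_, _, n) in stats.values()], dtype=float)
            variances = np.array([s**2 for (_, s, _) in stats.values()])
            pooled_sd = float(np.sqrt((dfs * variances).sum() / dfs.sum()))
            for b, idx in cols.items():
                if b not in stats:
                    if obs[idx].sum() == 1:
                        logger.warning(
                            "batch %s contributes one value to row %d; left unadjusted",
                            b, g,
                        )
                    continue
                mean_b, sd_b, _ = stats[b]
                sel = idx[obs[idx]]
                if sd_b == 0:
                    X[g, sel] = mu
                else:
                    X[g, sel] = mu + pooled_sd * (row[sel] - mean_b) / sd_b
    out = pd.DataFrame(X, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values=out, samples=expr.samples)


def _combat_eb(X: np.ndarray, cols: dict, n_iter: int = 100, tol: float = 1e-6):
    """Parametric empirical-Bayes batch adjustment (batch-only design),
    NaN-aware.  Per-batch location/scale estimates are shrunk across rows
    toward normal / inverse-gamma priors before removal."""
    grand = np.nanmean(X, axis=1)
    pooled_var = np.nanvar(X, axis=1, ddof=1)
    pooled_var[~np.isfinite(pooled_var) | (pooled_var == 0)] = 1.0
    Z = (X - grand[:, None]) / np.sqrt(pooled_var)[:, None]
    Zadj = Z.copy()
    for b, idx in cols.items():
        Zb = Z[:, idx]
        n_b = np.sum(~np.isnan(Zb), axis=1).astype(float)
        ok = n_b >= 2
        gamma_hat = np.nanmean(Zb, axis=1)
        delta_hat = np.nanvar(Zb, axis=1, ddof=1)
        gamma_hat[~ok] = 0.0
        delta_hat[~ok | (delta_hat == 0)] = 1.0
        # hyperpriors by method of moments across rows
        g_bar, t2 = float(np.mean(gamma_hat[ok])), float(np.var(gamma_hat[ok]))
        d_bar, s2 = float(np.mean(delta_hat[ok])), float(np.var(delta_hat[ok]))
        lam = (2 * s2 + d_bar**2) / s2 if s2 > 0 else 100.0
        theta = (d_bar * s2 + d_bar**3) / s2 if s2 > 0 else d_bar * 99.0
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        if t2 > 0:
            for _ in range(n_iter):
                g_new = (t2 * n_b * gamma_hat + delta_star * g_bar) / (
                    t2 * n_b + delta_star
                )
                ssq = np.nansum((Zb - g_new[:, None]) ** 2, axis=1)
                d_new = (theta + 0.5 * ssq) / (n_b / 2 + lam - 1)
                d_new[~ok | ~np.isfinite(d_new) | (d_new <= 0)] = 1.0
                if (
                    np.nanmax(np.abs(g_new - gamma_star)) < tol
                    and np.nanmax(np.abs(d_new - delta_star)) < tol
                ):
                    gamma_star, delta_star = g_new, d_new
                    break
                gamma_star, delta_star = g_new, d_new
        adj = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
        adj[~ok] = Zb[~ok]  # too few values: leave unadjusted
        Zadj[:, idx] = adj
    return Zadj * np.sqrt(pooled_var)[:, None] + grand[:, None]


@dataclass
class DEResult:
    mirna: str
    n_pairs_used: int
    mean_diff: float
    t_stat: float
    p: float
    q: float
    significant: bool
    flag: str = ""


def paired_de(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    fdr: float = 0.25,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Paired t-test (recurrent - primary) per miRNA over pairwise-complete
    pairs, with BH q-values over the tested miRNAs.

    miRNAs with fewer than ``min_pairs`` complete pairs get NaN statistics.
    Zero-variance differences are flagged: p -> 0 when the mean is nonzero
    (the test diverges), p = 1 when every difference is exactly 0.
    Significance is the dual threshold p < alpha and q < fdr.
    """
    roles = expr.samples["role"]
    prim = expr.samples.index[roles == "primary"]
    rec = expr.samples.index[roles == "recurrent"]
    pair_of = expr.samples["pair_id"]
    rec_by_pair = {pair_of[s]: s for s in rec}
    pairs = [(pair_of[s], s, rec_by_pair[pair_of[s]]) for s in prim]

    rows = []
    for mirna, vals in expr.values.iterrows():
        d = np.array(
            [
                vals[sr] - vals[sp]
                for _, sp, sr in pairs
                if np.isfinite(vals[sp]) and np.isfinite(vals[sr])
            ]
        )
        n = len(d)
        flag = ""
        if n < min_pairs:
            rows.append((mirna, n, np.nan, np.nan, np.nan, flag))
            continue
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            if mean == 0.0:
                t, p, flag = 0.0, 1.0, "all_differences_zero"
            else:
                t = np.inf if mean > 0 else -np.inf
                p, flag = 0.0, "zero_variance"
        else:
            t = mean / (sd / np.sqrt(n))
            p = float(2 * sps.t.sf(abs(t), df=n - 1))
        rows.append((mirna, n, mean, t, p, flag))

    res = pd.DataFrame(
        rows, columns=["mirna", "n_pairs_used", "mean_diff", "t_stat", "p", "flag"]
    )
    tested = res["p"].notna()
    q = np.full(len(res), np.nan)
    if tested.any():
        q[tested.values] = adjust_pvalues(res.loc[tested, "p"].to_numpy(), "bh")
    res["q"] = q
    res["significant"] = (res["p"] < alpha) & (res["q"] < fdr)
    return res[
        ["mirna", "n_pairs_used", "mean_diff", "t_stat", "p", "q", "significant", "flag"]
    ]
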