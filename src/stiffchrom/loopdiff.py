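"""Differential chromatin-loop analysis from anchor-summed contact counts.

The procedure mirrors the standard two-group negative-binomial count
workflow: raw per-replicate contact maps are summed over each loop's anchor
pixel block into a count table; size factors are estimated by
median-of-ratios; per-loop dispersions by method-of-moments, shrunk toward a
fitted mean-dispersion trend; and log2 fold changes are tested with a Wald
statistic, Benjamini-Hochberg corrected.

Conventions: positive log2FC means a stronger interaction in the *second*
condition of the design; significance filters are P_adj < 0.05,
|log2FC| > 0.5 and baseMean >= 10 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .loops import as_loop_frame
from .mapcore import ContactMap


@dataclass
class DesignError(ValueError):
    message: str

    def __str__(self) -> str:
        return self.message


def count_loop_contacts(
    raw_maps: dict[str, ContactMap], loops: pd.DataFrame
) -> pd.DataFrame:
    """Sum raw counts over each loop's anchor-bin block, per sample.

    ``raw_maps`` maps sample names to *raw* (unbalanced) contact maps at the
    loop resolution.  Anchors spanning several bins contribute the full
    rectangular pixel block.  Returns a loops x samples integer table indexed
    by loop id "chromA:startA-endA|chromB:startB-endB".
    """
    loops = as_loop_frame(loops)
    if len(raw_maps) == 0:
        raise ValueError("no maps supplied")
    resolutions = {m.resolution for m in raw_maps.values()}
    if len(resolutions) != 1:
        raise ValueError("all maps must share one resolution")
    res = resolutions.pop()
    mismatched = sorted(set(loops["resolution_bp"]) - {res})
    if mismatched:
        raise ValueError(
            f"loops at resolution(s) {mismatched} absent from maps at {res} bp"
        )
    ids = [
        f"{r.chromA}:{r.startA}-{r.endA}|{r.chromB}:{r.startB}-{r.endB}"
        for r in loops.itertuples(index=False)
    ]
    table = pd.DataFrame(index=pd.Index(ids, name="loop_id"))
    first = next(iter(raw_maps.values()))
    bins = first.bins
    chrom_start = {
        c: int(np.flatnonzero(bins["chrom"].to_numpy() == c)[0])
        for c in pd.unique(bins["chrom"])
    }
    chrom_n = {c: int((bins["chrom"] == c).sum()) for c in chrom_start}

    # precompute pixel-block indices per loop
    blocks = []
    for r in loops.itertuples(index=False):
        if r.chromA not in chrom_start or r.chromB not in chrom_start:
            blocks.append(None)
            continue
        i0 = chrom_start[r.chromA] + int(r.startA) // res
        i1 = chrom_start[r.chromA] + max(int(r.startA) // res + 1, -(-int(r.endA) // res))
        j0 = chrom_start[r.chromB] + int(r.startB) // res
        j1 = chrom_start[r.chromB] + max(int(r.startB) // res + 1, -(-int(r.endB) // res))
        i1 = min(i1, chrom_start[r.chromA] + chrom_n[r.chromA])
        j1 = min(j1, chrom_start[r.chromB] + chrom_n[r.chromB])
        blocks.append((i0, i1, j0, j1))

    for sample, cmap in raw_maps.items():
        dense = cmap.dense()
        col = np.zeros(len(loops), dtype=np.int64)
        for k, blk in enumerate(blocks):
            if blk is None:
                continue
            i0, i1, j0, j1 = blk
            col[k] = int(dense[i0:i1, j0:j1].sum())
        table[sample] = col
    return table


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over loops with all-positive counts."""
    counts = table.to_numpy(dtype=float)
    pos = (counts > 0).all(axis=1)
    if pos.sum() == 0:
        raise ValueError("no loop has positive counts in every sample")
    logc = np.log(counts[pos])
    ref = logc.mean(axis=1)
    sf = np.exp(np.median(logc - ref[:, None], axis=0))
    return pd.Series(sf, index=table.columns, name="size_factor")


def _trended_dispersion(mu: np.ndarray, phi_mom: np.ndarray) -> np.ndarray:
    """Fit phi ~ a0 + a1/mu on method-of-moments estimates (robust, clipped)."""
    ok = np.isfinite(mu) & (mu > 0) & np.isfinite(phi_mom)
    if ok.sum() < 3:
        return np.zeros_like(mu)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, phi_mom[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.inf)
    return np.clip(trend, 0.0, None)


def nb_differential(
    table: pd.DataFrame,
    design: dict[str, str],
    condition_a: str,
    condition_b: str,
    shrinkage_weight: float = 0.5,
    sample_size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test per loop; positive log2FC = stronger in B.

    ``design`` maps sample (column) names to condition labels.  Size factors
    normalize counts (median-of-ratios over the table by default; pass
    ``sample_size_factors`` when a better external estimate exists, e.g.
    total map counts after depth matching — with few loops and an asymmetric
    planted change the median-of-ratios reference itself shifts); per-loop
    dispersion is the pooled method-of-moments estimate shrunk toward the
    fitted mean-dispersion trend with a fixed weight; the Wald statistic uses
    the delta-method standard error of the log2 ratio of condition means.
    All-zero loops get missing p-values.
    """
    cols_a = [c for c, cond in design.items() if cond == condition_a]
    cols_b = [c for c, cond in design.items() if cond == condition_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError(
            f"need >=2 replicates per condition, got {len(cols_a)} vs {len(cols_b)}"
        )
    missing = [c for c in cols_a + cols_b if c not in table.columns]
    if missing:
        raise DesignError(f"design references absent samples: {missing}")

    if sample_size_factors is not None:
        sf = sample_size_factors[cols_a + cols_b].astype(float)
        sf = sf / np.exp(np.log(sf).mean())
    else:
        sf = size_factors(table[cols_a + cols_b])
    norm = table[cols_a + cols_b].to_numpy(dtype=float) / sf.to_numpy()[None, :]
    na, nb = len(cols_a), len(cols_b)
    A = norm[:, :na]
    B = norm[:, na:]
    mu_a = A.mean(axis=1)
    mu_b = B.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # pooled method-of-moments dispersion: var = mu + phi mu^2.  Estimates
    # stay unclipped until after shrinkage: clipping first would bias the
    # fitted trend upward under pure Poisson noise.
    def phi_of(block, mu):
        var = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (var - mu) / mu**2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        phi_mom = np.nanmean(
            np.column_stack([phi_of(A, mu_a), phi_of(B, mu_b)]), axis=1
        )
    phi_mom = np.clip(np.nan_to_num(phi_mom, nan=0.0), -10.0, 10.0)
    trend = _trended_dispersion(base_mean, phi_mom)
    # shrink toward the trend and floor at half of it: per-loop estimates may
    # flag extra-dispersed loops, but an apparently under-dispersed loop is
    # mostly noise with few replicates and would make the Wald tail
    # anti-conservative
    phi = np.clip(
        shrinkage_weight * phi_mom + (1.0 - shrinkage_weight) * trend,
        0.5 * np.clip(trend, 0.0, None),
        None,
    )

    pseudo = 0.5
    l2fc = np.log2((mu_b + pseudo) / (mu_a + pseudo))
    # delta method: Var(log2 mean) = (1/mu + phi) / (n ln(2)^2)
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_a = (1.0 / (mu_a + pseudo) + phi) / (na * ln2sq)
        var_b = (1.0 / (mu_b + pseudo) + phi) / (nb * ln2sq)
    se = np.sqrt(var_a + var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = l2fc / se
    # normal Wald reference: the dispersion entering the SE is pooled across
    # loops via the trend, so the per-loop statistic is close to Gaussian
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    all_zero = (table[cols_a + cols_b].to_numpy() == 0).all(axis=1)
    pvals = np.where(all_zero, np.nan, pvals)
    l2fc = np.where(all_zero, 0.0, l2fc)

    padj = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        padj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": l2fc,
            "SE": se,
            "stat": wald,
            "pvalue": pvals,
            "padj": padj,
            "dispersion": phi,
        },
        index=table.index,
    )


def filter_diff_loops(
    records: pd.DataFrame,
    padj_max: float = 0.05,
    min_abs_l2fc: float = 0.5,
    min_base_mean: float = 10.0,
) -> pd.DataFrame:
    """Keep loops passing all significance and effect-size thresholds.

    The kept frame carries summary counts by direction in ``attrs``.
    """
    if len(records) == 0:
        out = records.copy()
        out.attrs["n_up"] = out.attrs["n_down"] = 0
        return out
    keep = (
        (records["padj"] < padj_max)
        & (records["log2FC"].abs() > min_abs_l2fc)
        & (records["baseMean"] >= min_base_mean)
    )
    out = records[keep.fillna(False)].copy()
    out.attrs["n_up"] = int((out["log2FC"] > 0).sum())
    out.attrs["n_down"] = int((out["log2FC"] < 0).sum())
    return out


# threshold presets: Methods-style (|log2FC| > 0.5) and volcano-style
# (absolute FC > 1.5, i.e. |log2FC| > log2(1.5))
THRESHOLD_PRESETS = {
    "methods": {"padj_max": 0.05, "min_abs_l2fc": 0.5, "min_base_mean": 10.0},
    "fig_volcano": {
        "padj_max": 0.05,
        "min_abs_l2fc": float(np.log2(1.5)),
        "min_base_mean": 10.0,
    },
}
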