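"""Contact-matrix engine: balancing, expected/O-E, eigenvector compartments,
saddle analysis and cis-depth matching.

The :class:`ContactMap` container stores binned, symmetric contact counts in
upper-triangle sparse form at a fixed resolution with 0-based half-open bin
coordinates, together with per-bin balancing weights (NaN where a bin is
masked).  Masked bins propagate as missing values, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class ContactMap:
    """Binned symmetric contact counts for a (toy) genome.

    ``bins`` has columns chrom/start/end at fixed ``resolution``;
    ``pixels`` is an upper-triangle COO table with columns
    bin1_id/bin2_id/count (bin1_id <= bin2_id).
    """

    bins: pd.DataFrame
    pixels: pd.DataFrame
    resolution: int
    weights: np.ndarray | None = None
    _dense_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.bins.columns):
            raise ValueError(f"bins must have columns {sorted(required)}")
        if (self.pixels["bin1_id"] > self.pixels["bin2_id"]).any():
            raise ValueError("pixels must be upper-triangle (bin1_id <= bin2_id)")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chrom_of_bin(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    def dense(self) -> np.ndarray:
        """Full symmetric raw-count matrix (float64)."""
        if self._dense_cache is None:
            n = self.n_bins
            m = np.zeros((n, n))
            i = self.pixels["bin1_id"].to_numpy()
            j = self.pixels["bin2_id"].to_numpy()
            v = self.pixels["count"].to_numpy(dtype=float)
            m[i, j] = v
            m[j, i] = v
            object.__setattr__(self, "_dense_cache", m)
        return self._dense_cache.copy()

    def balanced(self) -> np.ndarray:
        """W C W with NaN rows/columns at masked bins."""
        if self.weights is None:
            raise ValueError("map is not balanced; run ice_balance first")
        w = self.weights
        m = self.dense() * w[:, None] * w[None, :]
        return m

    def cis_mask(self) -> np.ndarray:
        c = self.chrom_of_bin
        return c[:, None] == c[None, :]

    def cis_total(self) -> float:
        """Total raw cis counts (off-diagonal pixels counted once)."""
        c = self.chrom_of_bin
        px = self.pixels
        cis = c[px["bin1_id"].to_numpy()] == c[px["bin2_id"].to_numpy()]
        off = px["bin1_id"].to_numpy() != px["bin2_id"].to_numpy()
        return float(px["count"].to_numpy()[cis & off].sum())

    def with_pixels(self, pixels: pd.DataFrame) -> "ContactMap":
        return replace(self, pixels=pixels, weights=None, _dense_cache=None)


@dataclass
class CompartmentTrack:
    """Leading-eigenvector compartment track, sign-fixed per chromosome."""

    values: np.ndarray  # per bin; NaN at masked bins
    degenerate_chroms: tuple[str, ...] = ()


@dataclass
class SaddleProfile:
    """Quantile-binned average O/E matrix and its corner means."""

    profile: np.ndarray  # (n_q, n_q)
    scope: str
    corner_fraction: float = 0.2

    def corner_means(self) -> dict[str, float]:
        nq = self.profile.shape[0]
        k = max(1, int(round(nq * self.corner_fraction)))
        lo = self.profile[:k, :k]      # most negative track values (B-B)
        hi = self.profile[-k:, -k:]    # most positive (A-A)
        offd = (self.profile[-k:, :k], self.profile[:k, -k:])
        mean = lambda a: float(np.nanmean(a))
        return {
            "AA": mean(hi),
            "BB": mean(lo),
            "AB": (mean(offd[0]) + mean(offd[1])) / 2.0,
        }


def make_bins(chromsizes: dict[str, int], resolution: int) -> pd.DataFrame:
    rows = []
    for chrom, size in chromsizes.items():
        starts = np.arange(0, size, resolution)
        ends = np.minimum(starts + resolution, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def dense_to_pixels(matrix: np.ndarray) -> pd.DataFrame:
    """Upper-triangle COO table from a dense symmetric matrix."""
    iu, ju = np.nonzero(np.triu(matrix))
    return pd.DataFrame(
        {"bin1_id": iu, "bin2_id": ju, "count": matrix[iu, ju]}
    )


def ice_balance(
    cmap: ContactMap,
    tol: float = 1e-5,
    max_iter: int = 200,
    mask_quantile: float = 0.02,
) -> np.ndarray:
    """Iterative correction: per-bin weights equalizing the balanced marginals.

    Bins in the bottom ``mask_quantile`` of positive raw marginals (and all
    zero-coverage bins) are masked (weight NaN).  Convergence is declared when
    the coefficient of variation of the unmasked balanced marginals drops
    below ``tol``.  The returned weights are also stored on the map.
    """
    C = cmap.dense()
    n = C.shape[0]
    if n < 2:
        raise ValueError("need at least 2 bins to balance")
    marg = C.sum(axis=1)
    pos = marg > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 unmasked bins to balance")
    thresh = np.quantile(marg[pos], mask_quantile)
    mask = pos & (marg >= thresh)
    if mask.sum() < 2:
        mask = pos  # degenerate toy case: keep all covered bins
    b = np.ones(n)
    b[~mask] = 0.0
    sub = C[np.ix_(mask, mask)]
    bs = np.ones(mask.sum())
    residual = np.inf
    for _ in range(max_iter):
        m = (sub * bs[:, None] * bs[None, :]).sum(axis=1)
        mean = m[m > 0].mean()
        residual = float(np.std(m / mean))
        if residual < tol:
            break
        upd = m / mean
        upd[upd == 0] = 1.0
        bs /= np.sqrt(upd)
    else:
        raise RuntimeError(
            f"ICE did not converge in {max_iter} iterations "
            f"(marginal CV residual {residual:.3g})"
        )
    # scale so unmasked balanced marginals average to 1
    m = (sub * bs[:, None] * bs[None, :]).sum(axis=1)
    bs /= np.sqrt(m.mean())
    w = np.full(n, np.nan)
    w[mask] = bs
    cmap.weights = w
    return w


def expected_cis(cmap: ContactMap) -> np.ndarray:
    """Distance-decay expectation: mean balanced signal per bin separation.

    Computed per chromosome then pooled over chromosomes (pixel-weighted);
    entry d is the expected balanced count at separation d bins.  Distances
    with no valid pixels yield NaN.
    """
    B = cmap.balanced()
    chroms = cmap.chrom_of_bin
    max_d = 0
    sums: dict[int, float] = {}
    cnts: dict[int, int] = {}
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sub = B[np.ix_(idx, idx)]
        nloc = len(idx)
        max_d = max(max_d, nloc - 1)
        for d in range(1, nloc):
            diag = np.diagonal(sub, offset=d)
            vals = diag[np.isfinite(diag)]
            if len(vals):
                sums[d] = sums.get(d, 0.0) + vals.sum()
                cnts[d] = cnts.get(d, 0) + len(vals)
    exp = np.full(max_d + 1, np.nan)
    for d in sums:
        exp[d] = sums[d] / cnts[d]
    return exp


def expected_trans(cmap: ContactMap) -> float:
    """Uniform trans expectation: mean balanced inter-chromosomal pixel."""
    B = cmap.balanced()
    mask = ~cmap.cis_mask()
    vals = B[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no trans pixels")
    return float(vals.mean())


def oe(cmap: ContactMap) -> np.ndarray:
    """Observed/expected matrix: cis by distance decay, trans by uniform mean.

    Masked bins and empty diagonals propagate as NaN.
    """
    B = cmap.balanced()
    n = cmap.n_bins
    exp = expected_cis(cmap)
    chroms = cmap.chrom_of_bin
    out = np.full((n, n), np.nan)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sub = B[np.ix_(idx, idx)]
        nloc = len(idx)
        sep = np.abs(np.arange(nloc)[:, None] - np.arange(nloc)[None, :])
        e = np.where(sep > 0, exp[np.minimum(sep, len(exp) - 1)], np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[np.ix_(idx, idx)] = np.where(e > 0, sub / e, np.nan)
    # trans
    tmask = ~cmap.cis_mask()
    if tmask.any():
        te = expected_trans(cmap)
        if te > 0:
            with np.errstate(invalid="ignore"):
                out[tmask] = B[tmask] / te
    return out


def eigen_compartments(
    cmap: ContactMap, orientation_reference: np.ndarray
) -> CompartmentTrack:
    """Per-chromosome leading eigenvector of the O/E correlation matrix.

    The eigenvector sign is fixed so that its Pearson correlation with
    ``orientation_reference`` is non-negative on each chromosome.
    Chromosomes with no contact structure (near-constant O/E) are flagged
    degenerate and left NaN.
    """
    if len(orientation_reference) != cmap.n_bins:
        raise ValueError("orientation reference must have one value per bin")
    O = oe(cmap)
    chroms = cmap.chrom_of_bin
    values = np.full(cmap.n_bins, np.nan)
    degenerate: list[str] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sub = O[np.ix_(idx, idx)]
        valid = np.isfinite(sub).sum(axis=1) > 1
        if valid.sum() < 3:
            degenerate.append(str(chrom))
            continue
        vi = idx[valid]
        m = sub[np.ix_(valid, valid)]
        # fill remaining NaNs (empty diagonals) with the row means
        row_mean = np.nanmean(m, axis=1)
        bad = ~np.isfinite(m)
        m[bad] = np.broadcast_to(row_mean[:, None], m.shape)[bad]
        if np.nanstd(m) < 1e-12:
            degenerate.append(str(chrom))
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(m)
        corr[~np.isfinite(corr)] = 0.0
        evals, evecs = np.linalg.eigh(corr)
        e1 = evecs[:, -1]
        if evals[-1] <= 1e-10:
            degenerate.append(str(chrom))
            continue
        ref = orientation_reference[vi]
        ok = np.isfinite(ref)
        if ok.sum() >= 2 and np.std(e1[ok]) > 0:
            r = np.corrcoef(e1[ok], ref[ok])[0, 1]
            if np.isfinite(r) and r < 0:
                e1 = -e1
        values[vi] = e1
    return CompartmentTrack(values=values, degenerate_chroms=tuple(degenerate))


def saddle(
    cmap: ContactMap,
    track: np.ndarray,
    n_quantiles: int = 50,
    scope: str = "cis",
) -> SaddleProfile:
    """Average O/E between genome-wide quantile groups of a compartment track.

    Bins are ranked by track value and split into ``n_quantiles`` equal-size
    groups; entry (p, q) of the profile is the mean O/E over all pixel pairs
    between groups p and q in the requested scope (diagonal excluded in cis).
    """
    if scope not in ("cis", "trans"):
        raise ValueError("scope must be 'cis' or 'trans'")
    O = oe(cmap)
    finite_track = np.isfinite(track)
    n_valid = int(finite_track.sum())
    if n_quantiles > n_valid:
        raise ValueError(
            f"n_quantiles={n_quantiles} exceeds the {n_valid} scoreable bins"
        )
    order = np.argsort(track[finite_track], kind="stable")
    valid_idx = np.flatnonzero(finite_track)[order]
    groups = np.array_split(valid_idx, n_quantiles)
    cis = cmap.cis_mask()
    prof = np.full((n_quantiles, n_quantiles), np.nan)
    eye = np.eye(cmap.n_bins, dtype=bool)
    scope_mask = (cis & ~eye) if scope == "cis" else ~cis
    for p in range(n_quantiles):
        for q in range(p, n_quantiles):
            block = O[np.ix_(groups[p], groups[q])]
            sel = scope_mask[np.ix_(groups[p], groups[q])]
            vals = block[sel & np.isfinite(block)]
            if len(vals):
                prof[p, q] = prof[q, p] = vals.mean()
    return SaddleProfile(profile=prof, scope=scope)


def compartment_strength(profile: SaddleProfile, corner_fraction: float = 0.2) -> float:
    """(AA * BB) / AB^2 over the extreme corner groups of a saddle profile."""
    profile = replace(profile, corner_fraction=corner_fraction)
    c = profile.corner_means()
    if not np.isfinite(c["AB"]) or c["AB"] <= 0:
        raise ValueError("heterotypic corner mean undefined")
    return (c["AA"] * c["BB"]) / c["AB"] ** 2


def match_cis_depth(maps: list[ContactMap], seed: int = 0) -> list[ContactMap]:
    """Thin raw maps so all have the same total cis count (the minimum).

    Thinning is an exact without-replacement subsample over cis pixels
    (multivariate hypergeometric), so matched totals are identical, not just
    equal in expectation.  Trans pixels are left untouched.  Deterministic for
    a fixed seed.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps to match")
    totals = [m.cis_total() for m in maps]
    if min(totals) <= 0:
        raise ValueError("a map has zero cis counts; cannot match depth")
    target = int(min(totals))
    rng = np.random.default_rng(seed)
    out = []
    for m, tot in zip(maps, totals):
        if int(tot) == target:
            out.append(m)
            continue
        px = m.pixels.copy()
        c = m.chrom_of_bin
        b1 = px["bin1_id"].to_numpy()
        b2 = px["bin2_id"].to_numpy()
        is_cis = (c[b1] == c[b2]) & (b1 != b2)
        counts = px["count"].to_numpy().astype(np.int64)
        cis_counts = counts[is_cis]
        thinned = rng.multivariate_hypergeometric(
            cis_counts, target, method="marginals"
        )
        counts = counts.copy()
        counts[is_cis] = thinned
        px["count"] = counts
        px = px[px["count"] > 0].reset_index(drop=True)
        out.append(m.with_pixels(px))
    return out
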