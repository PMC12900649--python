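"""Synthetic contact maps, annotations and spike-in tables with known truth.

The generator emulates the inputs of the analysis pipeline on a toy genome:

* balanced-looking raw contact maps with a power-law cis distance decay
  ``P(s) ~ s^-alpha``, a planted multiplicative checkerboard compartment
  signal of amplitude ``s`` (O/E = 1 + s * sigma_i * sigma_j for a +-1
  compartment track), planted focal loops of enrichment ``lambda`` and
  Poisson or negative-binomial replicate noise;
* CTCF / histone-mark peak sets and TSS lists positioned so every loop class
  downstream is non-empty;
* spike-in read-count tables reproducing a wet-lab design where each sample
  carries a fixed admixture (default 8%) of foreign-genome cells.

Every dataset is reproducible from (config, seed) and the ground truth is
serializable as a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .mapcore import ContactMap, make_bins, dense_to_pixels

DEFAULT_CHROMSIZES = {f"chr{i}": 6_000_000 for i in range(1, 5)}
DEFAULT_RESOLUTION = 20_000


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    chromsizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMSIZES))
    resolution: int = DEFAULT_RESOLUTION
    alpha: float = 1.0  # cis decay exponent
    s: float = 0.2  # compartment amplitude, must be < 1
    block_bins: int = 10  # compartment block size in bins
    trans_level: float = 0.05  # trans mean relative to the cis mean at d=1
    noise: str = "nb"  # "poisson" or "nb"
    dispersion: float = 0.05  # NB dispersion phi (var = mu + phi mu^2)
    loops: pd.DataFrame | None = None  # chrom, bin1, bin2, enrichment
    loop_kernel: str = "flat"  # "flat": 3x3 plateau; "gaussian": width-1 kernel
    track_seed: int = 0  # seed for the irregular block-sign pattern

    def __post_init__(self) -> None:
        if not (0 <= self.s < 1):
            raise ValueError("compartment amplitude s must lie in [0, 1)")
        if self.noise not in ("poisson", "nb"):
            raise ValueError("noise must be 'poisson' or 'nb'")

    @property
    def bins(self) -> pd.DataFrame:
        return make_bins(self.chromsizes, self.resolution)

    def compartment_track(self) -> np.ndarray:
        """Per-bin +-1 block track with an irregular (seeded) sign pattern.

        Block signs are drawn at random rather than strictly alternating so
        that the sign autocorrelation at a fixed bin separation averages to
        ~0, as in real genomes; otherwise the data-driven distance-decay
        expectation would absorb part of the compartment signal.
        """
        bins = self.bins
        sign = np.empty(len(bins))
        for k, chrom in enumerate(self.chromsizes):
            idx = np.flatnonzero(bins["chrom"] == chrom)
            n_blocks = -(-len(idx) // self.block_bins)
            rng = np.random.default_rng(self.track_seed + 7919 * k)
            s = rng.choice([1.0, -1.0], size=n_blocks)
            if np.abs(s.sum()) == n_blocks:  # degenerate all-one-class draw
                s[::2] = -s[::2]
            sign[idx] = np.repeat(s, self.block_bins)[: len(idx)]
        return sign

    def to_json(self) -> str:
        d = asdict(self)
        if self.loops is not None:
            d["loops"] = self.loops.to_dict(orient="list")
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        if d.get("loops") is not None:
            d["loops"] = pd.DataFrame(d["loops"])
        return cls(**d)


def plant_loops(
    truth: SyntheticTruth,
    n_loops: int,
    seed: int,
    enrichment: float = 3.0,
    min_sep_bins: int = 15,
    max_sep_bins: int = 50,
) -> SyntheticTruth:
    """Place cis loop anchors uniformly at random with a fixed enrichment.

    The minimum anchor separation keeps the planted footprint a small
    fraction of each anchor bin's marginal: at short separations the decay
    is steep enough that matrix balancing would otherwise absorb a
    noticeable share of the planted enrichment.
    """
    rng = np.random.default_rng(seed)
    bins = truth.bins
    seen: set[tuple] = set()
    rows = []
    chroms = list(truth.chromsizes)
    guard = 0
    while len(rows) < n_loops and guard < n_loops * 200:
        guard += 1
        chrom = chroms[rng.integers(len(chroms))]
        nloc = int((bins["chrom"] == chrom).sum())
        sep = int(rng.integers(min_sep_bins, max_sep_bins + 1))
        if sep + 3 >= nloc:
            continue
        b1 = int(rng.integers(1, nloc - sep - 1))
        key = (chrom, b1, b1 + sep)
        if key in seen:
            continue
        seen.add(key)
        rows.append((chrom, b1, b1 + sep, enrichment))
    if len(rows) < n_loops:
        raise RuntimeError("could not place the requested number of loops")
    loops = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "enrichment"])
    return replace(truth, loops=loops)


def _expected_matrix(truth: SyntheticTruth) -> np.ndarray:
    """Noise-free relative expectation mu_ij (before depth scaling)."""
    bins = truth.bins
    n = len(bins)
    chroms = bins["chrom"].to_numpy()
    sigma = truth.compartment_track()
    mu = np.zeros((n, n))
    comp = 1.0 + truth.s * sigma[:, None] * sigma[None, :]
    for chrom in truth.chromsizes:
        idx = np.flatnonzero(chroms == chrom)
        nloc = len(idx)
        sep = np.abs(np.arange(nloc)[:, None] - np.arange(nloc)[None, :]).astype(float)
        with np.errstate(divide="ignore"):
            decay = np.where(sep >= 1, sep**-truth.alpha, 0.0)
        mu[np.ix_(idx, idx)] = decay
    tmask = chroms[:, None] != chroms[None, :]
    mu[tmask] = truth.trans_level
    mu *= comp
    # focal loops: multiplicative factor over a small anchor footprint
    if truth.loops is not None:
        chrom_start = {c: int(np.flatnonzero(chroms == c)[0]) for c in truth.chromsizes}
        factor = np.ones((n, n))
        for rec in truth.loops.itertuples(index=False):
            i = chrom_start[rec.chrom] + int(rec.bin1)
            j = chrom_start[rec.chrom] + int(rec.bin2)
            lam = float(rec.enrichment)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    a, b = i + di, j + dj
                    if 0 <= a < n and 0 <= b < n:
                        if truth.loop_kernel == "flat":
                            f = lam
                        else:  # gaussian, width 1 bin
                            f = 1.0 + (lam - 1.0) * np.exp(-(di**2 + dj**2) / 2.0)
                        factor[a, b] = max(factor[a, b], f)
                        factor[b, a] = factor[a, b]
        mu *= factor
    np.fill_diagonal(mu, 0.0)  # min cis separation: 1 bin
    return mu


def synth_contact_map(
    truth: SyntheticTruth, depth: float, replicate_seed: int
) -> ContactMap:
    """Draw one raw replicate contact map at the requested total depth.

    The expectation is the truth's decay x checkerboard x loop surface scaled
    so the upper-triangle total equals ``depth``; counts are Poisson or
    negative-binomial (dispersion phi) draws, symmetrized by construction.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(replicate_seed)
    mu = _expected_matrix(truth)
    triu = np.triu(mu, k=1)
    scale = depth / triu.sum()
    lam = triu * scale
    if truth.noise == "poisson":
        counts = rng.poisson(lam)
    else:
        phi = truth.dispersion
        # NB(mu, phi): gamma-poisson mixture with shape 1/phi
        shape = 1.0 / phi
        mix = rng.gamma(shape, 1.0, size=lam.shape) / shape
        counts = rng.poisson(lam * mix)
    counts = np.triu(counts, k=1)
    full = counts + counts.T
    return ContactMap(
        bins=truth.bins,
        pixels=dense_to_pixels(np.triu(full)),
        resolution=truth.resolution,
    )


def synth_annotations(
    truth: SyntheticTruth,
    seed: int,
    ctcf_anchor_fraction: float = 0.5,
    tss_anchor_fraction: float = 0.5,
    active_anchor_fraction: float = 0.3,
    repressive_anchor_fraction: float = 0.3,
    n_background_peaks: int = 50,
    peak_halfwidth: int = 300,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Peak sets (per mark) and a TSS list tied to the planted loop anchors.

    CTCF peaks are centered on both anchors of a stated fraction of loops;
    TSSs are placed within 2 kb of one anchor of a stated fraction; active
    (H3K27ac/H3K4me1/H3K4me3) and repressive (H3K27me3/H3K9me3/H2AK119ub)
    marks overlap anchors of disjoint loop subsets.  Background peaks are
    scattered uniformly.  Returns ({mark: BED-like frame}, tss frame).
    """
    if truth.loops is None or len(truth.loops) == 0:
        raise ValueError("truth has no planted loops; annotations need anchors")
    rng = np.random.default_rng(seed)
    res = truth.resolution
    loops = truth.loops.reset_index(drop=True)
    n = len(loops)

    def anchor_mid(rec, which):
        b = rec.bin1 if which == 0 else rec.bin2
        return int(b) * res + res // 2

    def pick(fraction):
        k = int(round(fraction * n))
        return set(rng.choice(n, size=k, replace=False).tolist()) if k else set()

    ctcf_idx = pick(ctcf_anchor_fraction)
    tss_idx = pick(tss_anchor_fraction)
    active_idx = pick(active_anchor_fraction)
    # repressive loops drawn from the complement of active ones where possible
    pool = np.array(sorted(set(range(n)) - active_idx))
    k_rep = int(round(repressive_anchor_fraction * n))
    if k_rep > len(pool):
        raise ValueError("repressive fraction too high for disjoint placement")
    rep_idx = set(rng.choice(pool, size=k_rep, replace=False).tolist()) if k_rep else set()

    marks = {
        "CTCF": [],
        "H3K27ac": [],
        "H3K4me1": [],
        "H3K4me3": [],
        "H3K27me3": [],
        "H3K9me3": [],
        "H2AK119ub": [],
    }
    for i, rec in enumerate(loops.itertuples(index=False)):
        for which in (0, 1):
            mid = anchor_mid(rec, which)
            peak = (rec.chrom, mid - peak_halfwidth, mid + peak_halfwidth)
            if i in ctcf_idx:
                marks["CTCF"].append(peak)
            if i in active_idx:
                marks[["H3K27ac", "H3K4me1", "H3K4me3"][i % 3]].append(peak)
            if i in rep_idx:
                marks[["H3K27me3", "H3K9me3", "H2AK119ub"][i % 3]].append(peak)

    # uniform background peaks far from anything in particular
    chroms = list(truth.chromsizes)
    for _ in range(n_background_peaks):
        chrom = chroms[rng.integers(len(chroms))]
        p = int(rng.integers(peak_halfwidth, truth.chromsizes[chrom] - peak_halfwidth))
        mark = list(marks)[rng.integers(len(marks))]
        marks[mark].append((chrom, p - peak_halfwidth, p + peak_halfwidth))

    peak_sets = {
        mark: pd.DataFrame(rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
        for mark, rows in marks.items()
        if rows
    }
    if not peak_sets:
        raise ValueError("annotation densities produced zero features")

    tss_rows = []
    for i, rec in enumerate(loops.itertuples(index=False)):
        if i in tss_idx:
            mid = anchor_mid(rec, 0)
            offset = int(rng.integers(-1500, 1501))
            tss_rows.append((rec.chrom, max(0, mid + offset), max(1, mid + offset + 1)))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "start", "end"])
    return peak_sets, tss


def synth_spikein(
    n_samples: int,
    fold_profile,
    seed: int,
    depth: float = 2e6,
    spike_fraction: float = 0.08,
) -> pd.DataFrame:
    """Per-sample target/spike-in read counts for a global-shift design.

    Sample i carries target-genome material proportional to ``fold_profile[i]``
    and a fixed ``spike_fraction`` admixture of foreign cells; each of
    ~``depth`` reads falls on the spike-in genome with probability
    s / (f_i (1 - s) + s).  Returns a frame with columns sample/m/h.
    """
    fold = np.asarray(fold_profile, dtype=float)
    if len(fold) != n_samples:
        raise ValueError("fold_profile length must equal n_samples")
    if not (0 < spike_fraction < 1):
        raise ValueError("spike_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for i, f in enumerate(fold):
        total = rng.poisson(depth)
        p_spike = spike_fraction / (f * (1 - spike_fraction) + spike_fraction)
        h = rng.binomial(total, p_spike)
        m = total - h
        rows.append((f"sample{i + 1}", int(m), int(h)))
    return pd.DataFrame(rows, columns=["sample", "m", "h"])


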