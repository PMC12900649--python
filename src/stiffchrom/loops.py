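"""Loop-list hygiene and pile-up quantification.

Loops are paired anchors in BEDPE convention (0-based half-open intervals,
anchor A upstream of anchor B within a chromosome), tagged with the calling
resolution and source condition.  The module provides multi-resolution
deduplication, chromatin-state classification against peak sets, O/E pile-up
aggregation and the paired t-test on the central 3x3 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapcore import ContactMap, oe

LOOP_COLUMNS = [
    "chromA", "startA", "endA", "chromB", "startB", "endB",
    "resolution_bp", "source_condition",
]

KNOWN_MARKS = {
    "CTCF", "H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3", "H2AK119ub",
}
ACTIVE_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac")
REPRESSIVE_MARKS = ("H3K9me3", "H3K27me3", "H2AK119ub")


def as_loop_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a loop table (sorted, anchors ordered)."""
    out = df.copy()
    for col in LOOP_COLUMNS:
        if col not in out.columns:
            if col == "resolution_bp":
                out[col] = out["endA"] - out["startA"]
            elif col == "source_condition":
                out[col] = ""
            else:
                raise ValueError(f"loop table missing column {col!r}")
    same = out["chromA"] == out["chromB"]
    swapped = same & (out["startA"] > out["startB"])
    if swapped.any():
        a = out.loc[swapped, ["chromA", "startA", "endA"]].to_numpy()
        out.loc[swapped, ["chromA", "startA", "endA"]] = out.loc[
            swapped, ["chromB", "startB", "endB"]
        ].to_numpy()
        out.loc[swapped, ["chromB", "startB", "endB"]] = a
    out = out.drop_duplicates(subset=LOOP_COLUMNS[:6]).reset_index(drop=True)
    return out.sort_values(LOOP_COLUMNS[:6], kind="stable").reset_index(drop=True)


@dataclass
class PileupResult:
    """Average O/E window around a loop set.

    ``matrix`` has odd side (2 * flank_bins + 1); ``central_values`` are the
    central 3x3 pixels and ``central_score`` their mean.
    """

    matrix: np.ndarray
    n_loops: int
    n_skipped: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] % 2 == 0 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("pile-up window must be square with odd side")

    @property
    def central_values(self) -> np.ndarray:
        c = self.matrix.shape[0] // 2
        return self.matrix[c - 1 : c + 2, c - 1 : c + 2].ravel()

    @property
    def central_score(self) -> float:
        return float(np.nanmean(self.central_values))


def _anchor_mid(start: np.ndarray, end: np.ndarray) -> np.ndarray:
    return (start + end) // 2


def deduplicate_loops(loops: pd.DataFrame, window_bp: int = 20_000) -> pd.DataFrame:
    """Merge redundant loops called at different resolutions.

    Two loops are redundant when both anchor midpoints are within
    ``window_bp`` of each other; merging is transitive (single-linkage
    clusters) and each cluster keeps the record called at the finest
    (smallest) resolution, ties broken by coordinate order.  Output order is
    deterministic.
    """
    loops = as_loop_frame(loops)
    if len(loops) == 0:
        return loops
    keep_rows = []
    for (ca, cb), grp in loops.groupby(["chromA", "chromB"], sort=True):
        g = grp.reset_index(drop=True)
        ma = _anchor_mid(g["startA"].to_numpy(), g["endA"].to_numpy())
        mb = _anchor_mid(g["startB"].to_numpy(), g["endB"].to_numpy())
        n = len(g)
        # union-find over pairs within the window on both anchors
        parent = np.arange(n)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if abs(ma[i] - ma[j]) <= window_bp and abs(mb[i] - mb[j]) <= window_bp:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        roots = np.array([find(i) for i in range(n)])
        for root in np.unique(roots):
            members = g.loc[roots == root]
            best = members.sort_values(
                ["resolution_bp", "startA", "startB"], kind="stable"
            ).iloc[0]
            keep_rows.append(best)
    out = pd.DataFrame(keep_rows).reset_index(drop=True)
    return as_loop_frame(out)


def _min_distance_to_peaks(
    chrom: str, start: int, end: int, peaks: pd.DataFrame
) -> float:
    """Gap between [start, end) and the nearest peak on chrom (0 if overlapping)."""
    sub = peaks[peaks["chrom"] == chrom]
    if len(sub) == 0:
        return np.inf
    ps = sub["start"].to_numpy()
    pe = sub["end"].to_numpy()
    gap = np.maximum(ps - end, start - pe)  # negative => overlap
    return float(max(0, gap.min()))


def classify_loops(
    loops: pd.DataFrame,
    peak_sets: dict[str, pd.DataFrame],
    tss: pd.DataFrame | None = None,
    ctcf_proximal_bp: int = 1_000,
    ctcf_exclusion_bp: int = 2_500,
    tss_bp: int = 2_000,
    ctcf_both_anchors: bool = True,
    unique_conditions: set[str] | None = None,
) -> pd.DataFrame:
    """Label loops by chromatin state at their anchors.

    Classes follow the anchor rules: ``CTCF`` — anchors within
    +-``ctcf_proximal_bp`` of a CTCF peak (both anchors by default, either
    anchor when ``ctcf_both_anchors=False``); ``non-CTCF`` — no CTCF peak
    within +-``ctcf_exclusion_bp`` of either anchor; loops falling in the gap
    between the two rules are labeled ``ambiguous``.  Independently, a loop is
    ``active`` (``repressive``) when either anchor overlaps an active
    (repressive) histone-mark peak, ``tss_loop`` when a TSS lies within
    ``tss_bp`` of either anchor, and ``de_novo_h3k9me3`` when it is unique to
    a condition in ``unique_conditions`` and overlaps an H3K9me3 peak.
    """
    unknown = set(peak_sets) - KNOWN_MARKS
    if unknown:
        raise ValueError(f"unknown mark keys: {sorted(unknown)}")
    loops = as_loop_frame(loops)
    n = len(loops)
    empty = pd.DataFrame({"chrom": [], "start": [], "end": []})
    ctcf = peak_sets.get("CTCF", empty)

    ctcf_class = np.empty(n, dtype=object)
    active = np.zeros(n, dtype=bool)
    repressive = np.zeros(n, dtype=bool)
    tss_loop = np.zeros(n, dtype=bool)
    h3k9me3 = np.zeros(n, dtype=bool)

    for i, rec in enumerate(loops.itertuples(index=False)):
        anchors = [
            (rec.chromA, int(rec.startA), int(rec.endA)),
            (rec.chromB, int(rec.startB), int(rec.endB)),
        ]
        dists = [
            _min_distance_to_peaks(c, s, e, ctcf) if len(ctcf) else np.inf
            for c, s, e in anchors
        ]
        near = [d <= ctcf_proximal_bp for d in dists]
        is_ctcf = all(near) if ctcf_both_anchors else any(near)
        if is_ctcf:
            ctcf_class[i] = "CTCF"
        elif all(d > ctcf_exclusion_bp for d in dists):
            ctcf_class[i] = "non-CTCF"
        else:
            ctcf_class[i] = "ambiguous"

        for mark in ACTIVE_MARKS:
            if mark in peak_sets and any(
                _min_distance_to_peaks(c, s, e, peak_sets[mark]) == 0
                for c, s, e in anchors
            ):
                active[i] = True
                break
        for mark in REPRESSIVE_MARKS:
            if mark in peak_sets and any(
                _min_distance_to_peaks(c, s, e, peak_sets[mark]) == 0
                for c, s, e in anchors
            ):
                repressive[i] = True
                break
        if "H3K9me3" in peak_sets:
            h3k9me3[i] = any(
                _min_distance_to_peaks(c, s, e, peak_sets["H3K9me3"]) == 0
                for c, s, e in anchors
            )
        if tss is not None and len(tss):
            tss_loop[i] = any(
                _min_distance_to_peaks(c, s, e, tss) <= tss_bp for c, s, e in anchors
            )

    out = loops.copy()
    out["ctcf_class"] = ctcf_class
    out["active"] = active
    out["repressive"] = repressive
    out["tss_loop"] = tss_loop
    if unique_conditions:
        out["de_novo_h3k9me3"] = h3k9me3 & out["source_condition"].isin(
            unique_conditions
        ).to_numpy()
    else:
        out["de_novo_h3k9me3"] = False
    return out


def pileup(
    cmap: ContactMap,
    loops: pd.DataFrame,
    flank_bp: int = 100_000,
    resolution: int | None = None,
) -> PileupResult:
    """Average O/E windows centered on loop anchor pixels.

    Loops are lifted to the map resolution; windows of (2 flank + 1)^2 pixels
    are averaged element-wise, excluding missing pixels.  Loops whose window
    exceeds the chromosome bounds are skipped and counted in ``n_skipped``.
    """
    resolution = resolution or cmap.resolution
    if resolution != cmap.resolution:
        raise ValueError("loops must be piled on a map at their own resolution")
    flank = int(flank_bp // resolution)
    side = 2 * flank + 1
    loops = as_loop_frame(loops)
    O = oe(cmap)
    bins = cmap.bins
    chrom_start = {
        c: int(np.flatnonzero(bins["chrom"].to_numpy() == c)[0])
        for c in pd.unique(bins["chrom"])
    }
    chrom_n = {c: int((bins["chrom"] == c).sum()) for c in chrom_start}
    acc = np.zeros((side, side))
    cnt = np.zeros((side, side))
    n_used = 0
    n_skipped = 0
    for rec in loops.itertuples(index=False):
        if rec.chromA != rec.chromB or rec.chromA not in chrom_start:
            n_skipped += 1
            continue
        bi = int(_anchor_mid(np.array([rec.startA]), np.array([rec.endA]))[0] // resolution)
        bj = int(_anchor_mid(np.array([rec.startB]), np.array([rec.endB]))[0] // resolution)
        nloc = chrom_n[rec.chromA]
        if bi - flank < 0 or bj - flank < 0 or bi + flank >= nloc or bj + flank >= nloc:
            n_skipped += 1
            continue
        base = chrom_start[rec.chromA]
        win = O[
            base + bi - flank : base + bi + flank + 1,
            base + bj - flank : base + bj + flank + 1,
        ]
        good = np.isfinite(win)
        acc[good] += win[good]
        cnt[good] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no loops could be piled (all skipped)")
    with np.errstate(invalid="ignore"):
        matrix = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return PileupResult(matrix=matrix, n_loops=n_used, n_skipped=n_skipped)


def paired_pileup_test(pile_a: PileupResult, pile_b: PileupResult):
    """Paired two-tailed t-test over the central 3x3 pixels of two pile-ups.

    Returns (t, p, degenerate); zero-variance differences give t = 0, p = 1
    with the degenerate flag set.
    """
    if pile_a.matrix.shape != pile_b.matrix.shape:
        raise ValueError("pile-ups must share window geometry")
    a = pile_a.central_values
    b = pile_b.central_values
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return 0.0, 1.0, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False
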