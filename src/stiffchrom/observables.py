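"""Model-side observables: contact maps, trans-contact ratio, compartment
strength and radial positioning of simulated nuclei.

Contacts are defined geometrically: two beads are in contact in a stored
conformation when their center-to-center distance is below ``r_contact``
(self-pairs excluded; every unordered pair counted at most once per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .layout import ChainLayout
from .simulate import NucleusEnsemble


@dataclass
class SimContactMap:
    """Bead-resolution (or coarse-grained) contact counts from an ensemble.

    ``counts`` is a dense symmetric matrix with zero diagonal (self-contacts
    excluded by convention); aggregation over samples is additive.
    """

    counts: np.ndarray
    chain_of_bin: np.ndarray
    binsize_beads: int = 1
    label_of_bin: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")


@dataclass
class TransRatioResult:
    """Per-chain trans-contact ratios, trans / (cis + trans)."""

    per_chain_ratio: np.ndarray  # NaN where a chain had no contacts
    median: float = field(init=False)

    def __post_init__(self) -> None:
        vals = self.per_chain_ratio[np.isfinite(self.per_chain_ratio)]
        self.median = float(np.median(vals)) if len(vals) else float("nan")


@dataclass
class RadialProfile:
    """Distances of one bead class to the confinement boundary."""

    distances: np.ndarray  # R_confine - |x|, per bead per sample
    R_confine: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    def quantiles(self, q=(0.25, 0.5, 0.75)) -> np.ndarray:
        return np.quantile(self.distances, q)


def contact_pairs(positions: np.ndarray, r_contact: float) -> np.ndarray:
    """All unordered bead pairs closer than r_contact, as an (m, 2) array."""
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r_contact, output_type="ndarray")
    return pairs


def contacts_from_ensemble(
    ensemble: NucleusEnsemble, r_contact: float = 2.5, binsize_beads: int = 1
) -> SimContactMap:
    """Aggregate geometric contacts over all stored samples into a map.

    Each pair (i, j), i < j, contributes one count per stored sample in which
    the bead distance is strictly below ``r_contact``.  With
    ``binsize_beads > 1`` consecutive beads of the same chain are pooled into
    coarse bins (counts added).
    """
    if ensemble.samples is None or len(ensemble.samples) == 0:
        raise ValueError("ensemble has no stored samples; run the simulation first")
    n_per_chain = ensemble.layout.n_beads
    if n_per_chain % binsize_beads != 0:
        raise ValueError("binsize_beads must divide the chain length")
    nb = n_per_chain // binsize_beads
    n_bins = nb * ensemble.n_chains
    counts = np.zeros((n_bins, n_bins))
    bead_bin = (
        np.repeat(np.arange(ensemble.n_chains), n_per_chain) * nb
        + (np.tile(np.arange(n_per_chain), ensemble.n_chains) // binsize_beads)
    )
    for sample in ensemble.samples:
        pairs = contact_pairs(sample, r_contact)
        if len(pairs) == 0:
            continue
        bi = bead_bin[pairs[:, 0]]
        bj = bead_bin[pairs[:, 1]]
        np.add.at(counts, (bi, bj), 1.0)
        np.add.at(counts, (bj, bi), 1.0)
    np.fill_diagonal(counts, 0.0)  # self-contacts excluded by convention
    chain_of_bin = np.repeat(np.arange(ensemble.n_chains), nb)
    labels = ensemble.layout.label_codes
    label_of_bin = np.tile(labels[::binsize_beads][:nb], ensemble.n_chains)
    return SimContactMap(
        counts=counts,
        chain_of_bin=chain_of_bin,
        binsize_beads=binsize_beads,
        label_of_bin=label_of_bin,
    )


def trans_contact_ratio(sim_map: SimContactMap) -> TransRatioResult:
    """Per-chain fraction of contacts made with other chains.

    For chain c with T_c inter-chain and C_c intra-chain contacts the ratio
    is T_c / (T_c + C_c); chains with zero total contacts yield NaN
    (undefined, reported as missing rather than 0).
    """
    chains = np.unique(sim_map.chain_of_bin)
    ratios = np.empty(len(chains))
    for k, c in enumerate(chains):
        rows = sim_map.chain_of_bin == c
        sub = sim_map.counts[rows]
        cis = sub[:, rows].sum() / 2.0  # each intra pair counted twice
        trans = sub[:, ~rows].sum()
        tot = cis + trans
        ratios[k] = trans / tot if tot > 0 else np.nan
    return TransRatioResult(per_chain_ratio=ratios)


def _block_oe_means(
    counts: np.ndarray,
    chain_of_bin: np.ndarray,
    label_of_bin: np.ndarray,
    scope: str,
    min_sep: int = 1,
) -> tuple[float, float, float]:
    """Aggregate O/E over A-A, B-B and A-B bin pairs in the requested scope.

    cis expectation: mean contact count at each intra-chain bin separation,
    pooled over chains.  trans expectation: mean inter-chain pixel.  Each
    class enrichment is the ratio of summed observed to summed expected counts
    (ratio of sums, not mean of per-pixel ratios), which stays well-defined
    and unbiased when long-range pixels are sparse.  cis pairs closer than
    ``min_sep`` bins are excluded: within-domain packing is not compartment
    signal, and the data-driven expectation absorbs it.
    """
    n = counts.shape[0]
    same_chain = chain_of_bin[:, None] == chain_of_bin[None, :]
    eye = np.eye(n, dtype=bool)
    if scope == "cis":
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :])
        mask = same_chain & ~eye & (sep >= max(1, min_sep))
        if not mask.any():
            raise ValueError("no cis pairs at or beyond min_sep")
        max_sep = sep[mask].max()
        exp_at = np.zeros(max_sep + 1)
        for s in range(1, max_sep + 1):
            sel = mask & (sep == s)
            if sel.any():
                exp_at[s] = counts[sel].mean()
        expected = np.where(mask, exp_at[np.minimum(sep, max_sep)], 0.0)
    elif scope == "trans":
        mask = ~same_chain
        mean_trans = counts[mask].mean()
        if mean_trans <= 0:
            raise ValueError("no trans contacts; trans O/E undefined")
        expected = np.where(mask, mean_trans, 0.0)
    else:
        raise ValueError(f"scope must be 'cis' or 'trans', got {scope!r}")

    a = label_of_bin == 0
    b = label_of_bin == 1
    if not a.any() or not b.any():
        raise ValueError("both A and B bins are required")

    obs_in_scope = np.where(mask, counts, 0.0)

    def enrich(m1, m2):
        e = expected[np.ix_(m1, m2)].sum()
        if e <= 0:
            return np.nan
        return float(obs_in_scope[np.ix_(m1, m2)].sum() / e)

    return enrich(a, a), enrich(b, b), enrich(a, b)


def _min_class_run(label_of_bin: np.ndarray, chain_of_bin: np.ndarray) -> int:
    """Smallest contiguous A/B domain width (bins) across chains."""
    runs = []
    for c in np.unique(chain_of_bin):
        lab = label_of_bin[chain_of_bin == c]
        start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[start]:
                if lab[start] in (0, 1):
                    runs.append(i - start)
                start = i
    return min(runs) if runs else 1


def model_compartment_strength(
    sim_map: SimContactMap,
    layout: ChainLayout | None = None,
    scope: str = "cis",
    return_components: bool = False,
    min_sep_bins: int | None = None,
):
    """Compartment strength of a simulated map: (AA * BB) / AB^2 on O/E block means.

    Telomeric bins are excluded.  The observed/expected normalization uses the
    intra-chain distance-decay expectation for ``scope="cis"`` and the uniform
    inter-chain expectation for ``scope="trans"``.  By default every cis pair
    contributes (count-weighted over all separations); raise ``min_sep_bins``
    to restrict the score to inter-domain contacts, e.g. to one domain width
    when within-domain pairs carry no class contrast by construction.
    """
    if sim_map.label_of_bin is None:
        if layout is None:
            raise ValueError("label information required")
        nb = sim_map.counts.shape[0] // len(np.unique(sim_map.chain_of_bin))
        label_of_bin = np.tile(layout.label_codes[:nb], len(np.unique(sim_map.chain_of_bin)))
    else:
        label_of_bin = sim_map.label_of_bin
    keep = label_of_bin != 2  # drop TEL bins
    counts = sim_map.counts[np.ix_(keep, keep)]
    if min_sep_bins is None:
        min_sep_bins = 1
    aa, bb, ab = _block_oe_means(
        counts, sim_map.chain_of_bin[keep], label_of_bin[keep], scope,
        min_sep=min_sep_bins,
    )
    if ab <= 0 or not np.isfinite(ab):
        raise ValueError("heterotypic O/E mean is zero/undefined")
    strength = (aa * bb) / ab**2
    if return_components:
        return strength, {"AA": aa, "BB": bb, "AB": ab}
    return strength


def radial_positions(ensemble: NucleusEnsemble, bead_class: str) -> RadialProfile:
    """Distance to the confinement boundary for every bead of one class.

    d = R_confine - |x|, pooled over all stored samples (or the current
    conformation when no samples are stored).
    """
    from .layout import CLASS_CODES

    if bead_class not in CLASS_CODES:
        raise ValueError(f"unknown bead class {bead_class!r}")
    code = CLASS_CODES[bead_class]
    sel = ensemble.label_codes == code
    if not sel.any():
        raise ValueError(f"no beads of class {bead_class!r} in this layout")
    if ensemble.samples is not None and len(ensemble.samples):
        coords = ensemble.samples[:, sel, :].reshape(-1, 3)
    else:
        coords = ensemble.positions[sel]
    d = ensemble.R_confine - np.linalg.norm(coords, axis=1)
    return RadialProfile(distances=d, R_confine=ensemble.R_confine)
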