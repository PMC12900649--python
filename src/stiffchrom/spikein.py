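"""Spike-in calibrated normalization of read counts.

Samples sequenced with a fixed admixture of foreign-genome (spike-in) cells
can be compared after equalizing their effective spike-in depth: sample i
with m_i target-genome and h_i spike-in-genome reads receives a downsampling
factor dF_i = h_min / h_i, and its reads are Bernoulli-thinned with
probability dF_i.  After thinning, target signal is proportional to m_i / h_i
across samples in expectation, which is the quantity a global-shift design
needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_dF(table: pd.DataFrame, mode: str = "spike") -> pd.DataFrame:
    """Add per-sample downsampling factors to a (sample, m, h) table.

    ``mode="spike"`` (default): dF_i = h_min / h_i, equalizing effective
    spike-in depth.  ``mode="depth_corrected"`` additionally corrects for
    target-depth imbalance: dF_i = (h_min / h_i) * (m_i h_min) / (m_min h_i),
    clipped to (0, 1].  The mode is recorded in ``attrs`` and a ``mode``
    column.
    """
    for col in ("m", "h"):
        if col not in table.columns:
            raise ValueError(f"table missing column {col!r}")
        if (table[col] <= 0).any():
            raise ValueError(
                f"all {col} counts must be positive (zero spike-in or target "
                "coverage means the calibration failed)"
            )
    out = table.copy()
    h = out["h"].to_numpy(dtype=float)
    m = out["m"].to_numpy(dtype=float)
    if mode == "spike":
        dF = h.min() / h
    elif mode == "depth_corrected":
        dF = (h.min() / h) * (m * h.min()) / (m.min() * h)
        dF = np.minimum(dF / dF.max(), 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["dF"] = dF
    out["mode"] = mode
    out.attrs["mode"] = mode
    return out


def thin_reads(counts, dF: float, seed: int = 0) -> np.ndarray:
    """Binomially thin a count vector, keeping each unit with probability dF.

    The same Bernoulli contract applies to per-read thinning of alignment
    records; here counts are thinned element-wise, seeded and reproducible.
    dF = 1 is the identity.
    """
    if not (0 < dF <= 1):
        raise ValueError(f"dF must lie in (0, 1], got {dF}")
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if dF == 1.0:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.binomial(counts.astype(np.int64), dF)
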