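"""Readers and writers for the package's on-disk formats.

All genomic coordinates are 0-based half-open.  Contact maps round-trip
through either a cooler-style HDF5 container (bins / pixels / chroms groups)
or a pair of plain TSV tables (bins + upper-triangle COO pixels) for toy
scale; loops use BEDPE with resolution/condition extension columns; peaks
and TSS use 3-column BED.  Trajectories round-trip through an XYZ-like TSV
(sample, chain, bead, x, y, z) or a compact NPZ container.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .layout import ChainLayout
from .loops import LOOP_COLUMNS, as_loop_frame
from .mapcore import ContactMap
from .simulate import NucleusEnsemble

# ---------------------------------------------------------------- contact maps


def write_cool(cmap: ContactMap, path: str | Path) -> None:
    """Write a contact map to a cooler-style HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "stiffchrom-cool"
        f.attrs["resolution"] = cmap.resolution
        chroms = pd.unique(cmap.bins["chrom"])
        sizes = [int(cmap.bins.loc[cmap.bins["chrom"] == c, "end"].max()) for c in chroms]
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(chroms, dtype="S32"))
        g.create_dataset("length", data=np.array(sizes, dtype=np.int64))
        g = f.create_group("bins")
        chrom_id = {c: i for i, c in enumerate(chroms)}
        g.create_dataset(
            "chrom", data=cmap.bins["chrom"].map(chrom_id).to_numpy(np.int32)
        )
        g.create_dataset("start", data=cmap.bins["start"].to_numpy(np.int64))
        g.create_dataset("end", data=cmap.bins["end"].to_numpy(np.int64))
        if cmap.weights is not None:
            g.create_dataset("weight", data=cmap.weights)
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=cmap.pixels["bin1_id"].to_numpy(np.int64))
        g.create_dataset("bin2_id", data=cmap.pixels["bin2_id"].to_numpy(np.int64))
        g.create_dataset("count", data=cmap.pixels["count"].to_numpy())


def read_cool(path: str | Path) -> ContactMap:
    with h5py.File(path, "r") as f:
        names = [n.decode() for n in f["chroms/name"][:]]
        bins = pd.DataFrame(
            {
                "chrom": [names[i] for i in f["bins/chrom"][:]],
                "start": f["bins/start"][:],
                "end": f["bins/end"][:],
            }
        )
        weights = f["bins/weight"][:] if "weight" in f["bins"] else None
        pixels = pd.DataFrame(
            {
                "bin1_id": f["pixels/bin1_id"][:],
                "bin2_id": f["pixels/bin2_id"][:],
                "count": f["pixels/count"][:],
            }
        )
        resolution = int(f.attrs["resolution"])
    return ContactMap(bins=bins, pixels=pixels, resolution=resolution, weights=weights)


def write_map_tsv(cmap: ContactMap, stem: str | Path) -> tuple[Path, Path]:
    """Write bins and COO pixels as '<stem>.bins.tsv' / '<stem>.pixels.tsv'."""
    stem = Path(stem)
    bins_path = stem.with_suffix(stem.suffix + ".bins.tsv")
    pixels_path = stem.with_suffix(stem.suffix + ".pixels.tsv")
    bins = cmap.bins.copy()
    if cmap.weights is not None:
        bins["weight"] = cmap.weights
    bins.to_csv(bins_path, sep="\t", index=False)
    px = cmap.pixels.copy()
    px.to_csv(pixels_path, sep="\t", index=False)
    # resolution travels in a header comment of the pixel table
    with open(pixels_path) as fh:
        body = fh.read()
    with open(pixels_path, "w") as fh:
        fh.write(f"# resolution={cmap.resolution}\n{body}")
    return bins_path, pixels_path


def read_map_tsv(stem: str | Path) -> ContactMap:
    stem = Path(stem)
    bins_path = stem.with_suffix(stem.suffix + ".bins.tsv")
    pixels_path = stem.with_suffix(stem.suffix + ".pixels.tsv")
    bins = pd.read_csv(bins_path, sep="\t")
    with open(pixels_path) as fh:
        header = fh.readline()
    resolution = int(header.strip().split("=")[1])
    pixels = pd.read_csv(pixels_path, sep="\t", comment="#")
    weights = None
    if "weight" in bins.columns:
        weights = bins.pop("weight").to_numpy()
    return ContactMap(bins=bins, pixels=pixels, resolution=resolution, weights=weights)


# ------------------------------------------------------------------- intervals


def write_bedpe(loops: pd.DataFrame, path: str | Path) -> None:
    loops = as_loop_frame(loops)
    loops[LOOP_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(LOOP_COLUMNS)]
    df.columns = LOOP_COLUMNS[: df.shape[1]]
    return as_loop_frame(df)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


# ---------------------------------------------------------------- trajectories


def write_trajectory_tsv(ensemble: NucleusEnsemble, path: str | Path) -> None:
    """XYZ-like text: one row per (sample, chain, bead) with coordinates."""
    if ensemble.samples is None or len(ensemble.samples) == 0:
        samples = ensemble.positions[None, :, :]
    else:
        samples = ensemble.samples
    n_samples, N, _ = samples.shape
    n = ensemble.layout.n_beads
    rows = {
        "sample": np.repeat(np.arange(n_samples), N),
        "chain": np.tile(np.repeat(np.arange(ensemble.n_chains), n), n_samples),
        "bead": np.tile(np.tile(np.arange(n), ensemble.n_chains), n_samples),
        "x": samples[:, :, 0].ravel(),
        "y": samples[:, :, 1].ravel(),
        "z": samples[:, :, 2].ravel(),
    }
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(
            f"# n_chains={ensemble.n_chains} n_beads={n} "
            f"R_confine={ensemble.R_confine!r} seed={ensemble.replicate_seed} "
            f"bead_bp={ensemble.layout.bead_bp}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_trajectory_tsv(path: str | Path, layout: ChainLayout) -> NucleusEnsemble:
    with open(path) as fh:
        header = fh.readline().strip("# \n")
    meta = dict(kv.split("=") for kv in header.split())
    df = pd.read_csv(path, sep="\t", comment="#")
    n_chains = int(meta["n_chains"])
    n = int(meta["n_beads"])
    n_samples = df["sample"].nunique()
    coords = df[["x", "y", "z"]].to_numpy().reshape(n_samples, n_chains * n, 3)
    return NucleusEnsemble(
        layout=layout,
        n_chains=n_chains,
        R_confine=float(meta["R_confine"]),
        positions=coords[-1].copy(),
        replicate_seed=int(meta["seed"]),
        samples=coords,
    )


def write_trajectory_npz(ensemble: NucleusEnsemble, path: str | Path) -> None:
    """Compact binary container (for scratch use; text formats ship)."""
    np.savez_compressed(
        path,
        samples=ensemble.samples if ensemble.samples is not None else np.empty((0,)),
        positions=ensemble.positions,
        R_confine=ensemble.R_confine,
        n_chains=ensemble.n_chains,
        seed=ensemble.replicate_seed,
    )


def read_trajectory_npz(path: str | Path, layout: ChainLayout) -> NucleusEnsemble:
    with np.load(path) as z:
        samples = z["samples"]
        return NucleusEnsemble(
            layout=layout,
            n_chains=int(z["n_chains"]),
            R_confine=float(z["R_confine"]),
            positions=z["positions"],
            replicate_seed=int(z["seed"]),
            samples=samples if samples.ndim == 3 else None,
        )


# ---------------------------------------------------------------------- config


def read_config(path: str | Path) -> dict:
    """Flat TOML config with [layout], [energy], [dynamics], [fit] sections."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_config(cfg: dict, path: str | Path) -> None:
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, str):
            return f'"{v}"'
        return repr(v)

    lines = []
    scalars = {k: v for k, v in cfg.items() if not isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {fmt(v)}")
    for section, sub in cfg.items():
        if isinstance(sub, dict):
            lines.append(f"\n[{section}]")
            for k, v in sub.items():
                lines.append(f"{k} = {fmt(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


DEFAULT_CONFIG = {
    "layout": {
        "chain_bp": 20_000_000,
        "bead_bp": 5_000,
        "domain_bp": 1_500_000,
        "telomere_bp": 1_000_000,
    },
    "energy": {
        "E_AA": 0.8,
        "E_BB": 0.7,
        "K_theta_base": 1.0,
        "K_A_TSA": 18.0,
        "K_B_TSA": 3.0,
        "r_contact": 2.5,
    },
    "dynamics": {
        "n_chains": 20,
        "n_replicates": 30,
        "volume_fraction": 0.10,
        "dt": 0.005,
        "equilibration_fraction": 0.5,
    },
    "fit": {
        "grid_E": [0.2, 0.4, 0.6, 0.8, 1.0],
        "grid_K": [1.0, 3.0, 6.0, 12.0, 18.0],
    },
}
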