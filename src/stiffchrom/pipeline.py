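"""End-to-end workflows with a reproducible run manifest.

``run_model_workflow`` chains the polymer-model calibration: attraction fit
on a single chain (untreated preset), stiffness fit on the multichain system
(perturbed preset), then the headline observables (trans-contact ratio,
cis compartment strength under both presets, radial A/B positioning).

``run_map_workflow`` chains the contact-map analysis on synthetic (or
user-provided) data: depth matching, balancing, eigenvector + saddle,
loop dedup/classification, differential testing and per-class pile-ups.

Both write tidy TSV outputs plus a JSON manifest (config hash, seeds,
package version, per-output checksums); deterministic stages reproduce
identical checksums for identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .energy import EnergyModel, preset
from .fitting import SimConfig, fit_attraction, fit_stiffness
from .layout import build_chain_layout
from .loopdiff import THRESHOLD_PRESETS, count_loop_contacts, filter_diff_loops, nb_differential
from .loops import classify_loops, deduplicate_loops, paired_pileup_test, pileup
from .mapcore import (
    compartment_strength,
    eigen_compartments,
    ice_balance,
    match_cis_depth,
    saddle,
)
from .observables import (
    contacts_from_ensemble,
    model_compartment_strength,
    radial_positions,
    trans_contact_ratio,
)
from .simulate import init_system, run_simulation
from .synth import SyntheticTruth, plant_loops, synth_annotations, synth_contact_map


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.stages.setdefault(stage, {})[Path(path).name] = digest

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_model_workflow(
    outdir: str | Path,
    seed: int = 0,
    scale: float = 0.1,
    n_chains: int = 2,
    n_steps: int = 16_000,
    grid_E=(0.4, 0.8, 1.2),
    grid_K=(1.0, 3.0, 18.0),
    target_strength: float | None = None,
    target_trans_ratio: float | None = None,
    n_replicates: int = 2,
    dry_run: bool = False,
) -> dict:
    """Calibrate the polymer model and report its observables.

    With no explicit targets, the untreated-preset strength and the
    perturbed-preset trans ratio measured at the same problem size serve as
    self-consistent fitting targets (a demo of the two-stage protocol).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = {
        "seed": seed, "scale": scale, "n_chains": n_chains, "n_steps": n_steps,
        "grid_E": list(grid_E), "grid_K": list(grid_K),
        "n_replicates": n_replicates,
    }
    manifest = RunManifest(config_hash=_config_hash(config), seed=seed)
    if dry_run:
        manifest.write(outdir / "manifest.json")
        return {"manifest": str(outdir / "manifest.json"), "dry_run": True}

    layout = build_chain_layout()
    base = SimConfig(
        layout=layout, scale=scale, n_chains=n_chains, n_steps=n_steps, seed=seed
    )
    report: dict = {"config": config}

    def simulate_preset(em: EnergyModel, rep_seed: int):
        lay = base.effective_layout()
        ens = init_system(lay, n_chains, base.volume_fraction, seed=rep_seed)
        out = run_simulation(ens, em, n_steps, base.sample_every, seed=rep_seed + 1)
        return out, contacts_from_ensemble(out, r_contact=base.r_contact)

    # stage 1: attraction fit (single chain, untreated stiffness)
    if target_strength is None:
        em0 = preset("dmso").with_attraction(0.8, 0.8)
        _, cmap0 = simulate_preset(em0, seed + 11)
        target_strength = model_compartment_strength(cmap0, scope="cis")
    E_AA, E_BB, table_e = fit_attraction(
        target_strength, grid_E, grid_E, SimConfig(**{**base.__dict__, "n_chains": 1})
    )
    table_e.to_csv(outdir / "fit_attraction.tsv", sep="\t", index=False)
    manifest.record("fit_attraction", outdir / "fit_attraction.tsv")
    fitted = preset("dmso").with_attraction(E_AA, E_BB)
    report["fit_attraction"] = {"E_AA": E_AA, "E_BB": E_BB, "target": target_strength}

    # stage 2: stiffness fit (multichain, perturbed condition)
    if target_trans_ratio is None:
        em_tsa = preset("tsa").with_attraction(E_AA, E_BB)
        _, cmap_t = simulate_preset(em_tsa, seed + 23)
        target_trans_ratio = trans_contact_ratio(cmap_t).median
    K_A, K_B, table_k = fit_stiffness(
        target_trans_ratio, grid_K, grid_K, fitted, base
    )
    table_k.to_csv(outdir / "fit_stiffness.tsv", sep="\t", index=False)
    manifest.record("fit_stiffness", outdir / "fit_stiffness.tsv")
    report["fit_stiffness"] = {
        "K_A": K_A, "K_B": K_B, "target": target_trans_ratio,
    }

    # stage 3: observables under both presets
    rows = []
    for name in ("dmso", "tsa"):
        em = preset(name).with_attraction(E_AA, E_BB)
        for rep in range(n_replicates):
            out, cmap = simulate_preset(em, seed + 100 + 7 * rep)
            tr = trans_contact_ratio(cmap)
            strength, comp = model_compartment_strength(
                cmap, scope="cis", return_components=True
            )
            rows.append(
                {
                    "condition": name, "replicate": rep,
                    "median_trans_ratio": tr.median,
                    "cis_strength": strength,
                    "cis_AA": comp["AA"], "cis_BB": comp["BB"], "cis_AB": comp["AB"],
                    "mean_dist_to_periphery_A": radial_positions(out, "A").mean,
                    "mean_dist_to_periphery_B": radial_positions(out, "B").mean,
                }
            )
    obs = pd.DataFrame(rows)
    obs.to_csv(outdir / "observables.tsv", sep="\t", index=False)
    manifest.record("observables", outdir / "observables.tsv")

    by_cond = obs.groupby("condition").mean(numeric_only=True)
    report["observables"] = by_cond.to_dict(orient="index")
    report["strength_ordering_swapped"] = bool(
        by_cond.loc["dmso", "cis_AA"] >= by_cond.loc["dmso", "cis_BB"]
        and by_cond.loc["tsa", "cis_AA"] < by_cond.loc["tsa", "cis_BB"]
    )
    manifest.write(outdir / "manifest.json")
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    report["manifest"] = str(outdir / "manifest.json")
    return report


def run_map_workflow(
    outdir: str | Path,
    seed: int = 0,
    n_replicates: int = 5,
    depth: float = 6e7,
    n_loops: int = 60,
    diff_fraction: float = 0.3,
    diff_fold: float = 2.0,
    preset_name: str = "methods",
) -> dict:
    """Synthetic-data contact-map workflow with planted differential loops.

    Generates two conditions x ``n_replicates`` raw maps in which a fraction
    of planted loops double their enrichment in the second condition, then
    runs depth matching, balancing, compartment/saddle analysis, loop
    classification, NB differential testing and per-class pile-ups.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = {
        "seed": seed, "n_replicates": n_replicates, "depth": depth,
        "n_loops": n_loops, "diff_fraction": diff_fraction,
        "diff_fold": diff_fold, "preset": preset_name,
    }
    manifest = RunManifest(config_hash=_config_hash(config), seed=seed)
    rng = np.random.default_rng(seed)

    truth = plant_loops(SyntheticTruth(), n_loops=n_loops, seed=seed)
    n_diff = int(round(diff_fraction * n_loops))
    diff_idx = rng.choice(n_loops, size=n_diff, replace=False)
    truth_b = truth.loops.copy()
    truth_b.loc[diff_idx, "enrichment"] *= diff_fold
    from dataclasses import replace as dc_replace

    truth2 = dc_replace(truth, loops=truth_b)
    (outdir / "truth.json").write_text(truth.to_json())
    manifest.record("synth", outdir / "truth.json")

    maps = {}
    for cond, tr in (("condA", truth), ("condB", truth2)):
        for rep in range(n_replicates):
            rep_seed = seed + 1000 * (cond == "condB") + rep + 1
            maps[f"{cond}_r{rep + 1}"] = synth_contact_map(tr, depth, rep_seed)

    matched = match_cis_depth(list(maps.values()), seed=seed + 5)
    maps = dict(zip(maps.keys(), matched))

    # merged per-condition maps for balancing/saddle/pileup
    merged = {}
    for cond in ("condA", "condB"):
        ms = [m for k, m in maps.items() if k.startswith(cond)]
        total = ms[0].pixels.copy()
        for m in ms[1:]:
            total = (
                pd.concat([total, m.pixels])
                .groupby(["bin1_id", "bin2_id"], as_index=False)["count"]
                .sum()
            )
        merged[cond] = ms[0].with_pixels(total)
        ice_balance(merged[cond])

    ref_track = truth.compartment_track()
    sad_rows = []
    for cond, cmap in merged.items():
        track = eigen_compartments(cmap, ref_track)
        prof = saddle(cmap, track.values, n_quantiles=10, scope="cis")
        sad_rows.append(
            {"condition": cond, "scope": "cis",
             "strength": compartment_strength(prof)}
        )
    pd.DataFrame(sad_rows).to_csv(outdir / "saddle_strength.tsv", sep="\t", index=False)
    manifest.record("saddle", outdir / "saddle_strength.tsv")

    # loop list from truth anchors (loop detection itself is out of scope)
    res = truth.resolution
    loops = pd.DataFrame(
        {
            "chromA": truth.loops["chrom"],
            "startA": truth.loops["bin1"] * res,
            "endA": (truth.loops["bin1"] + 1) * res,
            "chromB": truth.loops["chrom"],
            "startB": truth.loops["bin2"] * res,
            "endB": (truth.loops["bin2"] + 1) * res,
            "resolution_bp": res,
            "source_condition": "condA",
        }
    )
    loops = deduplicate_loops(loops)
    peak_sets, tss = synth_annotations(truth, seed=seed + 7)
    classified = classify_loops(loops, peak_sets, tss)
    classified.to_csv(outdir / "loops_classified.tsv", sep="\t", index=False)
    manifest.record("classify", outdir / "loops_classified.tsv")

    table = count_loop_contacts(maps, loops)
    design = {k: ("condA" if k.startswith("condA") else "condB") for k in maps}
    # after depth matching the map totals are the right normalization; the
    # small loop table itself is not a stable median-of-ratios reference
    map_totals = pd.Series({k: m.cis_total() for k, m in maps.items()})
    records = nb_differential(
        table, design, "condA", "condB", sample_size_factors=map_totals
    )
    records.to_csv(outdir / "diff_loops.tsv", sep="\t")
    manifest.record("diff", outdir / "diff_loops.tsv")
    kept = filter_diff_loops(records, **THRESHOLD_PRESETS[preset_name])

    # truth keyed by loop id: dedup may merge or reorder planted records
    diff_ids = set()
    for k in diff_idx:
        rec = truth.loops.iloc[int(k)]
        a, b = int(rec["bin1"]) * res, int(rec["bin2"]) * res
        diff_ids.add(
            f"{rec['chrom']}:{a}-{a + res}|{rec['chrom']}:{b}-{b + res}"
        )
    true_diff = records.index.isin(diff_ids)
    called = records.index.isin(kept.index)
    sensitivity = float(called[true_diff].mean()) if true_diff.any() else float("nan")
    fdr = float((~true_diff[called]).mean()) if called.any() else 0.0

    pile_rows = []
    for cls in ("CTCF", "non-CTCF"):
        sub = classified[classified["ctcf_class"] == cls]
        if len(sub) == 0:
            continue
        piles = {}
        for cond, cmap in merged.items():
            piles[cond] = pileup(cmap, sub, flank_bp=5 * res)
        t, p, degen = paired_pileup_test(piles["condA"], piles["condB"])
        pile_rows.append(
            {
                "class": cls, "n_loops": len(sub),
                "score_condA": piles["condA"].central_score,
                "score_condB": piles["condB"].central_score,
                "t": t, "p": p, "degenerate": degen,
            }
        )
    pd.DataFrame(pile_rows).to_csv(outdir / "pileups.tsv", sep="\t", index=False)
    manifest.record("pileup", outdir / "pileups.tsv")
    manifest.write(outdir / "manifest.json")

    report = {
        "config": config,
        "n_loops": int(len(loops)),
        "n_called": int(called.sum()),
        "sensitivity": sensitivity,
        "fdr": fdr,
        "saddle": sad_rows,
        "pileups": pile_rows,
        "manifest": str(outdir / "manifest.json"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
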