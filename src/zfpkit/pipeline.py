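"""End-to-end orchestration: simulate inputs, run every analysis stage,
write per-module TSVs and a run manifest.

The run is a pure function of the config: the manifest records the
package version, a hash of the resolved config, and the seed, and a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import binding, colocalization, kd_events, kinetics, overlap, rbns, reporters
from . import simulate as sim
from .io_formats import write_bed12, write_narrowpeak, write_windows

DEFAULT_CONFIG = {
    "seed": 0,
    "n_genes": 150,
    "n_windows": 2000,
    "n_peaks": 600,
    "planted_feature": "3'UTR",
    "planted_or": 8.0,
    "batch_means": {"A": 100.0, "B": 1000.0},
    "outlier_excess": 0.5,
    "rbns_consensus": "GAAGA",
    "rbns_fraction": 0.3,
    "rbns_reads": 20000,
    "slam_genes": 100,
    "slam_depth": 1000.0,
    "tethering_effect": 2.0,
    "out_dir": "zfpkit_run",
}


def validate_config(config: dict) -> dict:
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **config}
    return merged


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict) -> Path:
    """Run the full synthetic-scenario pipeline; returns the output dir."""
    config = validate_config(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    cfg = sim.SimConfig(seed=seed, n_genes=int(config["n_genes"]))

    # annotation + binding
    genes = sim.make_annotation(cfg)
    write_bed12(genes.values(), out / "genes.bed12")
    ip, bg, peaks, btruth = sim.simulate_binding(
        cfg, genes, planted_feature=config["planted_feature"],
        planted_or=float(config["planted_or"]), n_windows=int(config["n_windows"]),
        n_peaks=int(config["n_peaks"]))
    binding.annotate_windows(ip, genes)
    binding.annotate_windows(bg, genes)
    write_windows(ip, out / "windows.bed")
    write_narrowpeak(peaks, out / "peaks.narrowPeak")
    enr = binding.feature_enrichment_odds(ip, bg, config["planted_feature"])
    pd.DataFrame([dataclasses.asdict(enr)]).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # knockdown event counts + residuals
    matrix, _tables, ktruth = sim.simulate_kd_tables(
        cfg, {k: float(v) for k, v in config["batch_means"].items()},
        outlier_zfps={"OUTLIER": (list(config["batch_means"])[0],
                                  float(config["outlier_excess"]))})
    matrix.to_csv(out / "event_counts.tsv", sep="\t", index=False)
    residuals = []
    for et in ("DEG", "ASE", "APAE"):
        residuals += kd_events.fit_batch_residuals(matrix, et)
    pd.DataFrame([dataclasses.asdict(r) for r in residuals]).to_csv(
        out / "residuals.tsv", sep="\t", index=False)

    # RBNS
    pwm = sim.consensus_pwm(config["rbns_consensus"])
    pd_reads, in_reads, _ = sim.simulate_rbns(
        cfg, pwm, planted_fraction=float(config["rbns_fraction"]),
        n_reads=int(config["rbns_reads"]))
    enr_table, groups, pwms = rbns.derive_motif(pd_reads, in_reads)
    enr_table.head(50).to_csv(out / "rbns_enrichment.tsv", sep="\t", index=False)
    pwm_df = pd.DataFrame(pwms[0].matrix, columns=list(rbns.RNA_ALPHABET))
    pwm_df.insert(0, "position", np.arange(len(pwm_df)))
    pwm_df.to_csv(out / "rbns_pwm.tsv", sep="\t", index=False)

    # SLAM kinetics
    rng = np.random.default_rng(seed)
    hls = {f"G{i:04d}": float(h) for i, h in
           enumerate(rng.uniform(1, 12, size=int(config["slam_genes"])))}
    slam_df, _ = sim.simulate_slam(cfg, hls, depth=float(config["slam_depth"]))
    series = kinetics.read_slam_table(slam_df)
    fits = kinetics.fit_all(kinetics.filter_slam_genes(series))
    pd.DataFrame([dataclasses.asdict(f) for f in fits.values()]).to_csv(
        out / "decay_fits.tsv", sep="\t", index=False)

    # tethering
    teth_df, _ = sim.simulate_tethering(
        cfg, {"ZFP_TEST": float(config["tethering_effect"])}, reps=3)
    wells = [reporters.LuminescenceWell(r.construct_id, r.replicate, r.firefly, r.renilla)
             for r in teth_df.itertuples(index=False)]
    norm = reporters.normalize_ratios(wells)
    res = reporters.tethering_test(norm["ZFP_TEST"], norm["control"],
                                   construct_id="ZFP_TEST")
    pd.DataFrame([dataclasses.asdict(res)]).to_csv(out / "tethering.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config,
        "outputs": sorted(p.name for p in out.iterdir() if p.suffix in (".tsv", ".bed", ".bed12", ".narrowPeak")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
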