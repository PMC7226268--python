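"""Sweep orchestration: build -> simulate -> statistics -> information flow.

Runs the constant-drive protocol over a grid of synaptic strengths J and
hierarchical levels H for one or more seeds, computing per grid point the
mean rate, Fano factor, correlation time and (optionally) the microscopic
and macroscopic information measures, and aggregates the per-point records
into tidy tables.

The default scale is reduced (N = 2^13 with the full-scale in-degree
K = N_full * eps preserved by raising eps); the full-scale preset
(N = 2^17, eps = 0.01, K_spectrum = K_pairs = 10,000, 500 macro pairs)
is available but sized for a cluster, not a desk run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import info, stats
from .simulate import NeuronParams, SimConfig, SynapseParams, simulate, scaled_connectivity
from .topology import TopologyConfig, build_hierarchy
from .io import save_spikes

__all__ = ["SweepConfig", "run_sweep", "aggregate", "full_scale_config", "reduced_config"]


@dataclass
class SweepConfig:
    """Parameter grid and sampling sizes for a protocol sweep."""

    j_values: list = field(default_factory=lambda: [round(0.05 * k, 2) for k in range(21)])
    h_values: list = field(default_factory=lambda: list(range(10)))
    seeds: list = field(default_factory=lambda: [0])
    n_neurons: int = 2 ** 13
    scaling: str = "fixed_indegree"  # or "fixed_eps"
    t_total: float = 2000.0
    k_spectrum: int = 1000
    k_pairs_te: int = 0  # 0 disables the microscopic <TE> (expensive)
    k_macro_pairs: int = 100
    compute_macro: bool = True
    persist_rasters: bool = False
    out_dir: str | None = None

    def validate(self) -> None:
        if any(not 0.0 <= j <= 1.0 for j in self.j_values):
            raise ValueError("J values must lie in [0, 1]")
        if any(h > np.log2(self.n_neurons) for h in self.h_values):
            raise ValueError("H exceeds log2(N)")
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def full_scale_config() -> SweepConfig:
    """Publication-scale preset (N = 2^17; hours of compute per point)."""
    return SweepConfig(
        n_neurons=2 ** 17,
        scaling="fixed_eps",
        k_spectrum=10_000,
        k_pairs_te=10_000,
        k_macro_pairs=500,
    )


def reduced_config(n_neurons: int = 2 ** 13) -> SweepConfig:
    return SweepConfig(n_neurons=n_neurons)


def _point_record(cfg: SweepConfig, j: float, h: int, seed: int) -> dict:
    eps = scaled_connectivity(cfg.n_neurons, cfg.scaling)
    topo = build_hierarchy(
        TopologyConfig(
            n_neurons=cfg.n_neurons, connectivity=eps, hierarchy_level=h, seed=seed
        )
    )
    spk = simulate(
        topo,
        neuron=NeuronParams(),
        synapse=SynapseParams(j_exc=j),
        sim=SimConfig(t_total=cfg.t_total, seed=seed),
    )
    rec = {
        "J": j, "H": h, "seed": seed,
        "n_neurons": cfg.n_neurons, "eps": eps,
        "n_spikes": int(spk.n_spikes),
        "nu": spk.rate(),
    }
    if spk.n_spikes:
        spec = stats.averaged_spectrum(spk, sample_size=cfg.k_spectrum, seed=seed)
        rec.update(nu_sampled=spec.nu, fano=spec.fano, tau_c=spec.tau_c)
    else:
        rec.update(nu_sampled=0.0, fano=np.nan, tau_c=np.nan)
    if cfg.k_pairs_te:
        rec["te_micro"] = info.network_te(spk, n_pairs=cfg.k_pairs_te, seed=seed)
    if cfg.compute_macro and h >= 1 and spk.n_spikes:
        rates = info.module_activity(spk, topo)
        rec["te_macro"] = info.macro_te_network(
            rates, n_pairs=cfg.k_macro_pairs, seed=seed
        )
        rec["mi_adjacent"] = info.adjacent_mi(rates)
    if cfg.persist_rasters and cfg.out_dir:
        save_spikes(spk, Path(cfg.out_dir) / f"raster_J{j}_H{h}_s{seed}")
    return rec


def run_sweep(cfg: SweepConfig, progress: bool = False) -> pd.DataFrame:
    """Execute the full grid; restartable when ``out_dir`` is set (completed
    points are loaded from their JSON record instead of recomputed)."""
    cfg.validate()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        (out / "per_point").mkdir(parents=True, exist_ok=True)
    records = []
    for seed in cfg.seeds:
        for h in cfg.h_values:
            for j in cfg.j_values:
                tag = f"J{j}_H{h}_s{seed}"
                cache = out / "per_point" / f"{tag}.json" if out else None
                if cache and cache.exists():
                    records.append(json.loads(cache.read_text()))
                    continue
                if progress:
                    print(f"[sweep] {tag}", flush=True)
                rec = _point_record(cfg, j, h, seed)
                if cache:
                    cache.write_text(json.dumps(rec))
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    if out:
        df.to_csv(out / "grid_summary.csv", index=False)
        (out / "sweep_config.json").write_text(json.dumps(asdict(cfg)))
    return df


def aggregate(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mean/SD per (J, H) across seeds, and per-H distribution summaries of
    the macroscopic TE across J and seeds (boxplot-style quartiles).

    With a single seed the SD columns are left as NA, not zero.
    """
    value_cols = [
        c for c in ("nu", "fano", "tau_c", "te_micro", "te_macro", "mi_adjacent")
        if c in results.columns
    ]
    g = results.groupby(["J", "H"])[value_cols]
    mean = g.mean()
    sd = g.std(ddof=1)  # NaN for a single seed by construction
    per_point = mean.join(sd, lsuffix="_mean", rsuffix="_sd").reset_index()

    per_h = None
    if "te_macro" in results.columns:
        per_h = (
            results.dropna(subset=["te_macro"])
            .groupby("H")["te_macro"]
            .agg(
                mean="mean",
                var="var",
                q25=lambda v: v.quantile(0.25),
                median="median",
                q75=lambda v: v.quantile(0.75),
            )
            .reset_index()
        )
    return {"per_point": per_point, "per_h": per_h}
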