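"""Plain-text persistence for spike rasters and rate series.

Rasters round-trip as a two-column headered TSV (``neuron_id<TAB>time_ms``,
sorted by time) with a JSON metadata sidecar; rate series and summary
statistics as headered CSV / JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import SpikeData

__all__ = ["save_spikes", "load_spikes", "save_summary", "load_summary"]


def save_spikes(spikes: SpikeData, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "spikes.tsv", "w") as fh:
        fh.write("neuron_id\ttime_ms\n")
        for j, t in zip(spikes.neuron_ids, spikes.times):
            fh.write(f"{j}\t{t:.6g}\n")
    meta = {
        "n_neurons": spikes.n_neurons,
        "t_total": spikes.t_total,
        "dt": spikes.dt,
        "meta": spikes.meta,
    }
    (out / "spikes.json").write_text(json.dumps(meta))
    return out


def load_spikes(in_dir: str | Path) -> SpikeData:
    src = Path(in_dir)
    meta = json.loads((src / "spikes.json").read_text())
    body = (src / "spikes.tsv").read_text().splitlines()[1:]
    if body:
        data = np.loadtxt(body, ndmin=2)
    else:
        data = np.empty((0, 2))
    if data.size:
        ids = data[:, 0].astype(np.int64)
        times = data[:, 1].astype(np.float64)
    else:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0, dtype=np.float64)
    return SpikeData(
        neuron_ids=ids,
        times=times,
        n_neurons=int(meta["n_neurons"]),
        t_total=float(meta["t_total"]),
        dt=float(meta["dt"]),
        meta=meta.get("meta", {}),
    )


def save_summary(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return path


def load_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
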