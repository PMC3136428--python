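"""State map of the network over the [Mg2+] x injected-current plane.

``sweep`` runs a constant-current simulation per grid cell, computes the
oscillation index (OI), POT-representation index (PI), peak frequency and
mean granule rate, and ``classify`` assigns each cell one of four dynamical
states:

* **I**  synchronized oscillation (high OI),
* **II** POT-representing (high PI at a moderate 1-20 Hz granule rate),
* **III** metastable (a transient oscillation at stimulus onset that decays
  into a POT-representing drift),
* **IV** uniform firing (neither index high).

Cells are cached on disk keyed by their full configuration hash, so an
interrupted sweep resumes where it stopped and re-running a finished sweep
is a no-op.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import constant_protocol, run_protocol
from .metrics import compute_metrics
from .network import NetworkGraph
from .params import ModelParams, dump_params

__all__ = ["StateLabel", "SweepGrid", "sweep", "classify", "goc_ratio_sweep"]


class StateLabel(str, Enum):
    I = "I_synchronized_oscillation"
    II = "II_pot_representing"
    III = "III_metastable"
    IV = "IV_uniform_firing"


@dataclass
class SweepGrid:
    """Long-format sweep results: one row per (mg, i, seed)."""

    mg_values: np.ndarray
    i_values: np.ndarray
    results: pd.DataFrame
    duration_s: float

    def cell(self, mg: float, i: float) -> pd.DataFrame:
        r = self.results
        return r[(np.isclose(r.mg_mM, mg)) & (np.isclose(r.i_pA, i))]

    def pivot(self, value: str = "oi") -> pd.DataFrame:
        return self.results.pivot_table(index="i_pA", columns="mg_mM",
                                        values=value, aggfunc="mean")


def classify(cell_result: dict, oi_thresh: float = 0.5,
             pi_thresh: float = 0.5,
             rate_bounds: tuple[float, float] = (1.0, 20.0)) -> StateLabel:
    """Assign a dynamical-state label from one cell's metrics.

    ``cell_result`` needs ``oi``, ``pi`` and ``rate``; an optional
    ``oi_early`` (OI over the first quarter of the window) detects the
    metastable transient-oscillation-then-POT signature.
    """
    oi = cell_result.get("oi", np.nan)
    pi = cell_result.get("pi", np.nan)
    rate = cell_result.get("rate", np.nan)
    oi_early = cell_result.get("oi_early", np.nan)
    pot_like = (np.isfinite(pi) and pi >= pi_thresh
                and rate_bounds[0] <= rate <= rate_bounds[1])
    if (pot_like and np.isfinite(oi_early) and oi_early >= oi_thresh
            and (not np.isfinite(oi) or oi < oi_thresh)):
        return StateLabel.III
    if pot_like:
        return StateLabel.II
    if np.isfinite(oi) and oi >= oi_thresh:
        return StateLabel.I
    return StateLabel.IV


def _cell_key(graph: NetworkGraph, params: ModelParams, mg: float, i: float,
              duration: float, seed: int, dt_us: float) -> str:
    key = json.dumps([graph.geometry_hash(), graph.seed, graph.p,
                      dump_params(params), float(mg), float(i),
                      float(duration), int(seed), float(dt_us)])
    return hashlib.sha256(key.encode()).hexdigest()[:16]


def _run_cell(graph: NetworkGraph, params: ModelParams, mg: float, i: float,
              duration: float, seed: int, dt_us: float) -> dict:
    protocol = constant_protocol(i, duration_s=duration, mg_mM=mg)
    try:
        result = run_protocol(graph, params, protocol, dt_us=dt_us, seed=seed)
    except (FloatingPointError, RuntimeError) as exc:
        return {"mg_mM": mg, "i_pA": i, "seed": seed, "oi": np.nan,
                "pi": np.nan, "f_max": np.nan, "rate": np.nan,
                "oi_early": np.nan, "state": StateLabel.IV.value,
                "flags": f"simulation failure: {exc}"}
    m = compute_metrics(result.grc, (0.0, duration))
    oi_early = np.nan
    if duration >= 1.0:
        early = compute_metrics(result.grc, (0.0, duration / 4.0))
        oi_early = early.oi
    row = {"mg_mM": mg, "i_pA": i, "seed": seed, "oi": m.oi, "pi": m.pi,
           "f_max": m.f_max, "rate": m.mean_rate, "oi_early": oi_early,
           "flags": "; ".join(m.flags)}
    row["state"] = classify({"oi": m.oi, "pi": m.pi, "rate": m.mean_rate,
                             "oi_early": oi_early}).value
    return row


def sweep(graph: NetworkGraph, params: ModelParams,
          mg_values, i_values, duration: float = 2.0,
          seeds=(0,), dt_us: float = 20.0,
          cache_dir: str | Path | None = None) -> SweepGrid:
    """OI/PI/rate grid over ([Mg2+], I_MF); per-cell failures are recorded
    and the sweep continues."""
    mg_values = np.atleast_1d(np.asarray(mg_values, dtype=float))
    i_values = np.atleast_1d(np.asarray(i_values, dtype=float))
    seeds = tuple(int(s) for s in np.atleast_1d(seeds))
    if not seeds:
        raise ValueError("need at least one seed per cell")
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for mg in mg_values:
        for i in i_values:
            for seed in seeds:
                if cache is not None:
                    key = _cell_key(graph, params, mg, i, duration, seed,
                                    dt_us)
                    path = cache / f"cell_{key}.json"
                    if path.exists():
                        rows.append(json.loads(path.read_text()))
                        continue
                row = _run_cell(graph, params, mg, i, duration, seed, dt_us)
                if cache is not None:
                    path.write_text(json.dumps(row))
                rows.append(row)
    return SweepGrid(mg_values=mg_values, i_values=i_values,
                     results=pd.DataFrame(rows), duration_s=duration)


def goc_ratio_sweep(graph: NetworkGraph, params: ModelParams,
                    ratio_values, i_grc: float = 10.7,
                    duration: float = 2.0, mg_mM: float = 1.2,
                    seed: int = 0, dt_us: float = 20.0) -> pd.DataFrame:
    """OI and PI versus the Goc/grc injected-current ratio.

    Probes the effect of direct mossy-fiber drive onto Golgi somata (omitted
    in the default model, i.e. ratio 0) without modeling MF->Goc synapses.
    """
    rows = []
    for ratio in np.atleast_1d(np.asarray(ratio_values, dtype=float)):
        if ratio < 0:
            raise ValueError("ratio must be >= 0")
        protocol = constant_protocol(i_grc, duration_s=duration, mg_mM=mg_mM,
                                     goc_current_ratio=float(ratio))
        result = run_protocol(graph, params, protocol, dt_us=dt_us, seed=seed)
        m = compute_metrics(result.grc, (0.0, duration))
        rows.append({"ratio": float(ratio), "i_pA": i_grc, "oi": m.oi,
                     "pi": m.pi, "f_max": m.f_max, "rate": m.mean_rate})
    return pd.DataFrame(rows)
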