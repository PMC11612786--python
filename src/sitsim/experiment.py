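"""Factorial experiments: replicated scenario sets, parameter grids,
aggregation, and CSV output.

A grid crosses pest traits (F, Csterile, Csperm) with biocide traits
(Ph, Pv, Pc, LT, Virulence).  Replicate seeds are derived by stable hashing
of the base seed and the pest-cell values, so biocide combinations within a
pest cell share their initial conditions, rows are unaffected when further
grid values are added, and the control run and SIT sweep — which the biocide
parameters cannot influence — are computed once per pest cell and reused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SimParams
from .scenarios import FAIL, ScenarioResult, gain, run_scenario_set

__all__ = [
    "GridSpec",
    "stable_seed",
    "run_replicates",
    "results_to_frame",
    "summarize_replicates",
    "run_grid",
    "min_virulence_summary",
    "write_outputs",
]

logger = logging.getLogger("sitsim")

#: Pest-trait grid axes (determine the replicate seeds and the SIT outcome).
PEST_KEYS = ("F", "Csterile", "Csperm")
#: Biocide-trait grid axes (affect only the boosted scenario).
BIOCIDE_KEYS = ("Ph", "Pv", "LT", "Virulence", "Pc")
GRID_KEYS = PEST_KEYS + BIOCIDE_KEYS


def stable_seed(base_seed: int, *parts) -> int:
    """Deterministic seed below 2^31 derived from a base seed and values."""
    payload = repr((int(base_seed),) + tuple(parts)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 10**6)


@dataclass(frozen=True)
class GridSpec:
    """Explored value lists for the factorial experiment.

    Defaults are the canonical explored ranges: three levels each of
    horizontal and vertical transmission, five lethal times, four virulence
    levels, lekking on/off, low and high fecundity, three sterile-male
    competitiveness levels and all three sperm-competition regimes —
    6480 combinations.
    """

    F: tuple = (6.0, 45.0)
    Csterile: tuple = (0.5, 1.0, 2.0)
    Csperm: tuple = ("first", "last", "share")
    Ph: tuple = (0.1, 0.25, 0.5)
    Pv: tuple = (0.0, 0.25, 0.5)
    LT: tuple = (0.1, 0.25, 0.5, 0.75, 0.9)
    Virulence: tuple = (0.25, 0.5, 0.75, 1.0)
    Pc: tuple = (0.0, 0.25)
    n_replicates: int = 50
    base_seed: int = 1
    base_params: SimParams = SimParams()

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for key in GRID_KEYS:
            if not len(getattr(self, key)):
                raise ValueError(f"grid axis {key} is empty")

    @property
    def n_combinations(self) -> int:
        n = 1
        for key in GRID_KEYS:
            n *= len(getattr(self, key))
        return n

    def combinations(self):
        """Iterate parameter dicts in a stable (pest-major) order."""
        axes = [getattr(self, key) for key in GRID_KEYS]
        for values in itertools.product(*axes):
            yield dict(zip(GRID_KEYS, values))

    def subset(self, **fixed) -> "GridSpec":
        """Restrict axes to the given values (scalar or list per key)."""
        changes = {}
        for key, val in fixed.items():
            if key not in GRID_KEYS:
                raise KeyError(f"unknown grid axis {key!r}")
            vals = tuple(val) if isinstance(val, (tuple, list)) else (val,)
            allowed = getattr(self, key)
            bad = [v for v in vals if v not in allowed]
            if bad:
                raise ValueError(f"values {bad} not in grid axis {key}")
            changes[key] = vals
        return dataclasses.replace(self, **changes)


def run_replicates(params: SimParams, n_replicates: int, base_seed: int,
                   control_cache: dict | None = None,
                   sit_cache: dict | None = None) -> list[ScenarioResult]:
    """Run the full scenario protocol for seeds base_seed .. base_seed+n-1."""
    results = []
    for r in range(n_replicates):
        results.append(run_scenario_set(
            params, base_seed + r,
            control_cache=control_cache, sit_cache=sit_cache))
    return results


_REPLICATE_COLUMNS = (
    "seed", "t", "t_plus_1", "nb_generation", "t_fallback", "n_control_t1",
    "ratio_sit", "ratio_boosted", "sit_failed", "boosted_failed",
    "boosted_rescued", "G", "n_t1_sit", "n_t1_boosted",
)


def results_to_frame(results: list[ScenarioResult],
                     extra: dict | None = None) -> pd.DataFrame:
    """Per-replicate results as a tidy table (one row per seed).

    Failed sweeps are encoded as ratio -1 so the column stays integer.
    An empty result list yields a header-only table.
    """
    if not results:
        return pd.DataFrame(columns=list(extra or {}) + list(_REPLICATE_COLUMNS))
    rows = []
    for res in results:
        row = dict(extra or {})
        g = res.G
        row.update(
            seed=res.seed,
            t=res.timing.t,
            t_plus_1=res.timing.t_plus_1,
            nb_generation=res.timing.nb_generation,
            t_fallback=res.timing.t_fallback,
            n_control_t1=res.n_control_t1,
            ratio_sit=-1 if res.ratio_sit is FAIL else res.ratio_sit,
            ratio_boosted=-1 if res.ratio_boosted is FAIL else res.ratio_boosted,
            sit_failed=res.sit_failed,
            boosted_failed=res.boosted_failed,
            boosted_rescued=res.boosted_rescued,
            G=np.nan if g is None else g,
            n_t1_sit=json.dumps(res.n_t1_sit),
            n_t1_boosted=json.dumps(res.n_t1_boosted),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_frame(records) -> pd.DataFrame:
    """Daily records as a table, generation counts in ``gen_*`` columns
    (released sterile males under ``gen_released``)."""
    gens = sorted({g for rec in records for g in rec.counts_by_generation})
    rows = []
    for rec in records:
        row = {"day": rec.day, "N": rec.N_total, "pN": rec.pN,
               "n_sterile": rec.n_sterile,
               "n_contaminated": rec.n_contaminated}
        for g in gens:
            name = "gen_released" if g < 0 else f"gen_{g}"
            row[name] = rec.counts_by_generation.get(g, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_replicates(results: list[ScenarioResult]) -> dict:
    """Replicate-averaged summary of one parameter combination.

    Mean ratios average successful replicates only; mean G averages the
    replicates where G is defined (it is not when both scenarios fail, the
    SIT-failure convention G = 1 applies when only SIT fails).  The rescue
    fraction is the share of SIT-failure replicates in which boosted SIT
    succeeded.
    """
    n = len(results)
    sit_ok = [r.ratio_sit for r in results if r.ratio_sit is not FAIL]
    boo_ok = [r.ratio_boosted for r in results if r.ratio_boosted is not FAIL]
    gains = [r.G for r in results if r.G is not None]
    n_sit_fail = sum(r.sit_failed for r in results)
    n_rescued = sum(r.boosted_rescued for r in results)
    return {
        "n_replicates": n,
        "mean_ratio_sit": float(np.mean(sit_ok)) if sit_ok else np.nan,
        "mean_ratio_boosted": float(np.mean(boo_ok)) if boo_ok else np.nan,
        "mean_G": float(np.mean(gains)) if gains else np.nan,
        "sit_fail_fraction": n_sit_fail / n,
        "n_sit_fail": n_sit_fail,
        "n_boosted_fail": sum(r.boosted_failed for r in results),
        "boosted_rescue_fraction": (n_rescued / n_sit_fail
                                    if n_sit_fail else np.nan),
        "mean_t": float(np.mean([r.timing.t for r in results])),
        "mean_t_plus_1": float(np.mean([r.timing.t_plus_1 for r in results])),
    }


def run_grid(grid: GridSpec, collect_replicates: bool = False,
             progress: bool = False):
    """Run the factorial experiment.

    Returns a per-combination summary DataFrame (one row per combination),
    and additionally the per-replicate DataFrame when ``collect_replicates``.
    """
    summaries = []
    replicate_frames = []
    caches: dict[tuple, tuple[dict, dict]] = {}
    n_total = grid.n_combinations
    for i, combo in enumerate(grid.combinations()):
        params = grid.base_params.replace(**combo)
        cell = tuple(combo[k] for k in PEST_KEYS)
        control_cache, sit_cache = caches.setdefault(cell, ({}, {}))
        cell_seed = stable_seed(grid.base_seed, *cell)
        results = run_replicates(
            params, grid.n_replicates, cell_seed,
            control_cache=control_cache, sit_cache=sit_cache)
        row = dict(combo)
        row.update(summarize_replicates(results))
        row["base_seed"] = cell_seed
        summaries.append(row)
        if collect_replicates:
            replicate_frames.append(results_to_frame(results, extra=combo))
        if progress:
            logger.info("combination %d/%d %s", i + 1, n_total, combo)
    summary = pd.DataFrame(summaries)
    if collect_replicates:
        return summary, pd.concat(replicate_frames, ignore_index=True)
    return summary


def min_virulence_summary(summary: pd.DataFrame,
                          g_threshold: float = 0.1) -> pd.DataFrame:
    """Minimum virulence achieving a boosted-SIT gain above the threshold.

    For each cell of the remaining axes, the smallest explored virulence
    whose replicate-averaged G exceeds ``g_threshold``; NaN when no level
    qualifies.  Cells missing some virulence levels are flagged.
    """
    cell_keys = [k for k in GRID_KEYS if k != "Virulence"]
    n_levels = summary["Virulence"].nunique()
    rows = []
    for cell, block in summary.groupby(cell_keys, sort=True):
        qualifying = block.loc[block["mean_G"] > g_threshold, "Virulence"]
        rows.append(dict(
            zip(cell_keys, cell),
            min_virulence=(float(qualifying.min())
                           if not qualifying.empty else np.nan),
            complete=block["Virulence"].nunique() == n_levels,
        ))
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, metadata: dict) -> None:
    try:
        df.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(metadata, indent=2, default=str))
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def write_outputs(out_dir, params: SimParams | None = None,
                  trajectories: pd.DataFrame | None = None,
                  results: pd.DataFrame | None = None,
                  summaries: pd.DataFrame | None = None,
                  extra_meta: dict | None = None) -> dict[str, Path]:
    """Write the tabular output layers as CSV with JSON metadata sidecars.

    Layers: daily trajectories, per-replicate scenario results, and
    per-combination grid summaries; each sidecar records the full parameter
    set and software version.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"software": "sitsim", "version": __version__}
    if params is not None:
        meta["params"] = params.to_dict()
    meta.update(extra_meta or {})
    written = {}
    for name, df in (("trajectories", trajectories),
                     ("replicates", results),
                     ("grid_summary", summaries)):
        if df is not None:
            path = out / f"{name}.csv"
            _write_csv(df, path, meta)
            written[name] = path
    return written
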