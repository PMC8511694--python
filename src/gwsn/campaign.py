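"""Parameter-space sampling and multi-seed simulation campaigns.

A campaign samples the model's input box (uniformly, on a log10 scale
for the rate-like parameters, over inclusive integer ranges for N, F
and q), runs the checkpointed simulation protocol for several seeds per
parameter set, and assembles the training table: one row per
(parameter set, seed, checkpoint) holding the 10 parameters, the time
step t, the nine network properties, the per-run seed and the abort
flag.  Undefined statistics appear as empty CSV cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .model_core import (GWSNParams, PARAM_NAMES, SimulationProtocol, run)
from .netprops import PROPERTY_NAMES

logger = logging.getLogger("gwsn")

INPUT_COLUMNS = PARAM_NAMES + ("t",)
TABLE_COLUMNS = ("set_id",) + INPUT_COLUMNS + PROPERTY_NAMES + ("seed", "aborted")


@dataclass(frozen=True)
class RangeSpec:
    """One parameter's sampling rule: bounds, scale and integrality."""

    low: float
    high: float
    scale: str = "linear"  # "linear" | "log10"
    integer: bool = False

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low {self.low} > high {self.high}")
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"scale must be 'linear' or 'log10', got {self.scale!r}")
        if self.scale == "log10" and self.low <= 0:
            raise ValueError("log10 scale requires low > 0")

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        if self.integer:
            return rng.integers(int(self.low), int(self.high) + 1, size=size).astype(float)
        if self.scale == "log10":
            return 10.0 ** rng.uniform(np.log10(self.low), np.log10(self.high), size=size)
        return rng.uniform(self.low, self.high, size=size)


def default_ranges() -> dict[str, RangeSpec]:
    """The model's standard sampling box (log10 for the starred rates)."""
    return {
        "N": RangeSpec(2_000, 5_000, integer=True),
        "F": RangeSpec(1, 10, integer=True),
        "q": RangeSpec(1, 10, integer=True),
        "alpha": RangeSpec(0.0, 4.0),
        "p_r": RangeSpec(1e-5, 1e-2, scale="log10"),
        "p_delta": RangeSpec(1e-3, 1e-1, scale="log10"),
        "w_r": RangeSpec(0.0, 2.0),
        "p_nd": RangeSpec(1e-5, 1e-2, scale="log10"),
        "p_ld": RangeSpec(1e-6, 1e-3, scale="log10"),
        "A": RangeSpec(1e-5, 1e-1, scale="log10"),
    }


def sample_parameter_sets(n: int, ranges: dict[str, RangeSpec] | None = None,
                          rng: np.random.Generator | None = None,
                          w0: float = 1.0, w_th: float = 0.5) -> list[GWSNParams]:
    """Draw n i.i.d. parameter sets, each coordinate uniform on its scale."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = default_ranges()
    missing = set(PARAM_NAMES) - set(ranges)
    if missing:
        raise ValueError(f"ranges missing parameters: {sorted(missing)}")
    if rng is None:
        rng = np.random.default_rng()
    cols = {name: ranges[name].sample(n, rng) for name in PARAM_NAMES}
    out = []
    for i in range(n):
        kw = {name: cols[name][i] for name in PARAM_NAMES}
        for int_name in ("N", "F", "q"):
            kw[int_name] = int(round(kw[int_name]))
        out.append(GWSNParams(w0=w0, w_th=w_th, **kw))
    return out


def run_seed(set_id: int, seed_id: int, master_seed: int) -> int:
    """Counter-based per-run seed: SeedSequence(master, spawn_key=(set, seed))."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(set_id, seed_id))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _rows_for_run(set_id, params, protocol, seed):
    result = run(params, replace(protocol, seed=seed))
    rows = []
    base = {"set_id": set_id, **{k: getattr(params, k) for k in PARAM_NAMES},
            "seed": seed, "aborted": result.aborted}
    for t, props in result.checkpoints:
        rows.append({**base, "t": t, **props.as_dict()})
    return rows, result.aborted


def run_campaign(param_sets, protocol: SimulationProtocol, n_seeds: int = 5,
                 master_seed: int = 0, n_jobs: int = 1,
                 progress: bool = False) -> pd.DataFrame:
    """Run every (parameter set, seed) pair and assemble the training table.

    Rows recorded before an abort are retained with the abort flag set;
    a run that fails outright is logged and skipped, never silently
    dropped.  With ``n_jobs > 1`` runs execute in parallel worker
    processes; results are identical to the serial order because every
    run's seed is derived only from (master_seed, set index, seed index).
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    jobs = [(s, k, params, run_seed(s, k, master_seed))
            for s, params in enumerate(param_sets) for k in range(n_seeds)]
    all_rows: list[dict] = []
    n_failed = 0

    if n_jobs > 1:
        from joblib import Parallel, delayed
        outs = Parallel(n_jobs=n_jobs)(
            delayed(_rows_for_run)(s, p, protocol, seed) for s, k, p, seed in jobs)
        for (s, k, p, seed), out in zip(jobs, outs):
            all_rows.extend(out[0])
    else:
        it = jobs
        if progress:
            try:
                from tqdm import tqdm
                it = tqdm(jobs, desc="campaign")
            except ImportError:
                pass
        for s, k, params, seed in it:
            try:
                rows, _ = _rows_for_run(s, params, protocol, seed)
            except Exception:
                n_failed += 1
                logger.exception("run failed (set=%d seed_id=%d); skipping", s, k)
                continue
            all_rows.extend(rows)
    if n_failed:
        logger.warning("%d of %d runs failed and were skipped", n_failed, len(jobs))
    df = pd.DataFrame(all_rows, columns=list(TABLE_COLUMNS))
    return df.astype({"set_id": int, "t": int, "seed": int, "aborted": bool}) if len(df) else df


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

class TableFormatError(ValueError):
    """Malformed campaign table; message names the offending row/column."""


def write_table(table: pd.DataFrame, path) -> None:
    """Write the training table as headered CSV (missing stats -> empty)."""
    table.to_csv(path, index=False, columns=[c for c in TABLE_COLUMNS if c in table.columns])


def read_table(path) -> pd.DataFrame:
    """Read a training table back, validating every numeric cell.

    Raises :class:`TableFormatError` naming the first bad cell (1-based
    data row, column name) or any missing column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"missing columns: {missing_cols}")
    out = {}
    for col in TABLE_COLUMNS:
        raw = df[col]
        if col == "aborted":
            vals = raw.str.strip().str.lower()
            bad = ~vals.isin(["true", "false", "0", "1"])
            if bad.any():
                r = int(np.flatnonzero(bad)[0])
                raise TableFormatError(
                    f"row {r + 1}, column {col!r}: not a boolean: {raw.iloc[r]!r}")
            out[col] = vals.isin(["true", "1"]).to_numpy()
            continue
        stripped = raw.str.strip()
        numeric = pd.to_numeric(stripped.replace("", "nan"), errors="coerce")
        bad = numeric.isna() & (stripped != "") & (stripped.str.lower() != "nan")
        if bad.any():
            r = int(np.flatnonzero(bad)[0])
            raise TableFormatError(
                f"row {r + 1}, column {col!r}: not numeric: {raw.iloc[r]!r}")
        if stripped.eq("").any() and col not in PROPERTY_NAMES:
            r = int(np.flatnonzero(stripped.eq(""))[0])
            raise TableFormatError(f"row {r + 1}, column {col!r}: empty cell")
        out[col] = numeric.to_numpy()
    table = pd.DataFrame(out, columns=list(TABLE_COLUMNS))
    return table.astype({"set_id": int, "N": int, "F": int, "q": int,
                         "t": int, "seed": int, "aborted": bool})
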