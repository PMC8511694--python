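"""Variance-based global sensitivity analysis (Sobol indices).

For a model Y = f(X_1, ..., X_d) with independent inputs, the
first-order index S_i = V_i[E_~i[Y]] / V[Y] is the share of output
variance removed by fixing X_i alone, and the total-effect index
S_Ti = E_~i[V_i[Y]] / V[Y] additionally counts every interaction
involving X_i.

Estimation uses the Saltelli sampling scheme — two independent base
matrices A and B of n_base points in the unit hypercube plus the d
radial matrices AB_i (A with column i replaced from B), n_base * (d + 2)
model evaluations in total — with the Jansen estimators

    S_i  = (V - mean((f(B) - f(AB_i))^2) / 2) / V
    S_Ti = mean((f(A) - f(AB_i))^2) / 2 / V

and percentile bootstrap 95% confidence intervals over the base rows.
Small negative estimates (sampling noise) are reported as-is and
flagged, never clipped.  Inputs are sampled uniformly on their scale
(log10 axis for log-sampled parameters); integer model parameters are
treated as continuous here because the surrogate is defined on the
continuous box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .campaign import RangeSpec, default_ranges
from .campaign import INPUT_COLUMNS

#: total variances below this (relative to mean square) flag "undefined"
_VAR_EPS = 1e-12


def _as_range_list(ranges):
    """Normalize {name: RangeSpec} or [(low, high[, scale])] to a list."""
    if isinstance(ranges, dict):
        names = list(ranges)
        specs = [ranges[n] for n in names]
    else:
        names, specs = [], []
        for k, r in enumerate(ranges):
            if isinstance(r, RangeSpec):
                names.append(f"x{k + 1}")
                specs.append(r)
            else:
                low, high = r[0], r[1]
                scale = r[2] if len(r) > 2 else "linear"
                names.append(f"x{k + 1}")
                specs.append(RangeSpec(low, high, scale=scale))
    return names, specs


def map_unit_to_box(u: np.ndarray, specs) -> np.ndarray:
    """Map unit-cube points to raw input values, per-column scale-aware."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    for k, spec in enumerate(specs):
        if spec.scale == "log10":
            lo, hi = math.log10(spec.low), math.log10(spec.high)
            out[:, k] = 10.0 ** (lo + u[:, k] * (hi - lo))
        else:
            out[:, k] = spec.low + u[:, k] * (spec.high - spec.low)
    return out


def saltelli_design(d: int, n_base: int, rng: np.random.Generator):
    """(A, B, AB) unit-cube matrices; AB has shape (d, n_base, d)."""
    if d < 1 or n_base < 2:
        raise ValueError("need d >= 1 and n_base >= 2")
    a = rng.random((n_base, d))
    b = rng.random((n_base, d))
    ab = np.repeat(a[None, :, :], d, axis=0)
    for i in range(d):
        ab[i, :, i] = b[:, i]
    return a, b, ab


@dataclass
class SensitivityResult:
    """Tidy per-input indices with bootstrap CIs and sampling metadata."""

    table: pd.DataFrame  # input, S1, S1_lo, S1_hi, ST, ST_lo, ST_hi, negative_flag
    n_base: int
    n_boot: int
    defined: bool  # False when the output variance vanished

    def __getitem__(self, name):
        return self.table.set_index("input").loc[name]


def _jansen(f_a, f_b, f_ab):
    """Jansen-form S and ST estimates from evaluations; f_ab is (d, n)."""
    v = np.var(np.concatenate([f_a, f_b]))
    if v <= _VAR_EPS * max(1.0, float(np.mean(np.concatenate([f_a, f_b]) ** 2))):
        return None, None, v
    s1 = (v - 0.5 * np.mean((f_b[None, :] - f_ab) ** 2, axis=1)) / v
    st = 0.5 * np.mean((f_a[None, :] - f_ab) ** 2, axis=1) / v
    return s1, st, v


def sobol_indices(evaluator, ranges, n_base: int = 4096, n_boot: int = 200,
                  rng: np.random.Generator | None = None) -> SensitivityResult:
    """First-order and total-effect Sobol indices of ``evaluator``.

    ``evaluator`` maps an (n, d) array of raw inputs to n outputs and
    must be defined on the whole sampled box; ``ranges`` is either a
    {name: RangeSpec} dict or a list of (low, high[, scale]) tuples.
    """
    if rng is None:
        rng = np.random.default_rng()
    names, specs = _as_range_list(ranges)
    d = len(specs)
    a, b, ab = saltelli_design(d, n_base, rng)
    f_a = np.asarray(evaluator(map_unit_to_box(a, specs)), dtype=float).ravel()
    f_b = np.asarray(evaluator(map_unit_to_box(b, specs)), dtype=float).ravel()
    f_ab = np.empty((d, n_base))
    for i in range(d):
        f_ab[i] = np.asarray(evaluator(map_unit_to_box(ab[i], specs)), dtype=float).ravel()

    s1, st, v = _jansen(f_a, f_b, f_ab)
    if s1 is None:
        table = pd.DataFrame({"input": names,
                              "S1": np.nan, "S1_lo": np.nan, "S1_hi": np.nan,
                              "ST": np.nan, "ST_lo": np.nan, "ST_hi": np.nan,
                              "negative_flag": False})
        return SensitivityResult(table=table, n_base=n_base, n_boot=n_boot, defined=False)

    boot_s1 = np.empty((n_boot, d))
    boot_st = np.empty((n_boot, d))
    for r in range(n_boot):
        idx = rng.integers(0, n_base, size=n_base)
        bs1, bst, _ = _jansen(f_a[idx], f_b[idx], f_ab[:, idx])
        if bs1 is None:
            bs1 = np.full(d, np.nan)
            bst = np.full(d, np.nan)
        boot_s1[r] = bs1
        boot_st[r] = bst
    lo_s1, hi_s1 = np.nanpercentile(boot_s1, [2.5, 97.5], axis=0)
    lo_st, hi_st = np.nanpercentile(boot_st, [2.5, 97.5], axis=0)

    table = pd.DataFrame({
        "input": names,
        "S1": s1, "S1_lo": lo_s1, "S1_hi": hi_s1,
        "ST": st, "ST_lo": lo_st, "ST_hi": hi_st,
        "negative_flag": (s1 < 0) | (st < 0),
    })
    return SensitivityResult(table=table, n_base=n_base, n_boot=n_boot, defined=True)


def sobol_brute_force(evaluator, ranges, n_grid: int = 64) -> np.ndarray:
    """First-order indices by direct nested quadrature (test oracle).

    Transcribes S_i = V_i[E_~i[Y]] / V[Y] on a midpoint tensor grid of
    the (scale-aware uniform) input distributions.  Refuses d > 3 — the
    cost grows as n_grid**d; this is a validation oracle, not the
    estimator.
    """
    names, specs = _as_range_list(ranges)
    d = len(specs)
    if d > 3:
        raise ValueError("brute-force oracle limited to d <= 3")
    u1 = (np.arange(n_grid) + 0.5) / n_grid
    grids = np.meshgrid(*([u1] * d), indexing="ij")
    u = np.column_stack([g.ravel() for g in grids])
    y = np.asarray(evaluator(map_unit_to_box(u, specs)), dtype=float).reshape([n_grid] * d)
    v_total = float(np.var(y))
    if v_total <= _VAR_EPS:
        return np.full(d, np.nan)
    s = np.empty(d)
    for i in range(d):
        other = tuple(ax for ax in range(d) if ax != i)
        cond_mean = y.mean(axis=other) if other else y
        s[i] = float(np.var(cond_mean)) / v_total
    return s


def sensitivity_report(mm, ranges=None, n_base: int = 1024, n_boot: int = 100,
                       rng: np.random.Generator | None = None,
                       t_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Sobol indices of every trained surrogate against all 11 inputs.

    Returns tidy rows (output, input, S1, ST, CI bounds).  The input
    distribution matches the training design: uniform per parameter on
    its sampling scale, t uniform over the checkpoint range.  By default
    the box is the one the surrogate's scaler was built on.  Integer
    model parameters stay continuous — the surrogate is defined on the
    continuous box.
    """
    if not getattr(mm, "models", None):
        raise ValueError("metamodel has no trained surrogates")
    if rng is None:
        rng = np.random.default_rng()
    if ranges is None:
        if getattr(mm, "scaler", None) is not None:
            ranges = {name: RangeSpec(lo, hi, scale=sc)
                      for name, (lo, hi, sc) in mm.scaler.specs.items()}
        else:
            ranges = default_ranges()
    box = {name: ranges[name] for name in INPUT_COLUMNS if name != "t"}
    if t_range is not None:
        box["t"] = RangeSpec(t_range[0], t_range[1])
    elif "t" in ranges:
        box["t"] = ranges["t"]
    elif getattr(mm, "scaler", None) is not None and "t" in mm.scaler.specs:
        lo, hi, sc = mm.scaler.specs["t"]
        box["t"] = RangeSpec(lo, hi, scale=sc)
    else:
        box["t"] = RangeSpec(5_000.0, 50_000.0)

    frames = []
    for target in mm.targets:
        def evaluator(x, _target=target):
            df = pd.DataFrame(x, columns=list(box))
            return mm.predict(_target, df)
        res = sobol_indices(evaluator, box, n_base=n_base, n_boot=n_boot, rng=rng)
        t = res.table.copy()
        t.insert(0, "output", target)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
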