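"""Neural-network surrogates (metamodels) of the simulator.

One multilayer perceptron per output property regresses the campaign
table: 11 features (the 10 model parameters plus the time step t), each
scaled into the unit interval (after log10 for the rate-like
parameters), against one network property (log10-transformed for the
average link weight, whose scale spans orders of magnitude).

The regressor is a 3 x 30 fully connected ReLU network with a linear
output, trained to minimize the mean squared error with Adam
(batch 200, 2,000 epochs, learning rate 0.001 by default; a small
grid-search helper covers the learning rate).  Train/validation/test
splitting is by parameter set, never by row, so seeds and checkpoints
of one set can never leak across the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .model_core import GWSNParams, PARAM_NAMES
from .campaign import INPUT_COLUMNS, RangeSpec, default_ranges
from .netprops import PROPERTY_NAMES

logger = logging.getLogger("gwsn")

#: target transform per property; everything else is identity
LOG_TARGETS = ("w_avg",)


@dataclass(frozen=True)
class MetamodelConfig:
    """MLP architecture and training hyperparameters."""

    hidden_layers: int = 3
    n_units: int = 30
    batch_size: int = 200
    epochs: int = 2000
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_layers, self.n_units, self.batch_size, self.epochs) < 1:
            raise ValueError("architecture/training sizes must be positive integers")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


# ---------------------------------------------------------------------------
# Feature scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureScaler:
    """Maps raw inputs into [0,1]^11 and applies per-target transforms.

    Each input feature is scaled linearly over its sampling range, on a
    log10 axis for log-sampled parameters; t is scaled linearly over the
    checkpoint range [measure_every, t_max].
    """

    specs: dict  # name -> (low, high, scale)

    @classmethod
    def from_ranges(cls, ranges: dict[str, RangeSpec] | None = None,
                    t_range: tuple[float, float] = (5_000.0, 50_000.0)) -> "FeatureScaler":
        if ranges is None:
            ranges = default_ranges()
        specs = {name: (float(r.low), float(r.high), r.scale)
                 for name, r in ranges.items() if name in PARAM_NAMES}
        specs["t"] = (float(t_range[0]), float(t_range[1]), "linear")
        return cls(specs=specs)

    def _axis(self, name, x):
        low, high, scale = self.specs[name]
        x = np.asarray(x, dtype=float)
        if scale == "log10":
            return np.log10(x), np.log10(low), np.log10(high)
        return x, low, high

    def transform_one(self, name: str, x):
        xt, lo, hi = self._axis(name, x)
        if hi == lo:
            return np.zeros_like(xt)
        return (xt - lo) / (hi - lo)

    def inverse_one(self, name: str, u):
        low, high, scale = self.specs[name]
        u = np.asarray(u, dtype=float)
        if scale == "log10":
            lo, hi = np.log10(low), np.log10(high)
            return 10.0 ** (lo + u * (hi - lo))
        return low + u * (high - low)

    def transform_inputs(self, table) -> np.ndarray:
        """(n, 11) unit-interval feature matrix in INPUT_COLUMNS order."""
        cols = [self.transform_one(name, np.asarray(table[name], dtype=float))
                for name in INPUT_COLUMNS]
        return np.column_stack(cols)

    def transform_target(self, target: str, y):
        y = np.asarray(y, dtype=float)
        return np.log10(y) if target in LOG_TARGETS else y

    def inverse_target(self, target: str, y):
        y = np.asarray(y, dtype=float)
        return 10.0 ** y if target in LOG_TARGETS else y


def build_features(table: pd.DataFrame, target: str,
                   scaler: FeatureScaler) -> tuple[np.ndarray, np.ndarray]:
    """Scaled (X, y) for one target; rows with a missing target dropped."""
    if target not in PROPERTY_NAMES:
        raise KeyError(f"unknown target {target!r}; expected one of {PROPERTY_NAMES}")
    if len(table) == 0:
        raise ValueError("empty training table")
    y_raw = np.asarray(table[target], dtype=float)
    keep = np.isfinite(y_raw)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("target %s: dropped %d rows with undefined values", target, n_dropped)
    x = scaler.transform_inputs(table.loc[keep])
    y = scaler.transform_target(target, y_raw[keep])
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in features or transformed target")
    return x, y


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def train_metamodel(x: np.ndarray, y: np.ndarray,
                    config: MetamodelConfig = MetamodelConfig()) -> MLPRegressor:
    """Fit one MLP surrogate on scaled features (full epoch budget)."""
    if len(x) < 1:
        raise ValueError("need at least one training row")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite training data")
    model = MLPRegressor(
        hidden_layer_sizes=(config.n_units,) * config.hidden_layers,
        activation="relu",
        solver="adam",
        alpha=0.0,
        batch_size=min(config.batch_size, len(x)),
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        shuffle=True,
        random_state=config.seed,
        tol=0.0,
        n_iter_no_change=config.epochs,  # disable early stopping
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(x, y)
    return model


def split_by_parameter_set(table: pd.DataFrame,
                           fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                           seed: int = 0):
    """(train, val, test) tables split at the parameter-set level."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    sets = np.sort(table["set_id"].unique())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sets)
    n = len(sets)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    groups = (perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:])
    return tuple(table[table["set_id"].isin(g)].reset_index(drop=True) for g in groups)


@dataclass
class Metamodel:
    """Per-property surrogates plus their shared scaler and config."""

    scaler: FeatureScaler
    config: MetamodelConfig
    models: dict = field(default_factory=dict)        # target -> MLPRegressor
    evaluation: dict = field(default_factory=dict)    # target -> {"mse", "variance", "n_test"}

    @property
    def targets(self):
        return tuple(self.models)

    def predict(self, target: str, table, transformed: bool = True) -> np.ndarray:
        """Predict one property at raw input rows (DataFrame with the 11
        input columns).  ``transformed=False`` undoes the target transform."""
        if target not in self.models:
            raise KeyError(f"no trained surrogate for {target!r}")
        x = self.scaler.transform_inputs(table)
        if np.any((x < -1e-9) | (x > 1 + 1e-9)):
            raise ValueError("inputs outside the sampling ranges")
        y = self.models[target].predict(x)
        return y if transformed else self.scaler.inverse_target(target, y)

    def save(self, path) -> None:
        joblib.dump({"scaler": self.scaler, "config": self.config,
                     "models": self.models, "evaluation": self.evaluation}, path)

    @classmethod
    def load(cls, path) -> "Metamodel":
        d = joblib.load(path)
        return cls(scaler=d["scaler"], config=d["config"],
                   models=d["models"], evaluation=d["evaluation"])


def fit_surrogates(train_table: pd.DataFrame, scaler: FeatureScaler,
                   targets=PROPERTY_NAMES,
                   config: MetamodelConfig = MetamodelConfig()) -> Metamodel:
    """Train one surrogate per requested output property."""
    mm = Metamodel(scaler=scaler, config=config)
    for k, target in enumerate(targets):
        x, y = build_features(train_table, target, scaler)
        mm.models[target] = train_metamodel(x, y, replace(config, seed=config.seed + k))
        logger.info("trained surrogate for %s on %d rows", target, len(x))
    return mm


def evaluate(mm: Metamodel, test_table: pd.DataFrame) -> pd.DataFrame:
    """Test MSE per property on the transformed target scale, with the
    test-target variance as reference."""
    if len(test_table) == 0:
        raise ValueError("empty test table")
    rows = []
    for target in mm.targets:
        x, y = build_features(test_table, target, mm.scaler)
        pred = mm.models[target].predict(x)
        rec = {"target": target,
               "mse": float(np.mean((pred - y) ** 2)),
               "variance": float(np.var(y)),
               "n_test": int(len(y))}
        mm.evaluation[target] = {k: rec[k] for k in ("mse", "variance", "n_test")}
        rows.append(rec)
    return pd.DataFrame(rows)


def response_curve(mm: Metamodel, target: str, base: dict, vary: str,
                   grid) -> pd.DataFrame:
    """1-D parameter sweep of the surrogate's prediction.

    ``base`` holds raw values for all 11 inputs (10 parameters + t);
    ``vary`` is swept along ``grid`` (raw values inside the sampling
    range) with all other inputs held at base.
    """
    if vary not in INPUT_COLUMNS:
        raise KeyError(f"unknown input {vary!r}")
    grid = np.asarray(grid, dtype=float)
    low, high, _ = mm.scaler.specs[vary]
    if np.any(grid < low - 1e-12) or np.any(grid > high + 1e-12):
        raise ValueError(f"grid for {vary!r} outside sampling range [{low}, {high}]")
    rows = pd.DataFrame([dict(base) for _ in grid])
    rows[vary] = grid
    pred = mm.predict(target, rows, transformed=False)
    return pd.DataFrame({vary: grid, target: pred})


def grid_search_learning_rate(x, y, x_val, y_val,
                              rates=(0.001, 0.01),
                              config: MetamodelConfig = MetamodelConfig()) -> tuple[float, dict]:
    """Pick the learning rate with the lowest validation MSE."""
    scores = {}
    for lr in rates:
        model = train_metamodel(x, y, replace(config, learning_rate=lr))
        scores[lr] = float(np.mean((model.predict(x_val) - y_val) ** 2))
    best = min(scores, key=scores.get)
    return best, scores
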