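"""One-hidden-layer feed-forward soft sensors.

The networks use a tansig (hyperbolic-tangent) hidden layer and a logsig
output, min-max normalization of inputs and target to [0, 1] fitted on the
training subset only, a random 75/12.5/12.5 train/validation/test split,
and mean-squared-error training by one of three engines (scaled conjugate
gradient, Levenberg–Marquardt, Bayesian regularization).  Model selection
sweeps 1–15 hidden nodes per engine and picks the minimum-RMSE cell.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "tansig",
    "logsig",
    "FeatureSpec",
    "BATCH_BIOMASS_FEATURES",
    "FEDBATCH_BIOMASS_FEATURES",
    "GROWTH_RATE_FEATURES",
    "MinMaxNormalizer",
    "AnnSpec",
    "AnnModel",
    "FitGrid",
    "Selection",
    "split_dataset",
    "evaluate",
    "grid_search",
    "select_best",
    "predict_growth_rate_chain",
    "ENGINES",
]

ENGINES = ("scg", "lm", "br")
ENGINE_LABELS = {
    "scg": "Scaled Conjugate Gradient",
    "lm": "Levenberg-Marquardt",
    "br": "Bayesian Regularization",
}


def tansig(x):
    """Hidden-layer activation 2/(1+e^(−2x)) − 1, identically tanh(x)."""
    return np.tanh(x)


def logsig(x):
    """Output-layer activation 1/(1+e^(−x))."""
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


@dataclass(frozen=True)
class FeatureSpec:
    """Named, ordered input list and output name for one soft-sensor task."""

    name: str
    inputs: tuple
    output: str

    def __post_init__(self) -> None:
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError("feature names must be unique")


BATCH_BIOMASS_FEATURES = FeatureSpec(
    "batch_biomass",
    (
        "lactose",
        "total_carbon_solids",
        "total_solids",
        "inoculum_size",
        "do_pct",
        "base_cum_ml",
        "tcd_au",
        "our",
        "cer",
        "rq",
    ),
    "biomass_gl",
)

FEDBATCH_BIOMASS_FEATURES = FeatureSpec(
    "fedbatch_biomass",
    ("inoculum_size", "do_pct", "base_cum_ml", "tcd_au", "our", "cer", "rq", "volume_l"),
    "biomass_gl",
)

GROWTH_RATE_FEATURES = FeatureSpec(
    "growth_rate",
    FEDBATCH_BIOMASS_FEATURES.inputs + ("ann_predicted_biomass",),
    "mu_h",
)

FEATURE_PRESETS = {
    s.name: s
    for s in (BATCH_BIOMASS_FEATURES, FEDBATCH_BIOMASS_FEATURES, GROWTH_RATE_FEATURES)
}


class MinMaxNormalizer:
    """Per-feature min-max map to [0, 1]; the inverse transform is exact.

    Values outside the fitted range map outside [0, 1] and are passed
    through unclipped.
    """

    def __init__(self, mins: np.ndarray, maxs: np.ndarray, names=None):
        self.mins = np.asarray(mins, dtype=float)
        self.maxs = np.asarray(maxs, dtype=float)
        self.names = list(names) if names is not None else None

    @classmethod
    def fit(cls, x: np.ndarray, names=None) -> "MinMaxNormalizer":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        mins, maxs = x.min(axis=0), x.max(axis=0)
        flat = np.nonzero(maxs - mins < 1e-15)[0]
        if flat.size:
            labels = (
                [names[i] for i in flat] if names is not None else flat.tolist()
            )
            raise ValueError(f"constant feature(s) on the fitting subset: {labels}")
        return cls(mins, maxs, names)

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mins) / (self.maxs - self.mins)

    def inverse(self, xn):
        return np.asarray(xn, dtype=float) * (self.maxs - self.mins) + self.mins


def split_dataset(n_rows: int, fractions=(0.75, 0.125, 0.125), seed: int = 0):
    """Random disjoint (train, val, test) index partition.

    Validation and test sizes are rounded; the remainder goes to training.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if n_rows < 8:
        raise ValueError("need at least 8 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_val = round(n_rows * fractions[1])
    n_test = round(n_rows * fractions[2])
    test = np.sort(perm[:n_test])
    val = np.sort(perm[n_test : n_test + n_val])
    train = np.sort(perm[n_test + n_val :])
    return train, val, test


@dataclass(frozen=True)
class AnnSpec:
    """Hyperparameters of one training configuration."""

    n_inputs: int
    n_hidden: int
    engine: str = "lm"
    goal: float = 1e-3            # MSE target in normalized space
    max_epochs: int | None = None  # engine default if None
    restarts: int = 5
    patience: int = 6
    split: tuple = (0.75, 0.125, 0.125)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_hidden <= 15:
            raise ValueError("n_hidden must lie in [1, 15]")
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @property
    def epochs(self) -> int:
        if self.max_epochs is not None:
            return self.max_epochs
        return 1000 if self.engine == "scg" else 300


# parameter vector layout helpers ------------------------------------------


def n_params(n_in: int, n_hid: int) -> int:
    return n_hid * n_in + n_hid + n_hid + 1


def unpack(theta: np.ndarray, n_in: int, n_hid: int):
    i = 0
    w1 = theta[i : i + n_hid * n_in].reshape(n_hid, n_in); i += n_hid * n_in
    b1 = theta[i : i + n_hid]; i += n_hid
    w2 = theta[i : i + n_hid]; i += n_hid
    b2 = theta[i]
    return w1, b1, w2, b2


def pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([np.ravel(w1), np.ravel(b1), np.ravel(w2), [float(b2)]])


def forward_normalized(theta: np.ndarray, xn: np.ndarray, n_hid: int):
    """Normalized forward pass; returns (output, hidden activations, pre-acts)."""
    xn = np.atleast_2d(xn)
    w1, b1, w2, b2 = unpack(theta, xn.shape[1], n_hid)
    z1 = xn @ w1.T + b1
    a1 = tansig(z1)
    z2 = a1 @ w2 + b2
    return logsig(z2), a1, z2


def residuals_and_jacobian(theta, xn, yn, n_hid):
    """Per-sample residuals r = ŷ − y and the Jacobian dŷ/dθ (N × P)."""
    xn = np.atleast_2d(xn)
    n, n_in = xn.shape
    a2, a1, _ = forward_normalized(theta, xn, n_hid)
    w1, b1, w2, b2 = unpack(theta, n_in, n_hid)
    r = a2 - yn
    d2 = a2 * (1.0 - a2)                     # logsig'
    g1 = (d2[:, None] * w2) * (1.0 - a1**2)  # N × H, back through tansig
    j_w1 = g1[:, :, None] * xn[:, None, :]   # N × H × I
    j = np.concatenate(
        [j_w1.reshape(n, n_hid * n_in), g1, d2[:, None] * a1, d2[:, None]], axis=1
    )
    return r, j


def loss_and_grad(theta, xn, yn, n_hid):
    """Training MSE and its analytic gradient."""
    r, j = residuals_and_jacobian(theta, xn, yn, n_hid)
    n = r.size
    return float(r @ r) / n, (2.0 / n) * (j.T @ r)


def mse(theta, xn, yn, n_hid) -> float:
    a2, _, _ = forward_normalized(theta, xn, n_hid)
    d = a2 - yn
    return float(d @ d) / d.size


@dataclass
class AnnModel:
    """A trained soft sensor: weights, normalization and training history."""

    theta: np.ndarray
    n_inputs: int
    n_hidden: int
    engine: str
    x_norm: MinMaxNormalizer
    y_norm: MinMaxNormalizer
    feature_names: tuple | None = None
    output_name: str | None = None
    history: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def weights(self):
        return unpack(self.theta, self.n_inputs, self.n_hidden)

    def forward(self, x) -> np.ndarray:
        """Predict in output units from raw (unnormalized) inputs."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} inputs, got {x.shape[1]}"
            )
        yn, _, _ = forward_normalized(self.theta, self.x_norm.transform(x), self.n_hidden)
        return self.y_norm.inverse(yn)

    def forward_frame(self, frame: pd.DataFrame) -> np.ndarray:
        if self.feature_names is None:
            raise ValueError("model carries no feature names")
        missing = [c for c in self.feature_names if c not in frame]
        if missing:
            raise KeyError(f"missing features: {missing}")
        return self.forward(frame.loc[:, list(self.feature_names)].to_numpy())

    def to_json(self, path) -> None:
        payload = {
            "theta": self.theta.tolist(),
            "n_inputs": self.n_inputs,
            "n_hidden": self.n_hidden,
            "engine": self.engine,
            "x_min": self.x_norm.mins.tolist(),
            "x_max": self.x_norm.maxs.tolist(),
            "y_min": self.y_norm.mins.tolist(),
            "y_max": self.y_norm.maxs.tolist(),
            "feature_names": list(self.feature_names or []),
            "output_name": self.output_name,
            "history": _jsonable(self.history),
            "metrics": _jsonable(self.metrics),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "AnnModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            theta=np.asarray(p["theta"], dtype=float),
            n_inputs=p["n_inputs"],
            n_hidden=p["n_hidden"],
            engine=p["engine"],
            x_norm=MinMaxNormalizer(p["x_min"], p["x_max"], p.get("feature_names")),
            y_norm=MinMaxNormalizer(p["y_min"], p["y_max"]),
            feature_names=tuple(p.get("feature_names") or ()) or None,
            output_name=p.get("output_name"),
            history=p.get("history", {}),
            metrics=p.get("metrics", {}),
            seed=p.get("seed"),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def evaluate(y_true, y_pred) -> tuple[float, float]:
    """(RMSE, R²) on output-unit values; R² is NaN for zero-variance targets."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("cannot evaluate on empty data")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    return rmse, r2


class Selection(NamedTuple):
    engine: str
    n_hidden: int
    rmse: float
    r2: float


class FitGrid:
    """Engine × hidden-node RMSE/R² table with optional fitted models."""

    def __init__(self, frame: pd.DataFrame, models: dict | None = None):
        need = {"engine", "n_hidden", "rmse", "r2"}
        if not need <= set(frame.columns):
            raise ValueError(f"grid frame must have columns {sorted(need)}")
        self.frame = frame.reset_index(drop=True)
        self.models = models or {}

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "FitGrid":
        return cls(pd.read_csv(path))

    def model(self, engine: str, n_hidden: int) -> AnnModel:
        return self.models[(engine, n_hidden)]


def select_best(grid: FitGrid) -> Selection:
    """Minimum-RMSE cell; ties broken by fewer nodes, then engine order."""
    f = grid.frame.dropna(subset=["rmse"])
    if f.empty:
        raise ValueError("grid has no populated cells")
    order = {e: i for i, e in enumerate(ENGINES)}
    f = f.assign(_eo=f["engine"].str.lower().map(lambda e: order.get(e, 99)))
    f = f.sort_values(["rmse", "n_hidden", "_eo"], kind="mergesort")
    row = f.iloc[0]
    return Selection(
        str(row["engine"]), int(row["n_hidden"]), float(row["rmse"]), float(row["r2"])
    )


def grid_search(
    x: np.ndarray,
    y: np.ndarray,
    engines=ENGINES,
    nodes=range(1, 16),
    seed: int = 0,
    restarts: int = 5,
    goal: float = 1e-3,
    max_epochs: int | None = None,
    keep_models: bool = True,
) -> FitGrid:
    """Sweep engines × hidden nodes; metrics are on the full dataset.

    One model is fitted per cell (best of ``restarts`` seeded restarts);
    cell failures are recorded as missing rather than raised.  The whole
    grid is reproducible from ``seed``.
    """
    from .training import train_ann

    rows, models = [], {}
    for ei, engine in enumerate(engines):
        for node in nodes:
            spec = AnnSpec(
                n_inputs=x.shape[1],
                n_hidden=int(node),
                engine=engine,
                goal=goal,
                max_epochs=max_epochs,
                restarts=restarts,
                seed=seed + 1000 * ei + int(node),
            )
            try:
                model = train_ann(spec, x, y)
                rmse, r2 = evaluate(y, model.forward(x))
                if keep_models:
                    models[(engine, int(node))] = model
            except Exception:
                rmse, r2 = float("nan"), float("nan")
            rows.append(
                {"engine": engine, "n_hidden": int(node), "rmse": rmse, "r2": r2}
            )
    return FitGrid(pd.DataFrame(rows), models)


def predict_growth_rate_chain(
    fedbatch_model: AnnModel, growth_model: AnnModel, frame: pd.DataFrame
) -> np.ndarray:
    """Chained soft sensor: predicted biomass feeds the growth-rate network."""
    if fedbatch_model.feature_names is None or growth_model.feature_names is None:
        raise ValueError("both models must carry feature names")
    if "ann_predicted_biomass" not in growth_model.feature_names:
        raise ValueError(
            "growth model does not take the predicted-biomass input"
        )
    biomass = fedbatch_model.forward_frame(frame)
    frame2 = frame.copy()
    frame2["ann_predicted_biomass"] = biomass
    return growth_model.forward_frame(frame2)
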