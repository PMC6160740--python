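"""Per-object seedling-count regression.

Connected vegetation objects often contain more than one plant (typically
1-3, occasionally up to ~25), so the per-object count y is estimated from
shape descriptors with a linear model.  The workflow is:

1. collinearity pre-selection — of any descriptor pair with |r| > 0.8,
   keep the one more correlated with y;
2. stepwise multiple regression (partial-F entry p <= 0.05, removal
   p >= 0.10) on the survivors;
3. prediction: per-object counts are affine in the features and left
   unrounded; per-plot totals are the rounded sums;
4. validation: signed relative error of the plot total (Es, %) and the
   mean absolute Es over validation subsets (MAE, %).

Three fitted models from rapeseed field campaigns are packaged as
built-ins (``builtin:A`` and ``builtin:B`` for two acquisition dates ten
days apart, ``builtin:single`` pooled over both); all three use F4
(length-width ratio), F12 (density) and F15 (border length).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FeatureCorrelation", "CountModel", "PlotValidation",
    "preselect", "stepwise_fit", "predict_counts", "predict_plot_sum",
    "validation_metrics", "builtin_model", "correlation_matrix",
    "simulate_feature_table", "split_train_validation",
    "reference_correlation", "round_half_away",
]

VARIABLES = ("y",) + tuple(f"F{i}" for i in range(1, 16))


# ---------------------------------------------------------------------------
# reference correlation structure (empirical, rapeseed field campaigns)
#
# Symmetric 16 x 16 matrices over (y, F1..F15): correlations between the
# per-object plant count and the 15 shape descriptors observed at the two
# acquisition dates.  Used as a realistic dependence structure for
# simulating descriptor tables.

_STAGE1_UPPER = [
    # y row: F1..F15
    [0.93, 0.89, 0.87, 0.70, 0.84, 0.88, 0.71, 0.71, 0.86, 0.70, -0.62, -0.52, -0.69, 0.63, 0.91],
    [0.95, 0.99, 0.68, 0.90, 0.96, 0.79, 0.79, 0.90, 0.71, -0.66, -0.41, -0.75, 0.68, 0.99],
    [0.92, 0.66, 0.84, 0.99, 0.68, 0.70, 0.86, 0.65, -0.60, -0.48, -0.66, 0.57, 0.98],
    [0.60, 0.90, 0.93, 0.80, 0.80, 0.89, 0.65, -0.66, -0.33, -0.76, 0.66, 0.97],
    [0.63, 0.66, 0.57, 0.50, 0.71, 0.89, -0.47, -0.67, -0.55, 0.76, 0.70],
    [0.82, 0.91, 0.90, 0.99, 0.68, -0.79, -0.54, -0.87, 0.70, 0.91],
    [0.68, 0.67, 0.84, 0.64, -0.57, -0.42, -0.64, 0.57, 0.98],
    [0.87, 0.89, 0.64, -0.79, -0.50, -0.94, 0.75, 0.78],
    [0.88, 0.59, -0.85, -0.46, -0.89, 0.67, 0.77],
    [0.76, -0.77, -0.63, -0.86, 0.74, 0.92],
    [-0.49, -0.72, -0.59, 0.89, 0.71],
    [0.50, 0.84, -0.56, -0.66],
    [0.54, -0.60, -0.47],
    [-0.71, -0.74],
    [0.65],
]

_STAGE2_LOWER = [
    [0.94],
    [0.91, 0.94],
    [0.89, 0.99, 0.89],
    [0.66, 0.66, 0.64, 0.57],
    [0.83, 0.90, 0.78, 0.91, 0.58],
    [0.91, 0.95, 0.99, 0.91, 0.65, 0.78],
    [0.65, 0.74, 0.56, 0.77, 0.52, 0.89, 0.57],
    [0.70, 0.77, 0.62, 0.80, 0.45, 0.90, 0.61, 0.87],
    [0.85, 0.91, 0.82, 0.91, 0.67, 0.99, 0.81, 0.87, 0.88],
    [0.63, 0.65, 0.60, 0.58, 0.89, 0.61, 0.60, 0.59, 0.52, 0.70],
    [-0.66, -0.71, -0.59, -0.74, -0.46, -0.87, -0.57, -0.87, -0.93, -0.85, -0.46],
    [-0.48, -0.42, -0.47, -0.35, -0.66, -0.52, -0.43, -0.48, -0.46, -0.61, -0.73, 0.53],
    [-0.65, -0.73, -0.57, -0.76, -0.49, -0.88, -0.57, -0.94, -0.90, -0.86, -0.53, 0.92, 0.52],
    [0.54, 0.59, 0.47, 0.59, 0.72, 0.65, 0.47, 0.73, 0.63, 0.69, 0.87, -0.56, -0.60, -0.68],
    [0.93, 0.99, 0.97, 0.96, 0.68, 0.89, 0.97, 0.70, 0.73, 0.92, 0.65, -0.68, -0.48, -0.69, 0.56],
]


def reference_correlation(stage: int) -> pd.DataFrame:
    """Symmetric 16x16 correlation DataFrame over (y, F1..F15) for a stage."""
    m = np.eye(16)
    if stage == 1:
        for i, row in enumerate(_STAGE1_UPPER):
            for off, v in enumerate(row, start=1):
                m[i, i + off] = m[i + off, i] = v
    elif stage == 2:
        for i, row in enumerate(_STAGE2_LOWER, start=1):
            for j, v in enumerate(row):
                m[i, j] = m[j, i] = v
    else:
        raise ValueError("stage must be 1 or 2")
    return pd.DataFrame(m, index=VARIABLES, columns=VARIABLES)


# typical descriptor marginals (mean, sd) for simulation, per stage;
# F15 is in pixel edge units at 0.18 cm GSD, hence the large scale
_FEATURE_MARGINALS = {
    1: {"mean": [5.8, 1.9, 0.32, 1.8, 1.6, 120.0, 3.5, 1.9, 1.4, 2.1,
                 0.68, 1.5, 0.62, 0.45, 110.0],
        "sd": [2.4, 1.3, 0.09, 0.55, 0.45, 80.0, 1.6, 0.5, 0.35, 0.75,
               0.12, 0.35, 0.15, 0.18, 70.0]},
    2: {"mean": [7.4, 3.1, 0.40, 1.8, 1.7, 210.0, 4.2, 1.9, 1.5, 2.1,
                 0.66, 1.7, 0.60, 0.45, 160.0],
        "sd": [3.1, 2.1, 0.11, 0.55, 0.5, 140.0, 2.0, 0.5, 0.4, 0.75,
               0.12, 0.4, 0.15, 0.18, 100.0]},
}


# ---------------------------------------------------------------------------
# types


@dataclass
class FeatureCorrelation:
    """Pearson correlation matrix over (y, F1..F15)."""

    matrix: pd.DataFrame

    def r_with_y(self, name: str) -> float:
        return float(self.matrix.loc["y", name])


@dataclass
class CountModel:
    """Affine per-object count model: y_hat = intercept + sum(coef * F)."""

    features: list[str]
    coefficients: list[float]
    intercept: float
    stats: dict = dc_field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise KeyError(f"feature column(s) missing: {missing}")
        yhat = np.full(len(table), self.intercept, dtype=float)
        for name, coef in zip(self.features, self.coefficients):
            yhat += coef * table[name].to_numpy(dtype=float)
        return yhat

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "features": self.features,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "stats": self.stats,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CountModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(d["features"], d["coefficients"], d["intercept"], d.get("stats", {}))


@dataclass
class PlotValidation:
    """Per-plot totals and relative errors of the estimated stand count."""

    measured: list[int]
    estimated: list[int]
    es_percent: list[float]
    mae_percent: float


_BUILTINS = {
    "A": CountModel(["F4", "F12", "F15"], [0.382, -1.188, 0.011], 2.364,
                    {"F": 3863.525, "r2": 0.845, "rmse": 0.672, "p": "<0.05"}),
    "B": CountModel(["F4", "F12", "F15"], [0.167, -0.621, 0.009], 1.498,
                    {"F": 5874.029, "r2": 0.867, "rmse": 0.759, "p": "<0.05"}),
    "single": CountModel(["F4", "F12", "F15"], [0.462, -0.747, 0.009], 1.465,
                         {"F": 8863.680, "r2": 0.846, "rmse": 0.747, "p": "<0.05"}),
}


def resolve_model(spec) -> CountModel:
    """Resolve a CountModel instance, builtin name, or model-JSON path."""
    if isinstance(spec, CountModel):
        return spec
    name = str(spec)
    if name.startswith("builtin:") or name in _BUILTINS:
        return builtin_model(name)
    return CountModel.from_json(name)


def builtin_model(name: str) -> CountModel:
    """One of the packaged models: 'A', 'B' or 'single' (``builtin:`` prefix ok)."""
    key = name.removeprefix("builtin:")
    if key not in _BUILTINS:
        raise KeyError(f"unknown builtin model {name!r}; choose from {sorted(_BUILTINS)}")
    m = _BUILTINS[key]
    return CountModel(list(m.features), list(m.coefficients), m.intercept, dict(m.stats))


# ---------------------------------------------------------------------------
# correlation + pre-selection


def correlation_matrix(table: pd.DataFrame, y: np.ndarray | pd.Series | None = None,
                       features=None) -> FeatureCorrelation:
    """Pearson correlation over (y, features) from a data table."""
    feats = list(features) if features is not None else [
        c for c in table.columns if c.startswith("F")]
    df = table[feats].copy()
    if y is not None:
        df.insert(0, "y", np.asarray(y, dtype=float))
    elif "y" in table.columns:
        df.insert(0, "y", table["y"].to_numpy(dtype=float))
    else:
        raise ValueError("no y column or argument")
    return FeatureCorrelation(df.corr())


def preselect(corr: FeatureCorrelation | pd.DataFrame, cutoff: float = 0.8) -> list[str]:
    """Collinearity screen: keep one member of every |r| > cutoff pair.

    Pairs are visited in decreasing |r| order (ties by feature index); for
    a pair with both members still alive, the one with the lower |r(., y)|
    is dropped (ties keep the lower-indexed feature).  Returns survivors
    in feature order.
    """
    m = corr.matrix if isinstance(corr, FeatureCorrelation) else corr
    if not np.all(np.isfinite(m.to_numpy())):
        raise ValueError("correlation matrix contains non-finite entries")
    feats = [c for c in m.columns if c != "y"]
    order = {f: i for i, f in enumerate(feats)}

    pairs = []
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            r = float(m.loc[a, b])
            if abs(r) > cutoff:
                pairs.append((abs(r), order[a], order[b], a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    alive = set(feats)
    for _, _, _, a, b in pairs:
        if a in alive and b in alive:
            ra, rb = abs(float(m.loc["y", a])), abs(float(m.loc["y", b]))
            if ra > rb:
                alive.discard(b)
            elif rb > ra:
                alive.discard(a)
            else:  # tie: keep the lower-indexed feature
                alive.discard(b if order[a] < order[b] else a)
    return [f for f in feats if f in alive]


# ---------------------------------------------------------------------------
# stepwise regression


def stepwise_fit(table: pd.DataFrame, y=None, candidates=None,
                 p_enter: float = 0.05, p_remove: float = 0.10) -> CountModel:
    """Forward-entry / backward-removal stepwise OLS on partial-F p-values.

    At each step the candidate with the smallest entry p-value <= p_enter
    joins the model (ties broken by lower feature index), then any entered
    variable whose p-value >= p_remove leaves (largest first).  Stops when
    stable.  Returns an empty model (intercept only) when nothing enters.
    """
    if not p_enter < p_remove:
        raise ValueError(
            f"p_enter ({p_enter}) must be < p_remove ({p_remove}) to avoid oscillation")
    if y is None:
        y = table["y"]
    yv = np.asarray(y, dtype=float)
    if candidates is None:
        candidates = [c for c in table.columns if c.startswith("F")]
    candidates = list(candidates)
    n = len(yv)
    if n <= len(candidates) + 2:
        raise ValueError(f"need n > #candidates + 2 (n={n}, candidates={len(candidates)})")
    X = table[candidates].to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=0) == 0):
        bad = [c for c, r in zip(candidates, np.ptp(X, axis=0)) if r == 0]
        raise ValueError(f"constant candidate column(s): {bad}")

    order = {c: i for i, c in enumerate(candidates)}
    selected: list[str] = []
    if np.ptp(yv) == 0:
        return CountModel([], [], float(yv.mean()),
                          {"r2": 0.0, "rmse": 0.0, "note": "constant response"})

    def fit(cols):
        Xd = sm.add_constant(table[cols].to_numpy(dtype=float)) if cols else \
            np.ones((n, 1))
        return sm.OLS(yv, Xd).fit()

    max_iter = 2 * len(candidates) + 2
    for _ in range(max_iter):
        changed = False
        # forward entry: smallest partial-F p-value (== t-test p of the
        # added coefficient) at or below p_enter
        best = None
        for c in sorted(set(candidates) - set(selected), key=order.get):
            try:
                res = fit(selected + [c])
            except np.linalg.LinAlgError:
                continue
            p = float(res.pvalues[-1])
            if np.isnan(p):
                continue
            if p <= p_enter and (best is None or p < best[0] - 1e-15):
                best = (p, c)
        if best is not None:
            selected.append(best[1])
            selected.sort(key=order.get)
            changed = True
        # backward removal: largest p-value at or above p_remove
        while selected:
            res = fit(selected)
            pvals = dict(zip(selected, res.pvalues[1:]))
            worst = max(selected, key=lambda c: (pvals[c], order[c]))
            if pvals[worst] >= p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        import warnings

        warnings.warn("stepwise regression selected no variables; returning "
                      "an intercept-only model", stacklevel=2)
        resid = yv - yv.mean()
        return CountModel([], [], float(yv.mean()),
                          {"r2": 0.0, "rmse": float(np.sqrt(np.mean(resid ** 2)))})

    res = fit(selected)
    bse = dict(zip(["const"] + selected, res.bse))
    return CountModel(
        selected,
        [float(b) for b in res.params[1:]],
        float(res.params[0]),
        {
            "r2": float(res.rsquared),
            "rmse": float(np.sqrt(np.mean(res.resid ** 2))),
            "fvalue": float(res.fvalue),
            "pvalue": float(res.f_pvalue),
            "stderr": {k: float(v) for k, v in bse.items()},
            "n": n,
        },
    )


# ---------------------------------------------------------------------------
# prediction and validation


def round_half_away(x: float) -> int:
    """Round half away from zero (5.5 -> 6, -5.5 -> -6)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def predict_counts(model: CountModel, table: pd.DataFrame) -> np.ndarray:
    """Per-object estimated counts (affine, unrounded)."""
    return model.predict(table)


def predict_plot_sum(model: CountModel, table: pd.DataFrame,
                     floor_negative: bool = False) -> int:
    """Estimated plot total: rounded sum of per-object predictions."""
    yhat = model.predict(table)
    if floor_negative:
        yhat = np.maximum(yhat, 0.0)
    return round_half_away(float(yhat.sum()))


def validation_metrics(measured_sums, estimated_sums) -> PlotValidation:
    """Signed relative error per plot (Es, %) and their mean absolute value (MAE, %)."""
    measured = [int(m) for m in measured_sums]
    estimated = [int(e) for e in estimated_sums]
    if len(measured) != len(estimated):
        raise ValueError("measured and estimated lists differ in length")
    if any(m <= 0 for m in measured):
        raise ValueError("measured plot sums must be positive")
    es = [100.0 * (e - m) / m for m, e in zip(measured, estimated)]
    mae = float(np.mean([abs(v) for v in es])) if es else 0.0
    return PlotValidation(measured, estimated, es, mae)


# ---------------------------------------------------------------------------
# simulation + splitting utilities


def _nearest_correlation(m: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues to make a printed correlation matrix usable as a
    covariance (printed 2-decimal matrices are often slightly indefinite)."""
    w, v = np.linalg.eigh((m + m.T) / 2)
    w = np.clip(w, eps, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return (fixed + fixed.T) / 2


def simulate_feature_table(n: int, stage: int = 1, model: CountModel | None = None,
                           noise_sd: float | None = None,
                           rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Simulate a descriptor table with the reference correlation structure.

    Features are Gaussian with typical stage marginals and the packaged
    inter-feature correlation; ``y`` is generated from ``model`` (default:
    the stage's built-in) plus N(0, noise_sd) noise, with noise_sd
    defaulting to the model's reported RMSE.  Physically bounded features
    are clipped to their valid ranges afterwards.
    """
    rng = np.random.default_rng(rng)
    if model is None:
        model = builtin_model("A" if stage == 1 else "B")
    if noise_sd is None:
        noise_sd = float(model.stats.get("rmse", 0.7))

    corr = reference_correlation(stage).to_numpy()[1:, 1:]  # feature block
    cov = _nearest_correlation(corr)
    z = rng.multivariate_normal(np.zeros(15), cov, size=n, method="cholesky")
    marg = _FEATURE_MARGINALS[stage]
    table = pd.DataFrame(
        z * np.array(marg["sd"]) + np.array(marg["mean"]),
        columns=[f"F{i}" for i in range(1, 16)],
    )
    # physical ranges
    table["F4"] = table["F4"].clip(lower=1.0)
    table["F10"] = table["F10"].clip(lower=1.0)
    table["F11"] = table["F11"].clip(0.0, 1.0)
    table["F13"] = table["F13"].clip(0.0, 1.0)
    table["F14"] = table["F14"].clip(0.0, 0.999)
    for c in ("F1", "F2", "F3", "F5", "F6", "F12", "F15"):
        table[c] = table[c].clip(lower=0.05)
    table["y"] = model.predict(table) + rng.normal(0.0, noise_sd, size=n)
    return table


def split_train_validation(table: pd.DataFrame, plot_col: str = "plot",
                           device_col: str = "device", holdout_frac: float = 0.15,
                           seed: int | None = None):
    """Training/validation split mirroring a per-device holdout scheme.

    One plot per seeding device is held out whole (three device validation
    subsets), then ``holdout_frac`` of the remaining objects is held out at
    random as a fourth subset.  Returns ``(train, {name: subset})``.
    """
    rng = np.random.default_rng(seed)
    subsets: dict[str, pd.DataFrame] = {}
    held_plots = []
    for dev, grp in table.groupby(device_col, sort=True):
        plots = sorted(grp[plot_col].unique())
        chosen = plots[rng.integers(len(plots))]
        held_plots.append(chosen)
        subsets[f"device:{dev}"] = table[table[plot_col] == chosen]
    rest = table[~table[plot_col].isin(held_plots)]
    idx = rng.permutation(len(rest))
    n_hold = int(round(holdout_frac * len(rest)))
    subsets["random"] = rest.iloc[idx[:n_hold]]
    train = rest.iloc[idx[n_hold:]]
    return train, subsets
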