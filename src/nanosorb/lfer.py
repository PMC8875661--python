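"""pp-LFER (Abraham solvation-parameter) modeling and validation.

A polyparameter linear free energy relationship expresses an adsorption
endpoint (here ``logK`` or ``|E_ad|``) as a linear combination of the
Abraham solute descriptors

* ``E`` — excess molar refraction,
* ``S`` — dipolarity/polarizability,
* ``A`` — hydrogen-bond acidity,
* ``B`` — hydrogen-bond basicity,
* ``V`` — McGowan characteristic volume,
* ``L`` — log gas–hexadecane partition coefficient,

fitted by ordinary least squares.  Gaseous-phase endpoints use the
(E, S, A, B, L) set, aqueous-phase endpoints (E, S, A, B, V), the
conventional split between the L-based gas-to-surface and V-based
water-to-surface formulations.

The module also provides the full QSAR validation suite — adjusted R²,
RMSE, leave-one-out Q², repeated k-fold Q² and external Q² — and
Williams-plot applicability-domain characterization (leverage versus
standardized residual).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DESCRIPTOR_NAMES",
    "GASEOUS_DESCRIPTORS",
    "AQUEOUS_DESCRIPTORS",
    "ENDPOINTS",
    "PPLFERModel",
    "ValidationReport",
    "ADResult",
    "CollinearityError",
    "CollinearityWarning",
    "MissingDescriptorError",
    "read_descriptor_table",
    "split_train_validation",
    "fit_pplfer",
    "predict",
    "validate",
    "williams_domain",
    "descriptor_set_for_phase",
]

DESCRIPTOR_NAMES = ("E", "S", "A", "B", "V", "L")
GASEOUS_DESCRIPTORS = ("E", "S", "A", "B", "L")
AQUEOUS_DESCRIPTORS = ("E", "S", "A", "B", "V")

#: Endpoint columns understood by the pipeline.
ENDPOINTS = (
    "logK_gaseous",
    "logK_aqueous",
    "absEad_gaseous",
    "absEad_aqueous",
    "deltaG_gaseous",
    "deltaG_aqueous",
)


class CollinearityError(ValueError):
    """The design matrix is rank deficient (or numerically singular)."""


class CollinearityWarning(UserWarning):
    """A variance inflation factor exceeds 10."""


class MissingDescriptorError(KeyError):
    pass


def descriptor_set_for_phase(phase: str) -> tuple[str, ...]:
    if phase == "gaseous":
        return GASEOUS_DESCRIPTORS
    if phase == "aqueous":
        return AQUEOUS_DESCRIPTORS
    raise ValueError(f"unknown phase {phase!r}")


def _phase_of_endpoint(endpoint: str) -> str:
    if endpoint.endswith("gaseous"):
        return "gaseous"
    if endpoint.endswith("aqueous"):
        return "aqueous"
    raise ValueError(f"cannot infer phase from endpoint name {endpoint!r}")


@dataclass
class PPLFERModel:
    """A fitted (or literature) pp-LFER model: intercept + Σ coefficient·descriptor."""

    endpoint: str
    phase: str
    descriptor_set: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    n_train: int = 0
    stderr: dict[str, float] | None = None  # keys: descriptors + "intercept"
    df_resid: int | None = None
    r2_train: float | None = None
    source: str = "fit"

    def __post_init__(self):
        self.descriptor_set = tuple(self.descriptor_set)
        missing = [d for d in self.descriptor_set if d not in self.coefficients]
        if missing:
            raise ValueError(f"coefficients missing for descriptors {missing}")

    def predict(self, data) -> float | np.ndarray:
        return predict(self, data)

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Two-sided t confidence intervals for intercept and coefficients."""
        if self.stderr is None or self.df_resid is None:
            raise ValueError("model carries no standard errors (literature fixture?)")
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        out = {
            "intercept": (
                self.intercept - tcrit * self.stderr["intercept"],
                self.intercept + tcrit * self.stderr["intercept"],
            )
        }
        for d in self.descriptor_set:
            c, se = self.coefficients[d], self.stderr[d]
            out[d] = (c - tcrit * se, c + tcrit * se)
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["descriptor_set"] = list(self.descriptor_set)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PPLFERModel":
        d = dict(d)
        d["descriptor_set"] = tuple(d["descriptor_set"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PPLFERModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ValidationReport:
    """Goodness-of-fit, robustness and external-predictivity statistics."""

    endpoint: str
    n_train: int
    n_ext: int
    r2_train: float
    r2_adj: float
    rmse_train: float
    q2_loo: float
    q2_kfold: float
    q2_kfold_sd: float
    k: int
    repetitions: int
    seed: int
    rmse_ext: float | None
    q2_ext: float | None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ADResult:
    """Williams-plot coordinates and applicability-domain flags."""

    leverage_threshold: float  # h* = 3(p+1)/n_train
    train: pd.DataFrame  # leverage, std_residual, high_leverage, outlier, in_domain
    others: pd.DataFrame | None = None


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV with a ``compound_id`` column into an indexed table."""
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise ValueError("descriptor table must have a 'compound_id' column")
    if df["compound_id"].duplicated().any():
        dups = df["compound_id"][df["compound_id"].duplicated()].tolist()
        raise ValueError(f"duplicate compound_id values: {dups}")
    return df.set_index("compound_id")


def split_train_validation(
    table: pd.DataFrame, seed: int, train_fraction: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random 4:1 (by default) split into training and validation sets.

    Sizes are ``⌈f·n⌉`` and the remainder; deterministic per seed.
    With 41 compounds this yields the 33/8 partition used for model
    development.
    """
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    n_train = math.ceil(train_fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    valid_idx = np.sort(perm[n_train:])
    return table.iloc[train_idx], table.iloc[valid_idx]


def _design(table: pd.DataFrame, descriptor_set: Sequence[str]) -> np.ndarray:
    missing = [d for d in descriptor_set if d not in table.columns]
    if missing:
        raise MissingDescriptorError(f"missing descriptor column(s) {missing}")
    X = table[list(descriptor_set)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = table.index[np.isnan(X).any(axis=1)].tolist()
        raise ValueError(f"missing descriptor values for compounds {bad}")
    return np.column_stack([np.ones(len(X)), X])


def _check_collinearity(X: np.ndarray, descriptor_set: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            "design matrix is rank deficient (duplicated or constant descriptors?)"
        )
    # VIF of each descriptor on the others (intercept included in the auxiliary fits)
    if X.shape[1] > 2:
        for j, name in enumerate(descriptor_set, start=1):
            others = np.delete(X, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
            if ss_tot == 0:
                continue
            r2 = 1.0 - np.sum(resid**2) / ss_tot
            if r2 < 1.0 and 1.0 / (1.0 - r2) > 10.0:
                warnings.warn(
                    f"variance inflation factor of {name} is "
                    f"{1.0 / (1.0 - r2):.1f} (> 10)",
                    CollinearityWarning,
                    stacklevel=3,
                )


def fit_pplfer(
    train: pd.DataFrame,
    endpoint: str,
    descriptor_set: Sequence[str] | None = None,
    phase: str | None = None,
) -> PPLFERModel:
    """OLS fit of ``endpoint`` on the phase-appropriate Abraham descriptors."""
    import statsmodels.api as sm

    phase = phase or _phase_of_endpoint(endpoint)
    descriptor_set = tuple(descriptor_set or descriptor_set_for_phase(phase))
    if endpoint not in train.columns:
        raise MissingDescriptorError(f"endpoint column {endpoint!r} not in table")
    n, p = len(train), len(descriptor_set)
    if n <= p + 1:
        raise ValueError(f"need n_train > p+1 = {p + 1}, got {n}")
    X = _design(train, descriptor_set)
    _check_collinearity(X, descriptor_set)
    y = train[endpoint].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_train = 1.0 - float(res.ssr) / ss_tot if ss_tot > 0 else None
    coefs = {d: float(res.params[j + 1]) for j, d in enumerate(descriptor_set)}
    stderr = {d: float(res.bse[j + 1]) for j, d in enumerate(descriptor_set)}
    stderr["intercept"] = float(res.bse[0])
    return PPLFERModel(
        endpoint=endpoint,
        phase=phase,
        descriptor_set=descriptor_set,
        coefficients=coefs,
        intercept=float(res.params[0]),
        n_train=n,
        stderr=stderr,
        df_resid=int(res.df_resid),
        r2_train=r2_train,
    )


def predict(model: PPLFERModel, data) -> float | np.ndarray:
    """Evaluate the exact linear form on a table, Series, or mapping."""
    if isinstance(data, pd.DataFrame):
        missing = [d for d in model.descriptor_set if d not in data.columns]
        if missing:
            raise MissingDescriptorError(f"missing descriptor column(s) {missing}")
        X = data[list(model.descriptor_set)].to_numpy(dtype=float)
        coef = np.array([model.coefficients[d] for d in model.descriptor_set])
        return model.intercept + X @ coef
    # single row: Series or mapping
    total = model.intercept
    for d in model.descriptor_set:
        try:
            total += model.coefficients[d] * float(data[d])
        except (KeyError, IndexError):
            raise MissingDescriptorError(f"missing descriptor {d!r}") from None
    return total


def _lstsq_fit_predict(
    X: np.ndarray, y: np.ndarray, X_new: np.ndarray
) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X_new @ beta


def _leverages(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return np.sum(q**2, axis=1)


def validate(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    endpoint: str,
    descriptor_set: Sequence[str] | None = None,
    k: int = 5,
    repetitions: int = 5000,
    seed: int = 0,
) -> ValidationReport:
    """Compute the full validation-statistic suite for one model spec.

    * ``r2_adj = 1 − (1−R²)(n−1)/(n−p−1)``;
    * ``rmse = √(Σ resid²/n)``;
    * ``q2_loo = 1 − PRESS/SS_tot`` with PRESS from leave-one-out refits
      (computed exactly via the hat-matrix identity
      ``e_(i) = e_i/(1−h_i)``);
    * ``q2_kfold`` — mean over ``repetitions`` random unstratified k-fold
      partitions of the fold-pooled ``1 − PRESS/SS_tot``;
    * ``q2_ext = 1 − Σ_ext(y−ŷ)² / Σ_ext(y−ȳ_train)²`` (the variant
      referenced to the training mean).

    An empty validation set yields ``rmse_ext = q2_ext = None``.
    """
    phase = _phase_of_endpoint(endpoint)
    descriptor_set = tuple(descriptor_set or descriptor_set_for_phase(phase))
    overlap = set(train.index) & set(validation.index)
    if overlap:
        raise ValueError(f"train and validation sets overlap: {sorted(overlap)}")
    n, p = len(train), len(descriptor_set)
    if n < k:
        raise ValueError(f"n_train = {n} < k = {k}")
    X = _design(train, descriptor_set)
    _check_collinearity(X, descriptor_set)
    y = train[endpoint].to_numpy(dtype=float)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    rmse_train = math.sqrt(ss_res / n)

    # LOO via the hat-matrix shortcut (algebraically equal to n refits)
    h = _leverages(X)
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    q2_loo = 1.0 - press / ss_tot

    # repeated k-fold, pooled PRESS per repetition
    rng = np.random.default_rng(seed)
    q2_reps = np.empty(repetitions)
    for rep in range(repetitions):
        perm = rng.permutation(n)
        press_k = 0.0
        for fold in np.array_split(perm, k):
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            yhat = _lstsq_fit_predict(X[mask], y[mask], X[fold])
            press_k += float(np.sum((y[fold] - yhat) ** 2))
        q2_reps[rep] = 1.0 - press_k / ss_tot
    q2_kfold = float(q2_reps.mean())
    q2_kfold_sd = float(q2_reps.std(ddof=1)) if repetitions > 1 else 0.0

    if len(validation) > 0:
        Xv = _design(validation, descriptor_set)
        yv = validation[endpoint].to_numpy(dtype=float)
        ev = yv - Xv @ beta
        rmse_ext = math.sqrt(float(np.mean(ev**2)))
        q2_ext = 1.0 - float(np.sum(ev**2)) / float(np.sum((yv - y.mean()) ** 2))
    else:
        rmse_ext = None
        q2_ext = None

    return ValidationReport(
        endpoint=endpoint,
        n_train=n,
        n_ext=len(validation),
        r2_train=r2,
        r2_adj=r2_adj,
        rmse_train=rmse_train,
        q2_loo=q2_loo,
        q2_kfold=q2_kfold,
        q2_kfold_sd=q2_kfold_sd,
        k=k,
        repetitions=repetitions,
        seed=seed,
        rmse_ext=rmse_ext,
        q2_ext=q2_ext,
    )


def williams_domain(
    model: PPLFERModel,
    train: pd.DataFrame,
    others: pd.DataFrame | None = None,
) -> ADResult:
    """Williams-plot applicability domain for a fitted model.

    Leverage ``h_i = x_iᵀ(XᵀX)⁻¹x_i`` (intercept column included),
    threshold ``h* = 3(p+1)/n_train``; residuals standardized by the
    training RMSE with a ±3 outlier cutoff.
    """
    X = _design(train, model.descriptor_set)
    try:
        xtx_inv = np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError:
        raise CollinearityError("XᵀX is singular") from None
    n, p1 = X.shape
    h_train = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    yhat = predict(model, train)
    y = train[model.endpoint].to_numpy(dtype=float)
    resid = y - yhat
    rmse = math.sqrt(float(np.mean(resid**2)))
    std_resid = resid / rmse if rmse > 0 else np.zeros_like(resid)
    h_star = 3.0 * p1 / n

    def _frame(idx, h, sr):
        df = pd.DataFrame({"leverage": h, "std_residual": sr}, index=idx)
        df["high_leverage"] = df["leverage"] > h_star
        df["outlier"] = df["std_residual"].abs() > 3.0
        df["in_domain"] = ~(df["high_leverage"] | df["outlier"])
        return df

    result_train = _frame(train.index, h_train, std_resid)

    result_others = None
    if others is not None:
        Xo = _design(others, model.descriptor_set)
        h_o = np.einsum("ij,jk,ik->i", Xo, xtx_inv, Xo)
        if model.endpoint in others.columns:
            ro = others[model.endpoint].to_numpy(dtype=float) - predict(model, others)
            sr_o = ro / rmse if rmse > 0 else np.zeros_like(ro)
        else:
            sr_o = np.full(len(others), np.nan)
        result_others = _frame(others.index, h_o, sr_o)

    return ADResult(leverage_threshold=h_star, train=result_train, others=result_others)
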