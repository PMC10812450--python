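"""Second-order response-surface regression on coded harvest factors.

Factors are affinely coded onto [-1, +1] (centered design convention) and
the response is fit by ordinary least squares to a fixed 20-term
polynomial: intercept, the five linear terms, four quadratics (the
geographic-area quadratic is excluded — with only two areas it is
collinear with the intercept) and all ten pairwise interactions.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datamodel import AREAS, VARIETIES, SampleCondition, fixture_path

__all__ = [
    "TERMS",
    "FactorCoding",
    "RSMModel",
    "code_factors",
    "build_design_matrix",
    "fit_polynomial",
    "predict",
    "significance_stars",
    "surface_grid",
    "load_coefficient_fixture",
    "model_from_coefficients",
]

#: (name, exponents over X1..X5) — order mirrors the coefficient table.
TERMS: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("intercept", (0, 0, 0, 0, 0)),
    ("X1", (1, 0, 0, 0, 0)),
    ("X2", (0, 1, 0, 0, 0)),
    ("X3", (0, 0, 1, 0, 0)),
    ("X4", (0, 0, 0, 1, 0)),
    ("X5", (0, 0, 0, 0, 1)),
    ("X1^2", (2, 0, 0, 0, 0)),
    ("X2^2", (0, 2, 0, 0, 0)),
    # X3^2 excluded: area is binary, its square is constant
    ("X4^2", (0, 0, 0, 2, 0)),
    ("X5^2", (0, 0, 0, 0, 2)),
    ("X1X2", (1, 1, 0, 0, 0)),
    ("X1X3", (1, 0, 1, 0, 0)),
    ("X1X4", (1, 0, 0, 1, 0)),
    ("X1X5", (1, 0, 0, 0, 1)),
    ("X2X3", (0, 1, 1, 0, 0)),
    ("X2X4", (0, 1, 0, 1, 0)),
    ("X2X5", (0, 1, 0, 0, 1)),
    ("X3X4", (0, 0, 1, 1, 0)),
    ("X3X5", (0, 0, 1, 0, 1)),
    ("X4X5", (0, 0, 0, 1, 1)),
)

TERM_NAMES = tuple(name for name, _ in TERMS)

FACTOR_NAMES = ("X1", "X2", "X3", "X4", "X5")


class CodingError(ValueError):
    """Raw factor value outside the coding's declared range/levels."""


def _affine(value: float, lo: float, hi: float, what: str) -> float:
    if not lo <= value <= hi:
        raise CodingError(f"{what}={value!r} outside coded range [{lo}, {hi}]")
    if hi == lo:
        return 0.0
    return 2.0 * (value - lo) / (hi - lo) - 1.0


@dataclass(frozen=True)
class FactorCoding:
    """Affine maps from raw factor values to coded [-1, +1].

    Defaults reproduce a centered design over the study: date → days since
    the earliest collection; area → {Guariba: -1, Valparaiso: +1};
    variety → ordinal index in the sampling-plan listing; infection % and
    harvest number → observed range.  Variety is nominal in reality; the
    one-column ordinal coding is a documented modeling caveat of the
    polynomial approach (the network model one-hot encodes it instead).
    """

    date_range: tuple[_dt.date, _dt.date]
    infection_range: tuple[float, float]
    harvest_range: tuple[int, int] = (1, 7)
    area_levels: tuple[str, ...] = AREAS
    variety_levels: tuple[str, ...] = VARIETIES

    @classmethod
    def from_conditions(cls, conditions: list[SampleCondition]) -> "FactorCoding":
        dates = [c.collection_date for c in conditions]
        inf = [c.infection_level for c in conditions]
        harv = [c.harvest_number for c in conditions]
        return cls(
            date_range=(min(dates), max(dates)),
            infection_range=(min(inf), max(inf)),
            harvest_range=(min(harv), max(harv)),
        )

    def code(self, condition: SampleCondition) -> np.ndarray:
        """Coded vector (X1..X5) for one condition."""
        lo, hi = self.date_range
        x1 = _affine((condition.collection_date - lo).days, 0.0, (hi - lo).days, "date")
        try:
            vi = self.variety_levels.index(condition.variety)
        except ValueError:
            raise CodingError(f"variety {condition.variety!r} not in coding") from None
        x2 = _affine(vi, 0, len(self.variety_levels) - 1, "variety")
        try:
            ai = self.area_levels.index(condition.area)
        except ValueError:
            raise CodingError(f"area {condition.area!r} not in coding") from None
        x3 = -1.0 + 2.0 * ai if len(self.area_levels) == 2 else _affine(
            ai, 0, len(self.area_levels) - 1, "area"
        )
        x4 = _affine(condition.infection_level, *self.infection_range, "infection")
        x5 = _affine(condition.harvest_number, *self.harvest_range, "harvest")
        return np.array([x1, x2, x3, x4, x5])

    def code_all(self, conditions: list[SampleCondition]) -> np.ndarray:
        return np.vstack([self.code(c) for c in conditions])


def code_factors(condition: SampleCondition, coding: FactorCoding) -> np.ndarray:
    """Functional alias for :meth:`FactorCoding.code`."""
    return coding.code(condition)


def build_design_matrix(
    coded: np.ndarray, terms: tuple[tuple[str, tuple[int, ...]], ...] = TERMS
) -> np.ndarray:
    """Evaluate each polynomial term on each coded row (n × len(terms))."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    cols = []
    for _name, expo in terms:
        col = np.ones(coded.shape[0])
        for j, e in enumerate(expo):
            if e:
                col = col * coded[:, j] ** e
        cols.append(col)
    return np.column_stack(cols)


@dataclass
class RSMModel:
    """A fitted (or fixture-seeded) second-order polynomial model."""

    response: str
    beta: np.ndarray
    terms: tuple[tuple[str, tuple[int, ...]], ...] = TERMS
    se: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    r2: float | None = None
    adj_r2: float | None = None
    rmse: float | None = None
    residuals: np.ndarray | None = None
    n: int | None = None
    rank: int | None = None
    df_resid: int | None = None
    sigma2: float | None = None
    xtx_pinv: np.ndarray | None = None
    non_identifiable: tuple[str, ...] = ()

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)

    def coefficient_table(self) -> pd.DataFrame:
        """Term, estimate, se, p and significance stars."""
        df = pd.DataFrame({"term": self.term_names, "beta": self.beta})
        df["se"] = self.se if self.se is not None else np.nan
        df["p"] = self.pvalues if self.pvalues is not None else np.nan
        df["stars"] = [
            significance_stars(p) if np.isfinite(p) else "" for p in df["p"]
        ]
        return df

    def to_json(self, path: str | Path) -> None:
        payload = {
            "response": self.response,
            "terms": [[name, list(expo)] for name, expo in self.terms],
            "beta": self.beta.tolist(),
            "se": None if self.se is None else self.se.tolist(),
            "pvalues": None if self.pvalues is None else self.pvalues.tolist(),
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "n": self.n,
            "rank": self.rank,
            "df_resid": self.df_resid,
            "sigma2": self.sigma2,
            "xtx_pinv": None if self.xtx_pinv is None else self.xtx_pinv.tolist(),
            "non_identifiable": list(self.non_identifiable),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RSMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            response=d["response"],
            terms=tuple((n, tuple(e)) for n, e in d["terms"]),
            beta=np.asarray(d["beta"], dtype=float),
            se=None if d["se"] is None else np.asarray(d["se"], dtype=float),
            pvalues=None if d["pvalues"] is None else np.asarray(d["pvalues"], dtype=float),
            r2=d["r2"],
            adj_r2=d["adj_r2"],
            rmse=d["rmse"],
            n=d["n"],
            rank=d["rank"],
            df_resid=d["df_resid"],
            sigma2=d["sigma2"],
            xtx_pinv=None if d.get("xtx_pinv") is None else np.asarray(d["xtx_pinv"]),
            non_identifiable=tuple(d.get("non_identifiable", ())),
        )


def fit_polynomial(
    design: np.ndarray, y: np.ndarray, response: str = "y",
    terms: tuple[tuple[str, tuple[int, ...]], ...] = TERMS,
) -> RSMModel:
    """Ordinary least squares on an explicit design matrix.

    Rank-deficient designs get the minimum-norm solution, a warning, and a
    list of non-identifiable terms (pivoted-QR columns beyond the rank).
    R² is defined as 0 (with a warning) for zero-variance y.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("design and response lengths differ")

    beta, _res, rank, _sv = linalg.lstsq(X, y)
    non_ident: tuple[str, ...] = ()
    if rank < p:
        _q, _r, piv = linalg.qr(X, mode="economic", pivoting=True)
        non_ident = tuple(terms[j][0] for j in sorted(piv[rank:]))
        warnings.warn(
            f"rank-deficient design (rank {rank} < {p} terms); "
            f"minimum-norm solution; non-identifiable: {non_ident}",
            stacklevel=2,
        )
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn("zero-variance response; R^2 defined as 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - sse / sst
    df_resid = n - rank
    adj_r2 = (
        1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 and sst > 0 else float("nan")
    )
    rmse = float(np.sqrt(sse / n))

    xtx_pinv = np.linalg.pinv(X.T @ X)
    if df_resid > 0:
        sigma2 = sse / df_resid
        se = np.sqrt(np.clip(np.diag(xtx_pinv) * sigma2, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    else:
        sigma2 = float("nan")
        se = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
        warnings.warn("no residual degrees of freedom; se/p undefined", stacklevel=2)
    if non_ident:
        mask = np.isin(np.array([t[0] for t in terms]), non_ident)
        se = se.copy(); pvals = pvals.copy()
        se[mask] = np.nan
        pvals[mask] = np.nan

    return RSMModel(
        response=response, beta=beta, terms=terms, se=se, pvalues=pvals,
        r2=r2, adj_r2=adj_r2, rmse=rmse, residuals=resid, n=n, rank=int(rank),
        df_resid=int(df_resid), sigma2=sigma2, xtx_pinv=xtx_pinv,
        non_identifiable=non_ident,
    )


def predict(
    model: RSMModel, x: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float] | None]:
    """Point prediction and confidence interval for the mean response at
    coded point *x* (length 5).

    The interval uses the OLS prediction variance; it is ``None`` for
    fixture-seeded models that carry no fit covariance.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != 5:
        raise ValueError("coded point must have 5 factors")
    row = build_design_matrix(x[None, :], model.terms)[0]
    yhat = float(row @ model.beta)
    if (
        model.xtx_pinv is None
        or model.sigma2 is None
        or not np.isfinite(model.sigma2)
        or model.df_resid is None
        or model.df_resid <= 0
    ):
        return yhat, None
    var = float(row @ model.xtx_pinv @ row) * model.sigma2
    half = stats.t.ppf(0.5 + level / 2.0, model.df_resid) * np.sqrt(max(var, 0.0))
    return yhat, (yhat - half, yhat + half)


def significance_stars(p: float) -> str:
    """Printed significance annotation: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def surface_grid(
    model: RSMModel,
    factor_pair: tuple[int, int],
    fixed: dict[int, float] | None = None,
    resolution: int = 25,
) -> pd.DataFrame:
    """Predicted-response grid over [-1, 1]² for two factors.

    *factor_pair* holds 0-based factor indices; the other three factors sit
    at the coded values in *fixed* (default 0).  Rows are row-major,
    ascending — deterministic for export.
    """
    i, j = factor_pair
    if i == j:
        raise ValueError("factor_pair must name two distinct factors")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    fixed = fixed or {}
    axis = np.linspace(-1.0, 1.0, resolution)
    rows = []
    for xi in axis:
        for xj in axis:
            x = np.zeros(5)
            for k, v in fixed.items():
                x[k] = v
            x[i], x[j] = xi, xj
            rows.append((xi, xj, predict(model, x)[0]))
    return pd.DataFrame(rows, columns=[FACTOR_NAMES[i], FACTOR_NAMES[j], "predicted"])


def load_coefficient_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Long-format published coefficient table (term, response, beta, stars)."""
    path = fixture_path("table5_coefficients.csv") if path is None else path
    return pd.read_csv(path, dtype={"term": str, "response": str}, keep_default_na=False)


_STAT_ROWS = ("R2", "R2_adj", "RMSE")


def model_from_coefficients(
    response: str, fixture: pd.DataFrame | None = None
) -> RSMModel:
    """Seed an RSMModel from the published coefficient column (no refit).

    The excluded area quadratic carries β = 0; fit statistics transfer as
    reported values, the covariance does not (so predictions carry no CI).
    """
    fx = load_coefficient_fixture() if fixture is None else fixture
    sub = fx[fx["response"] == response]
    if sub.empty:
        raise KeyError(f"response {response!r} not in coefficient fixture")
    lookup = dict(zip(sub["term"], sub["beta"]))
    beta = np.array([float(lookup.get(name, 0.0)) for name in TERM_NAMES])
    stats_ = {k: float(lookup[k]) for k in _STAT_ROWS if k in lookup}
    return RSMModel(
        response=response,
        beta=beta,
        r2=stats_.get("R2"),
        adj_r2=stats_.get("R2_adj"),
        rmse=stats_.get("RMSE"),
    )
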