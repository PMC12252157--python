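"""Full-factorial design of experiments for printing-parameter optimization.

The design crosses nozzle gauge A in {27, 25} G, applied pressure B in
{160, 170, 180, 190, 200} kPa, and printing velocity C in {5, 10, 15, 20, 25}
mm/s (2 x 5 x 5 = 50 cells). Responses (strand diameter, SSIM-based
similarity, manual similarity) are modelled by ordinary least squares on
natural-unit *centered* factors

    A - 26,  B - 180,  C - 15

with all products up to ABC, so coefficients read directly in physical units
per unit factor change. Non-significant terms are pruned in one pass at
alpha = 0.01 and the surviving model is refitted.

Two literal reference surfaces are shipped under the names ``eq19`` (strand
diameter, mm) and ``eq20`` (SSIM similarity, %); they serve as ground truth
for the synthetic-response generator and as fixed oracles, independent of
any fitting:

    diameter = 1.0980 - 0.5492 a + 0.0073 b - 0.0648 c - 0.0088 ab - 0.0403 ac
    ssim%    = 51.810 + 0.233 a + 0.10  b + 0.02  c + 0.28  ab - 0.63  ac

(lower-case letters denote the centered factors).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FACTOR_LEVELS",
    "FACTOR_CENTERS",
    "FACTOR_COLUMNS",
    "ALL_TERMS",
    "FactorialDesign",
    "build_full_factorial",
    "FactorialModel",
    "FactorialResults",
    "reference_model",
    "fit_factorial_model",
    "prune",
    "predict",
    "main_effects",
    "response_surface_grid",
    "mae",
    "mse",
    "pearson",
]

FACTOR_LEVELS: dict[str, tuple] = {
    "A": (27, 25),
    "B": (160, 170, 180, 190, 200),
    "C": (5, 10, 15, 20, 25),
}
FACTOR_CENTERS: dict[str, float] = {"A": 26.0, "B": 180.0, "C": 15.0}
FACTOR_COLUMNS: dict[str, str] = {
    "A": "nozzle_G",
    "B": "pressure_kPa",
    "C": "velocity_mm_s",
}
#: Model terms in standard order; the intercept ("1") is always present.
ALL_TERMS: tuple[str, ...] = ("A", "B", "C", "AB", "AC", "BC", "ABC")

_EQ19 = {
    "1": 1.0980,
    "A": -0.5492,
    "B": 0.0073,
    "C": -0.0648,
    "AB": -0.0088,
    "AC": -0.0403,
}
_EQ20 = {
    "1": 51.810,
    "A": 0.233,
    "B": 0.10,
    "C": 0.02,
    "AB": 0.28,
    "AC": -0.63,
}


@dataclass(frozen=True)
class FactorialDesign:
    """The 2x5x5 full factorial plan with a replicate count."""

    replicates: int = 1
    levels: dict = field(default_factory=lambda: dict(FACTOR_LEVELS))

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return int(np.prod([len(v) for v in self.levels.values()]))

    def runs(self) -> pd.DataFrame:
        """All runs, each cell repeated ``replicates`` times, deterministic order."""
        cells = list(itertools.product(*(self.levels[f] for f in "ABC")))
        rows = []
        rid = 1
        for rep in range(self.replicates):
            for a, b, c in cells:
                rows.append((rid, a, b, c, rep + 1))
                rid += 1
        return pd.DataFrame(
            rows,
            columns=["run_id", "nozzle_G", "pressure_kPa", "velocity_mm_s", "replicate"],
        )


def build_full_factorial(replicates: int = 1) -> pd.DataFrame:
    """Convenience: the full 50 x replicates run table."""
    return FactorialDesign(replicates=replicates).runs()


def _centered_columns(df: pd.DataFrame) -> dict[str, np.ndarray]:
    cols = {}
    for f, col in FACTOR_COLUMNS.items():
        if col not in df.columns:
            raise KeyError(f"run table is missing column {col!r} (factor {f})")
        cols[f] = df[col].to_numpy(dtype=float) - FACTOR_CENTERS[f]
    return cols


def _term_column(term: str, centered: dict[str, np.ndarray]) -> np.ndarray:
    if term == "1":
        n = len(next(iter(centered.values())))
        return np.ones(n)
    out = np.ones_like(centered["A"])
    for letter in term:
        out = out * centered[letter]
    return out


def _design_matrix(df: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    centered = _centered_columns(df)
    return np.column_stack([_term_column(t, centered) for t in ("1", *terms)])


def _check_full_crossing(df: pd.DataFrame) -> None:
    observed = {f: sorted(df[FACTOR_COLUMNS[f]].unique()) for f in "ABC"}
    have = set(zip(*(df[FACTOR_COLUMNS[f]] for f in "ABC")))
    missing = [
        cell
        for cell in itertools.product(*(observed[f] for f in "ABC"))
        if cell not in have
    ]
    if missing:
        shown = ", ".join(map(str, missing[:5]))
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        raise ValueError(f"design has empty cells (A, B, C): {shown}{more}")


class FactorialResults:
    """Fitted (or literal) centered polynomial response model.

    Attributes
    ----------
    params : dict
        Coefficient per term; always contains the intercept "1".
    pvalues : dict or None
        Two-sided t-test p-value per term (None for literal models or when
        no residual degrees of freedom remain).
    rsquared : float or None
    response_name : str
    """

    def __init__(
        self,
        params: dict[str, float],
        pvalues: dict[str, float] | None = None,
        bse: dict[str, float] | None = None,
        rsquared: float | None = None,
        response_name: str = "response",
        nobs: int | None = None,
        df_resid: int | None = None,
        model: "FactorialModel | None" = None,
    ) -> None:
        if "1" not in params:
            raise ValueError("model must contain an intercept term '1'")
        self.params = dict(params)
        self.pvalues = None if pvalues is None else dict(pvalues)
        self.bse = None if bse is None else dict(bse)
        self.rsquared = rsquared
        self.response_name = response_name
        self.nobs = nobs
        self.df_resid = df_resid
        self.model = model

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t in ALL_TERMS if t in self.params)

    def predict(self, A, B, C):
        """Evaluate the surface at natural-unit factor settings."""
        a = np.asarray(A, dtype=float) - FACTOR_CENTERS["A"]
        b = np.asarray(B, dtype=float) - FACTOR_CENTERS["B"]
        c = np.asarray(C, dtype=float) - FACTOR_CENTERS["C"]
        a, b, c = np.broadcast_arrays(a, b, c)
        centered = {"A": a, "B": b, "C": c}
        out = np.full(a.shape, self.params["1"], dtype=float)
        for term in self.terms:
            mono = np.ones_like(out)
            for letter in term:
                mono = mono * centered[letter]
            out = out + self.params[term] * mono
        return float(out) if out.ndim == 0 else out

    def prune(self, alpha: float = 0.01):
        """Single-pass significance pruning, then refit.

        Removes every non-intercept term with p >= alpha, refits the model on
        the surviving terms, and returns ``(results, trace)`` where the trace
        lists (term, p_value, kept) for each candidate term.
        """
        if self.pvalues is None or self.model is None:
            raise ValueError("prune requires a fitted model with p-values")
        trace = []
        kept = []
        for term in self.terms:
            p = self.pvalues.get(term, np.nan)
            keep = bool(np.isfinite(p) and p < alpha)
            trace.append({"term": term, "p_value": p, "kept": keep})
            if keep:
                kept.append(term)
        refit = self.model.fit(terms=tuple(kept))
        return refit, pd.DataFrame(trace)

    def summary(self) -> str:
        lines = [
            f"Centered factorial OLS: {self.response_name}",
            f"  terms: 1 + {' + '.join(self.terms) if self.terms else '(intercept only)'}",
        ]
        if self.nobs is not None:
            lines.append(f"  nobs = {self.nobs}, df_resid = {self.df_resid}")
        if self.rsquared is not None:
            lines.append(f"  R^2 = {self.rsquared:.4f}")
        lines.append(f"  {'term':>6} {'coef':>12} {'std err':>10} {'p-value':>10}")
        for term in ("1", *self.terms):
            coef = self.params[term]
            se = "" if not self.bse else f"{self.bse.get(term, float('nan')):10.4g}"
            p = "" if not self.pvalues else (
                f"{self.pvalues[term]:10.4g}" if term in self.pvalues and np.isfinite(self.pvalues.get(term, np.nan)) else f"{'--':>10}"
            )
            lines.append(f"  {term:>6} {coef:12.5g} {se:>10} {p:>10}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<FactorialResults {self.response_name}: 1+{'+'.join(self.terms)}>"


class FactorialModel:
    """OLS model of one response on the centered factorial terms.

    Build from a run table with :meth:`from_dataframe`, then :meth:`fit`.
    """

    def __init__(self, runs: pd.DataFrame, response_name: str) -> None:
        if response_name not in runs.columns:
            raise KeyError(f"response column {response_name!r} not in run table")
        y = runs[response_name].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError(f"response {response_name!r} contains non-finite values")
        _check_full_crossing(runs)
        self.runs = runs.reset_index(drop=True)
        self.response_name = response_name

    @classmethod
    def from_dataframe(cls, runs: pd.DataFrame, response_name: str) -> "FactorialModel":
        return cls(runs, response_name)

    def fit(self, terms: tuple[str, ...] = ALL_TERMS) -> FactorialResults:
        import statsmodels.api as sm

        terms = tuple(t for t in ALL_TERMS if t in terms)
        X = _design_matrix(self.runs, terms)
        y = self.runs[self.response_name].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            # constant response: intercept only, zero slopes, R^2 defined as 0
            params = {"1": float(y[0]), **{t: 0.0 for t in terms}}
            pvals = {t: 1.0 for t in terms}
            return FactorialResults(
                params, pvalues=pvals, bse={t: 0.0 for t in ("1", *terms)},
                rsquared=0.0, response_name=self.response_name,
                nobs=len(y), df_resid=len(y) - X.shape[1], model=self,
            )
        res = sm.OLS(y, X).fit()
        names = ("1", *terms)
        params = dict(zip(names, map(float, res.params)))
        df_resid = int(res.df_resid)
        if df_resid > 0:
            pvalues = dict(zip(names, map(float, res.pvalues)))
            bse = dict(zip(names, map(float, res.bse)))
        else:
            pvalues = {t: float("nan") for t in names}
            bse = {t: float("nan") for t in names}
        return FactorialResults(
            params,
            pvalues={t: pvalues[t] for t in terms},
            bse=bse,
            rsquared=float(res.rsquared),
            response_name=self.response_name,
            nobs=int(res.nobs),
            df_resid=df_resid,
            model=self,
        )


def reference_model(name: str) -> FactorialResults:
    """The shipped literal response surfaces: ``eq19`` (mm) or ``eq20`` (%)."""
    table = {
        "eq19": (_EQ19, "filament_diameter_mm"),
        "eq20": (_EQ20, "ssim_pct"),
    }
    try:
        coeffs, resp = table[name]
    except KeyError:
        raise KeyError(f"unknown reference model {name!r}; available: eq19, eq20") from None
    return FactorialResults(dict(coeffs), response_name=resp)


def fit_factorial_model(runs: pd.DataFrame, response_name: str) -> FactorialResults:
    """Fit the all-terms centered OLS model to a run table."""
    return FactorialModel.from_dataframe(runs, response_name).fit()


def prune(model: FactorialResults, alpha: float = 0.01):
    """Functional form of :meth:`FactorialResults.prune`."""
    return model.prune(alpha=alpha)


def predict(model: FactorialResults, A, B, C):
    """Functional form of :meth:`FactorialResults.predict`."""
    return model.predict(A, B, C)


def main_effects(runs: pd.DataFrame, response_name: str) -> dict[str, pd.Series]:
    """Per-factor level means of one response.

    On a balanced design these equal the OLS main-effect predictions; on
    unbalanced data a warning is issued and plain (weighted) means returned.
    """
    if response_name not in runs.columns:
        raise KeyError(f"response column {response_name!r} not in run table")
    counts = runs.groupby([FACTOR_COLUMNS[f] for f in "ABC"]).size()
    if counts.nunique() > 1:
        warnings.warn(
            "design is unbalanced; main effects are weighted level means",
            UserWarning,
            stacklevel=2,
        )
    return {
        f: runs.groupby(FACTOR_COLUMNS[f])[response_name].mean()
        for f in "ABC"
    }


def response_surface_grid(
    model: FactorialResults,
    factor_pair: tuple[str, str],
    fixed_level: float | None = None,
    num: int = 41,
):
    """Predictions of ``model`` over a dense grid of two factors.

    The remaining factor is held at ``fixed_level`` (default: its center).
    Returns ``(x_values, y_values, Z)`` with ``Z[i, j]`` the prediction at
    ``(x_values[i], y_values[j])``.
    """
    fx, fy = factor_pair
    for f in (fx, fy):
        if f not in FACTOR_LEVELS:
            raise KeyError(f"unknown factor {f!r}; expected one of A, B, C")
    if fx == fy:
        raise ValueError("factor_pair must name two distinct factors")
    (other,) = set("ABC") - {fx, fy}
    fixed = FACTOR_CENTERS[other] if fixed_level is None else float(fixed_level)
    xs = np.linspace(min(FACTOR_LEVELS[fx]), max(FACTOR_LEVELS[fx]), num)
    ys = np.linspace(min(FACTOR_LEVELS[fy]), max(FACTOR_LEVELS[fy]), num)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    settings = {fx: XX, fy: YY, other: np.full_like(XX, fixed)}
    Z = model.predict(settings["A"], settings["B"], settings["C"])
    return xs, ys, np.asarray(Z)


def mae(y, yhat) -> float:
    """Mean absolute error between observed and predicted values."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("inputs must have equal length")
    return float(np.mean(np.abs(y - yhat)))


def mse(y, yhat) -> float:
    """Mean squared error between observed and predicted values."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("inputs must have equal length")
    return float(np.mean((y - yhat) ** 2))


def pearson(x, y) -> float:
    """Product-moment correlation coefficient in [-1, 1]."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson needs two equal-length vectors with >= 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson correlation is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)
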