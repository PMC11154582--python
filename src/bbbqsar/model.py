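"""Multiple linear regression of log BB on descriptor blocks.

The core modelling objects follow the Model/Results idiom:

>>> from bbbqsar import dataset, model
>>> frame = dataset.load_fixture_frame()
>>> res = model.LogBBModel.from_dataframe(frame).fit()
>>> round(res.r2, 4)
0.9342

:class:`LogBBModel` holds the response (log BB) and a descriptor design with
intercept; :meth:`LogBBModel.fit` returns a :class:`LogBBResults` carrying the
complete statistic set used to judge a QSAR model: R2, adjusted and predicted
R2, leave-one-out PRESS, the ANOVA F test, variance inflation factors and the
hat diagonal.  Cross-validation and the leverage-based applicability domain
hang off the results object (:meth:`LogBBResults.cross_validate`,
:meth:`LogBBResults.applicability_domain`).

The headline model regresses log BB on the chromatographic lipophilicity
index log k_w,IAM, molecular weight, and the total hydrogen-bond count
HBD + HBA; :func:`enumerate_candidates` rebuilds the model-selection step
over the alternative size/polarity/flexibility descriptor blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogBBModel",
    "LogBBResults",
    "ModelCandidate",
    "CollinearityError",
    "EQ4_PREDICTORS",
    "fit_ols",
    "compute_loo_press",
    "compute_vif",
    "anova_f",
    "enumerate_candidates",
]

#: Predictor block of the published equation.
EQ4_PREDICTORS = ("log_kw_iam", "mw", "hb_total")

#: Reciprocal-condition-number threshold below which the design is rejected.
RCOND_THRESHOLD = 1e-10


class CollinearityError(ValueError):
    """The design matrix is (numerically) rank deficient."""


def _design_matrix(frame: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    missing = [p for p in predictors if p not in frame.columns]
    if missing:
        raise KeyError(f"missing predictor column(s): {missing}")
    X = frame[list(predictors)].astype(float).copy()
    X.insert(0, "const", 1.0)
    return X


class LogBBModel:
    """OLS model of a response on a descriptor block, with intercept.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response values (log BB).
    exog : DataFrame or array-like, shape (n, p)
        Predictor columns *without* the intercept; one is added internally.
    predictor_names : sequence of str, optional
        Names for array input; taken from columns for DataFrame input.
    """

    def __init__(self, endog, exog, predictor_names: Optional[Sequence[str]] = None):
        if isinstance(exog, pd.DataFrame):
            names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            names = list(predictor_names) if predictor_names else [
                f"x{i + 1}" for i in range(X.shape[1])
            ]
        y = np.asarray(endog, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
        self.endog = y
        self.exog_names = tuple(names)
        self.design = np.column_stack([np.ones(n), X])
        self.design_names = ("const", *names)
        self.n = n
        self.p = p
        self._check_rank()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        predictors: Sequence[str] = EQ4_PREDICTORS,
        response: str = "log_bb",
    ) -> "LogBBModel":
        """Build the model from a compound table (adds hb_total if needed)."""
        frame = frame.copy()
        if "hb_total" not in frame.columns and {"hbd", "hba"} <= set(frame.columns):
            frame["hb_total"] = frame["hbd"] + frame["hba"]
        if response not in frame.columns:
            raise KeyError(f"missing response column {response!r}")
        X = _design_matrix(frame, predictors)
        return cls(frame[response].to_numpy(dtype=float),
                   X.drop(columns="const"), predictors)

    def _check_rank(self) -> None:
        singular = np.linalg.svd(self.design, compute_uv=False)
        rcond = singular[-1] / singular[0]
        if rcond < RCOND_THRESHOLD:
            # name the offending columns via near-perfect auxiliary fits
            offenders = []
            for j, name in enumerate(self.design_names[1:], start=1):
                others = np.delete(self.design, j, axis=1)
                beta, *_ = np.linalg.lstsq(others, self.design[:, j], rcond=None)
                resid = self.design[:, j] - others @ beta
                tot = self.design[:, j] - self.design[:, j].mean()
                denom = float(tot @ tot)
                if denom == 0 or 1.0 - float(resid @ resid) / denom > 1.0 - 1e-8:
                    offenders.append(name)
            raise CollinearityError(
                f"design is rank deficient (rcond={rcond:.2e}); "
                f"offending columns: {offenders or list(self.design_names[1:])}"
            )

    def fit(self) -> "LogBBResults":
        """Exact OLS fit via QR, with the full diagnostic statistic set."""
        import statsmodels.api as sm

        ols = sm.OLS(self.endog, self.design).fit()
        q, _ = np.linalg.qr(self.design)
        hat = np.sum(q * q, axis=1)
        return LogBBResults(model=self, _sm_results=ols, hat_diagonal=hat)


@dataclass
class LogBBResults:
    """Fitted OLS model with the complete validation-statistic set.

    All derived quantities use the standard OLS decomposition with n
    observations and p predictors (p + 1 estimated coefficients):
    ``ss_total = sse + ssr``, ``mse = sse / (n - p - 1)``,
    ``press`` from the hat-matrix leave-one-out identity, and
    ``r2_pred = 1 - press / ss_total``.
    """

    model: LogBBModel
    _sm_results: object
    hat_diagonal: np.ndarray

    # ---- basic dimensions -------------------------------------------------
    @property
    def n(self) -> int:
        return self.model.n

    @property
    def p(self) -> int:
        return self.model.p

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return self.model.exog_names

    # ---- coefficients and inference --------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._sm_results.params, index=self.model.design_names)

    @property
    def se(self) -> pd.Series:
        return pd.Series(self._sm_results.bse, index=self.model.design_names)

    @property
    def t_stats(self) -> pd.Series:
        return pd.Series(self._sm_results.tvalues, index=self.model.design_names)

    @property
    def p_values(self) -> pd.Series:
        """Two-sided t-test p-values with n - p - 1 degrees of freedom."""
        return pd.Series(self._sm_results.pvalues, index=self.model.design_names)

    # ---- sums of squares and fit statistics -------------------------------
    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self._sm_results.resid)

    @property
    def fitted_values(self) -> np.ndarray:
        return np.asarray(self._sm_results.fittedvalues)

    @property
    def sse(self) -> float:
        return float(self._sm_results.ssr)  # statsmodels: residual SS

    @property
    def ss_total(self) -> float:
        return float(self._sm_results.centered_tss)

    @property
    def ssr(self) -> float:
        return float(self._sm_results.ess)  # explained SS

    @property
    def r2(self) -> float:
        return float(self._sm_results.rsquared)

    @property
    def r2_adj(self) -> float:
        return float(self._sm_results.rsquared_adj)

    @property
    def mse(self) -> float:
        """Residual mean square, sse / (n - p - 1)."""
        return self.sse / (self.n - self.p - 1)

    @property
    def is_perfect_fit(self) -> bool:
        """True when residuals vanish to numerical precision (SSE ~ 0)."""
        return self.sse <= 1e-14 * max(self.ss_total, 1e-300)

    @property
    def f_stat(self) -> float:
        return float(self._sm_results.fvalue)

    @property
    def p_f(self) -> float:
        return float(self._sm_results.f_pvalue)

    # ---- leave-one-out PRESS ----------------------------------------------
    @property
    def press(self) -> float:
        """Leave-one-out PRESS via the hat-matrix identity."""
        press, _ = compute_loo_press(self)
        return press

    @property
    def r2_pred(self) -> float:
        _, r2_pred = compute_loo_press(self)
        return r2_pred

    @property
    def vif(self) -> pd.Series:
        """Variance inflation factor of each predictor."""
        return compute_vif(
            pd.DataFrame(self.model.design[:, 1:], columns=self.predictor_names)
        )

    # ---- prediction --------------------------------------------------------
    def predict(self, data, *, coef_precision: Optional[int] = None) -> np.ndarray:
        """Predict the response for new descriptor rows.

        Parameters
        ----------
        data : DataFrame or array-like
            DataFrame with the model's predictor columns (``hb_total`` derived
            from hbd + hba if absent), or an array with columns in predictor
            order (no intercept column).
        coef_precision : int, optional
            If given, predictions use the coefficient vector rounded to this
            many decimals — i.e. the model *as published* rather than at full
            numerical precision.  Reproductions of reported modeled values
            use ``coef_precision=4``.
        """
        if isinstance(data, pd.DataFrame):
            frame = data.copy()
            if "hb_total" not in frame.columns and {"hbd", "hba"} <= set(frame.columns):
                frame["hb_total"] = frame["hbd"] + frame["hba"]
            missing = [c for c in self.predictor_names if c not in frame.columns]
            if missing:
                raise KeyError(f"missing predictor column(s): {missing}")
            X = frame[list(self.predictor_names)].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(
                f"expected {self.p} predictor columns, got {X.shape[1]}"
            )
        beta = self.params.to_numpy()
        if coef_precision is not None:
            beta = np.round(beta, coef_precision)
        return np.column_stack([np.ones(len(X)), X]) @ beta

    # ---- delegation to validation / applicability-domain modules ----------
    def cross_validate(self, **kwargs):
        """Leave-group-out cross-validation; see :func:`bbbqsar.validation.leave_group_out_cv`."""
        from .validation import leave_group_out_cv

        return leave_group_out_cv(self, **kwargs)

    def applicability_domain(self, **kwargs):
        """Williams-plot assessment; see :func:`bbbqsar.domain.williams_assessment`."""
        from .domain import williams_assessment

        return williams_assessment(self, **kwargs)

    # ---- reporting ---------------------------------------------------------
    def to_dict(self) -> dict:
        """All statistics as a JSON-serialisable mapping."""
        return {
            "predictor_names": list(self.predictor_names),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "t_stats": {k: float(v) for k, v in self.t_stats.items()},
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "n": self.n,
            "p": self.p,
            "ss_total": self.ss_total,
            "sse": self.sse,
            "ssr": self.ssr,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "r2_pred": self.r2_pred,
            "press": self.press,
            "mse": self.mse,
            "f_stat": self.f_stat,
            "p_f": self.p_f,
            "vif": {k: float(v) for k, v in self.vif.items()},
            "hat_diagonal": [float(h) for h in self.hat_diagonal],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def statistics_row(self) -> pd.Series:
        """Flat one-row summary in the conventional reporting order."""
        return pd.Series(
            {
                "R2": self.r2,
                "R2_adj": self.r2_adj,
                "R2_pred": self.r2_pred,
                "PRESS": self.press,
                "max_VIF": float(self.vif.max()),
                "SS": self.ss_total,
                "MSE": self.mse,
                "F": self.f_stat,
                "p": self.p_f,
            }
        )

    def summary(self) -> str:
        """Human-readable coefficient and statistics tables."""
        coef = pd.DataFrame(
            {
                "coef": self.params.round(4),
                "std err": self.se.round(4),
                "t": self.t_stats.round(3),
                "P>|t|": self.p_values.round(4),
            }
        )
        stat = self.statistics_row()
        lines = [
            "log BB ~ " + " + ".join(self.predictor_names),
            f"n = {self.n}, p = {self.p}",
            "",
            coef.to_string(),
            "",
            "R2={R2:.4f}  R2_adj={R2_adj:.4f}  R2_pred={R2_pred:.4f}  "
            "PRESS={PRESS:.5f}".format(**stat),
            "SS={SS:.4f}  MSE={MSE:.5f}  F={F:.1f} (p={p:.3g})  "
            "max VIF={max_VIF:.2f}".format(**stat),
        ]
        return "\n".join(lines)


def fit_ols(endog, exog, predictor_names: Optional[Sequence[str]] = None) -> LogBBResults:
    """Fit OLS of ``endog`` on ``exog`` (intercept added); see :class:`LogBBModel`."""
    return LogBBModel(endog, exog, predictor_names).fit()


def compute_loo_press(results: LogBBResults) -> tuple[float, float]:
    """Leave-one-out PRESS and predicted R2 via the hat-matrix shortcut.

    PRESS = sum_i (e_i / (1 - h_ii))^2 equals the sum of squared prediction
    errors from n explicit refits each leaving one observation out.
    """
    h = np.asarray(results.hat_diagonal, dtype=float)
    if np.any(1.0 - h < 1e-12):
        bad = np.nonzero(1.0 - h < 1e-12)[0]
        raise ZeroDivisionError(
            f"leverage equals 1 for observation(s) {bad.tolist()}: each fully "
            "determines its own fit and cannot be left out"
        )
    press = float(np.sum((results.residuals / (1.0 - h)) ** 2))
    return press, 1.0 - press / results.ss_total


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R2_j) from regressing predictor j on the others.

    ``X`` holds the predictor columns without intercept; the auxiliary
    regressions include one.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    values = {}
    arr = X.to_numpy(dtype=float)
    n = len(X)
    for j, name in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
        resid = arr[:, j] - others @ beta
        centered = arr[:, j] - arr[:, j].mean()
        sst = float(centered @ centered)
        r2_aux = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        if r2_aux >= 1.0 - 1e-12:
            raise CollinearityError(
                f"predictor {name!r} is perfectly explained by the others "
                "(infinite VIF)"
            )
        values[name] = 1.0 / (1.0 - r2_aux)
    return pd.Series(values)


def anova_f(results: LogBBResults) -> tuple[float, float]:
    """Overall regression F statistic (SSR/p)/MSE and its upper-tail p-value."""
    if results.mse == 0 or results.is_perfect_fit:
        return float("inf"), 0.0
    f = (results.ssr / results.p) / results.mse
    p_f = float(stats.f.sf(f, results.p, results.n - results.p - 1))
    return float(f), p_f


# ---------------------------------------------------------------------------
# candidate-model enumeration
# ---------------------------------------------------------------------------

SIZE_DESCRIPTORS = ("mw", "alpha")
POLARITY_DESCRIPTORS = ("tpsa", "hb_total")
FLEXIBILITY_DESCRIPTORS = ("nrb", None)


@dataclass
class ModelCandidate:
    """One descriptor-block combination and its fitted model."""

    predictors: tuple[str, ...]
    results: LogBBResults
    rank: int = field(default=-1)

    @property
    def r2_adj(self) -> float:
        return self.results.r2_adj

    @property
    def press(self) -> float:
        return self.results.press


def enumerate_candidates(
    frame: pd.DataFrame,
    response: str = "log_bb",
    *,
    parsimony_threshold: float = 0.005,
) -> list[ModelCandidate]:
    """Fit the eight admissible descriptor blocks and rank them.

    Blocks always include the lipophilicity index log k_w,IAM, exactly one
    size descriptor (MW or alpha), exactly one polarity descriptor (TPSA or
    HB_total) and optionally NRB — intercorrelated descriptors never co-enter.
    Ranking is by adjusted R2 (ties by PRESS), with a parsimony rule: a model
    outranks a nested smaller one only when its adjusted R2 is higher by more
    than ``parsimony_threshold``.
    """
    candidates: list[ModelCandidate] = []
    for size in SIZE_DESCRIPTORS:
        for pol in POLARITY_DESCRIPTORS:
            for flex in FLEXIBILITY_DESCRIPTORS:
                block = ("log_kw_iam", size, pol) + ((flex,) if flex else ())
                res = LogBBModel.from_dataframe(frame, block, response).fit()
                candidates.append(ModelCandidate(block, res))

    candidates.sort(key=lambda c: (-c.r2_adj, c.press, len(c.predictors)))
    # parsimony: move a nested smaller model ahead of a larger one that does
    # not beat it by more than the threshold
    changed = True
    while changed:
        changed = False
        for i, large in enumerate(candidates):
            for j in range(i + 1, len(candidates)):
                small = candidates[j]
                if (
                    set(small.predictors) < set(large.predictors)
                    and large.r2_adj - small.r2_adj <= parsimony_threshold
                ):
                    candidates.insert(i, candidates.pop(j))
                    changed = True
                    break
            if changed:
                break
    for rank, cand in enumerate(candidates):
        cand.rank = rank
    return candidates
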