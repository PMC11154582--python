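"""Leverage-based applicability domain (Williams plot).

A QSAR model is only trusted inside the descriptor-space region it was
trained on.  The leverage approach bounds that region with the warning
leverage h* = 3(p+1)/n; a compound with hat-diagonal leverage above h* is
structurally remote from the training set, and one with a standardized
residual outside +/- 3 SD is a response outlier.  The Williams plot is the
scatter of standardized residual against leverage with those two bounds.

Standardized residuals default to e_i / sqrt(MSE); internally studentized
residuals e_i / sqrt(MSE (1 - h_ii)) are available via
``studentized=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import LogBBResults

__all__ = [
    "AdAssessment",
    "warning_leverage",
    "compute_leverages",
    "williams_assessment",
]

FLAGS = ("in_domain", "high_leverage", "response_outlier", "both")


def warning_leverage(p: int, n: int) -> float:
    """Warning leverage h* = 3 (p + 1) / n.

    ``p`` is the number of predictors and ``n`` the number of training
    compounds; requires n > p + 1.
    """
    if p < 0 or n <= p + 1:
        raise ValueError(f"need n > p + 1 >= 1 (got p={p}, n={n})")
    return 3.0 * (p + 1) / n


def compute_leverages(design: np.ndarray, query_points: np.ndarray | None = None) -> np.ndarray:
    """Hat-diagonal leverages of training rows, or of query rows.

    ``design`` is the full-rank training design *including* the intercept
    column.  For training rows h_ii = diag(X (X'X)^-1 X'); for a query row
    x_q the leverage is x_q' (X'X)^-1 x_q against the training moment matrix
    (queries never update it).
    """
    design = np.asarray(design, dtype=float)
    singular = np.linalg.svd(design, compute_uv=False)
    if singular[-1] / singular[0] < 1e-10:
        raise ValueError("design matrix is rank deficient")
    q, r = np.linalg.qr(design)
    if query_points is None:
        return np.sum(q * q, axis=1)
    query = np.atleast_2d(np.asarray(query_points, dtype=float))
    if query.shape[1] != design.shape[1]:
        raise ValueError(
            f"query rows must have {design.shape[1]} columns (incl. intercept)"
        )
    # h_q = || R^-T x_q ||^2  since (X'X)^-1 = R^-1 R^-T
    w = np.linalg.solve(r.T, query.T)
    return np.sum(w * w, axis=0)


@dataclass
class AdAssessment:
    """Per-compound leverage / standardized-residual table with domain flags."""

    h_star: float
    table: pd.DataFrame          # columns: leverage, std_residual, flag
    residual_band: float
    n: int
    p: int
    studentized: bool

    @property
    def flags(self) -> pd.Series:
        return self.table["flag"]

    def n_in_domain(self) -> int:
        return int((self.table["flag"] == "in_domain").sum())

    def to_tsv(self, path) -> None:
        """Williams table as TSV with h* echoed in a header comment."""
        with open(path, "w") as fh:
            fh.write(
                f"# h_star={self.h_star:.6g}\tresidual_band={self.residual_band}"
                f"\tn={self.n}\tp={self.p}\n"
            )
            self.table.to_csv(fh, sep="\t", index=True)

    def plot(self, ax=None):
        """Convenience Williams plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.table["leverage"], self.table["std_residual"], s=12)
        ax.axvline(self.h_star, ls="--", color="k")
        ax.axhline(self.residual_band, ls="--", color="k")
        ax.axhline(-self.residual_band, ls="--", color="k")
        ax.set_xlabel("leverage $h_{ii}$")
        ax.set_ylabel("standardized residual")
        return ax


def _flag(leverage: np.ndarray, std_resid: np.ndarray, h_star: float, band: float) -> list[str]:
    flags = []
    for h, r in zip(leverage, std_resid):
        high = h > h_star
        outlier = abs(r) > band
        if high and outlier:
            flags.append("both")
        elif high:
            flags.append("high_leverage")
        elif outlier:
            flags.append("response_outlier")
        else:
            flags.append("in_domain")
    return flags


def williams_assessment(
    results: LogBBResults,
    *,
    residual_band: float = 3.0,
    studentized: bool = False,
    index=None,
) -> AdAssessment:
    """Assess every training compound against the model's applicability domain.

    Raises
    ------
    ZeroDivisionError
        If the fit is perfect (MSE = 0), when residual standardization is
        undefined.
    """
    if results.mse == 0 or results.is_perfect_fit:
        raise ZeroDivisionError(
            "MSE is zero: standardized residuals are undefined for a perfect fit"
        )
    h = np.asarray(results.hat_diagonal, dtype=float)
    resid = results.residuals
    if studentized:
        std_resid = resid / np.sqrt(results.mse * (1.0 - h))
    else:
        std_resid = resid / np.sqrt(results.mse)
    h_star = warning_leverage(results.p, results.n)
    table = pd.DataFrame(
        {
            "leverage": h,
            "std_residual": std_resid,
            "flag": _flag(h, std_resid, h_star, residual_band),
        },
        index=index if index is not None else pd.RangeIndex(results.n),
    )
    return AdAssessment(
        h_star=h_star,
        table=table,
        residual_band=residual_band,
        n=results.n,
        p=results.p,
        studentized=studentized,
    )
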