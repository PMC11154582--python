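"""Isocratic retention factors and extrapolation to buffer-only lipophilicity.

On an immobilized-artificial-membrane (IAM) column the retention factor of a
solute measured at several organic-modifier fractions follows the
Soczewinski-Wachtmeister relation

    log k = log k_w - s * phi

where phi is the acetonitrile volume fraction and k_w the retention factor
extrapolated to pure aqueous buffer (phi = 0).  The intercept log k_w is the
chromatographic lipophilicity index used as a predictor of blood-brain
distribution.  All logarithms here are base 10, the chromatographic
convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RetentionMeasurement",
    "ExtrapolationResult",
    "RetentionError",
    "InsufficientDataError",
    "compute_retention_factor",
    "fit_isocratic_series",
    "batch_extrapolate",
    "read_retention_table",
]


class RetentionError(ValueError):
    """Invalid chromatographic input (non-retained solute, bad dead time)."""


class InsufficientDataError(ValueError):
    """Too few distinct modifier fractions to fit the extrapolation line."""


@dataclass(frozen=True)
class RetentionMeasurement:
    """One isocratic measurement: either times (t_r, t_0, minutes) or log_k."""

    compound_id: int
    phi: float
    t_r: Optional[float] = None
    t_0: Optional[float] = None
    log_k: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise RetentionError(
                f"phi must be a volume fraction in (0, 1), got {self.phi}"
            )
        if self.log_k is None:
            if self.t_r is None or self.t_0 is None:
                raise RetentionError(
                    "measurement needs either log_k or both t_r and t_0"
                )

    def resolve_log_k(self) -> float:
        if self.log_k is not None:
            return float(self.log_k)
        _, log_k = compute_retention_factor(self.t_r, self.t_0)
        return log_k


@dataclass(frozen=True)
class ExtrapolationResult:
    """Fitted line log k = log_kw - slope_s * phi for one compound."""

    compound_id: int
    log_kw: float
    slope_s: float
    r2_fit: float
    n_points: int
    se_intercept: float


def compute_retention_factor(t_r: float, t_0: float) -> tuple[float, float]:
    """Retention factor k = (t_r - t_0)/t_0 and its base-10 logarithm.

    Raises
    ------
    RetentionError
        If ``t_0 <= 0`` or ``t_r <= t_0`` (non-retained solute, k <= 0).
    """
    if t_0 is None or t_0 <= 0:
        raise RetentionError(f"dead time t_0 must be positive, got {t_0}")
    if t_r is None or t_r <= t_0:
        raise RetentionError(
            f"t_r ({t_r}) must exceed t_0 ({t_0}): solute not retained (k <= 0)"
        )
    k = (t_r - t_0) / t_0
    return k, math.log10(k)


def fit_isocratic_series(
    measurements: Sequence[RetentionMeasurement],
    *,
    average_replicates: bool = True,
) -> ExtrapolationResult:
    """Ordinary least squares of log k on phi for one compound.

    Replicate injections at the same phi are averaged on the log k scale
    before fitting (``average_replicates=True``, the default) or entered as
    individual points.

    Returns an :class:`ExtrapolationResult` with ``log_kw`` the intercept at
    phi = 0 and ``slope_s`` the *negated* slope, so that the fitted line reads
    ``log k = log_kw - slope_s * phi``.
    """
    if not measurements:
        raise InsufficientDataError("no measurements supplied")
    ids = {m.compound_id for m in measurements}
    if len(ids) != 1:
        raise ValueError(f"measurements mix compounds: {sorted(ids)}")
    (compound_id,) = ids

    phi = np.array([m.phi for m in measurements], dtype=float)
    log_k = np.array([m.resolve_log_k() for m in measurements], dtype=float)
    if average_replicates:
        table = pd.DataFrame({"phi": phi, "log_k": log_k}).groupby("phi", as_index=False).mean()
        phi, log_k = table["phi"].to_numpy(), table["log_k"].to_numpy()

    distinct = np.unique(phi)
    if distinct.size < 2:
        raise InsufficientDataError(
            f"compound {compound_id}: need >= 2 distinct phi values, "
            f"got {distinct.size}"
        )
    if distinct.size < 3:
        warnings.warn(
            f"compound {compound_id}: only {distinct.size} distinct phi levels; "
            "the extrapolation line is poorly determined",
            stacklevel=2,
        )

    n = phi.size
    design = np.column_stack([np.ones(n), phi])
    coef, *_ = np.linalg.lstsq(design, log_k, rcond=None)
    intercept, slope = coef
    fitted = design @ coef
    residuals = log_k - fitted
    sse = float(residuals @ residuals)
    sst = float(np.sum((log_k - log_k.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    if n > 2:
        sigma2 = sse / (n - 2)
        sxx = float(np.sum((phi - phi.mean()) ** 2))
        se_intercept = math.sqrt(sigma2 * (1.0 / n + phi.mean() ** 2 / sxx))
    else:
        se_intercept = float("nan")
    return ExtrapolationResult(
        compound_id=compound_id,
        log_kw=float(intercept),
        slope_s=float(-slope),
        r2_fit=min(1.0, r2),
        n_points=int(n),
        se_intercept=se_intercept,
    )


def batch_extrapolate(
    measurements: Iterable[RetentionMeasurement],
    *,
    average_replicates: bool = True,
) -> tuple[list[ExtrapolationResult], dict[int, str]]:
    """Fit every compound's series; report failures instead of dropping them.

    Returns ``(results, failures)`` where ``failures`` maps compound_id to the
    error message for compounds whose series could not be fitted.
    """
    measurements = list(measurements)
    if not measurements:
        raise InsufficientDataError("empty measurement table")
    groups: dict[int, list[RetentionMeasurement]] = {}
    for m in measurements:
        groups.setdefault(m.compound_id, []).append(m)
    results: list[ExtrapolationResult] = []
    failures: dict[int, str] = {}
    for cid in sorted(groups):
        try:
            results.append(
                fit_isocratic_series(groups[cid], average_replicates=average_replicates)
            )
        except (InsufficientDataError, RetentionError) as exc:
            failures[cid] = str(exc)
    return results, failures


def read_retention_table(path) -> list[RetentionMeasurement]:
    """Read a retention CSV: compound_id, phi and either (t_r, t_0) or log_k."""
    frame = pd.read_csv(path, comment="#")
    if "compound_id" not in frame.columns or "phi" not in frame.columns:
        raise ValueError("retention CSV needs 'compound_id' and 'phi' columns")
    has_times = {"t_r", "t_0"} <= set(frame.columns)
    has_logk = "log_k" in frame.columns
    if not (has_times or has_logk):
        raise ValueError("retention CSV needs either (t_r, t_0) or log_k columns")
    out = []
    for _, row in frame.iterrows():
        out.append(
            RetentionMeasurement(
                compound_id=int(row["compound_id"]),
                phi=float(row["phi"]),
                t_r=float(row["t_r"]) if has_times else None,
                t_0=float(row["t_0"]) if has_times else None,
                log_k=float(row["log_k"]) if has_logk and not pd.isna(row.get("log_k")) else None,
            )
        )
    return out
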