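"""Leave-group-out cross-validation of a fitted descriptor model.

The model-comparison protocol is leave-30%-out: with n = 126 compounds the
nominal holdout is ceil(0.30 * 126) = 38 compounds.  Two schemes are
provided:

* ``grouped-folds`` (default): a seeded shuffle partitions the compounds into
  ceil(n / holdout) folds of as equal size as possible; each fold is predicted
  once from a model refitted on its complement, so every compound is held out
  exactly once and PRESS_cv accumulates n squared prediction errors.
* ``repeated-random-splits``: ``repeats`` independent random holdouts of the
  nominal size; squared errors are averaged per held-out prediction and
  rescaled to n predictions so PRESS_cv is comparable across schemes.

Q2_cv = 1 - PRESS_cv / SS uses the corrected total sum of squares of the full
response as denominator.  The conventional quality bar for a QSAR model is
Q2_cv > 0.6, equivalently PRESS_cv / SS < 0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import LogBBModel, LogBBResults

__all__ = ["CvResult", "CvStability", "leave_group_out_cv", "cv_stability"]

SCHEMES = ("grouped-folds", "repeated-random-splits")


@dataclass
class CvResult:
    """One cross-validation run (fully determined by config + seed)."""

    holdout_fraction: float
    holdout_size: int                 # nominal ceil(fraction * n)
    scheme: str
    repeats: int
    seed: int
    press_cv: float
    q2_cv: float
    ss_total: float
    per_fold: list[tuple[list[int], float]] = field(repr=False)

    @property
    def press_over_ss(self) -> float:
        return self.press_cv / self.ss_total

    def passes_quality_bar(self) -> bool:
        """Q2_cv > 0.6 and PRESS/SS < 0.4."""
        return self.q2_cv > 0.6 and self.press_over_ss < 0.4


@dataclass
class CvStability:
    """Dispersion of Q2_cv across seeds plus the PRESS/SS quality check."""

    n_seeds: int
    q2_mean: float
    q2_sd: float
    press_cv_mean: float
    all_pass_quality_bar: bool
    results: list[CvResult] = field(repr=False)


def _refit_predict(model: LogBBModel, train: np.ndarray, test: np.ndarray) -> np.ndarray:
    X, y = model.design, model.endog
    sub = X[train]
    singular = np.linalg.svd(sub, compute_uv=False)
    if singular[-1] / singular[0] < 1e-10:
        raise ValueError("training subset is rank deficient")
    beta, *_ = np.linalg.lstsq(sub, y[train], rcond=None)
    return X[test] @ beta


def leave_group_out_cv(
    results_or_model,
    *,
    fraction: float = 0.30,
    scheme: str = "grouped-folds",
    repeats: int | None = None,
    seed: int = 0,
) -> CvResult:
    """Leave-``fraction``-out cross-validation of a fitted model.

    Parameters
    ----------
    results_or_model : LogBBResults or LogBBModel
        The model specification to validate (refits use the same design).
    fraction : float
        Holdout fraction in (0, 1); nominal holdout size is ceil(fraction*n).
    scheme : {"grouped-folds", "repeated-random-splits"}
    repeats : int, optional
        Number of random splits (repeated-random-splits only; default 100).
        Grouped folds always make one pass (repeats = 1).
    seed : int
        Seed for the partition shuffle / split draws.
    """
    model = (
        results_or_model.model
        if isinstance(results_or_model, LogBBResults)
        else results_or_model
    )
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    n = model.n
    holdout = math.ceil(fraction * n)
    if n - holdout <= model.p + 1:
        raise ValueError("training complement too small to fit the model")
    y = model.endog
    ss_total = float(np.sum((y - y.mean()) ** 2))
    rng = np.random.default_rng(seed)

    per_fold: list[tuple[list[int], float]] = []
    if scheme == "grouped-folds":
        repeats = 1
        order = rng.permutation(n)
        n_folds = math.ceil(n / holdout)
        folds = np.array_split(order, n_folds)
        press = 0.0
        for fold in folds:
            train = np.setdiff1d(order, fold)
            pred = _refit_predict(model, train, fold)
            fold_press = float(np.sum((y[fold] - pred) ** 2))
            press += fold_press
            per_fold.append((sorted(int(i) for i in fold), fold_press))
        press_cv = press
    else:
        repeats = 100 if repeats is None else int(repeats)
        if repeats < 1:
            raise ValueError("repeats must be >= 1")
        total, count = 0.0, 0
        for _ in range(repeats):
            fold = rng.choice(n, size=holdout, replace=False)
            train = np.setdiff1d(np.arange(n), fold)
            pred = _refit_predict(model, train, fold)
            fold_press = float(np.sum((y[fold] - pred) ** 2))
            total += fold_press
            count += holdout
            per_fold.append((sorted(int(i) for i in fold), fold_press))
        press_cv = total / count * n  # scale to n held-out predictions

    return CvResult(
        holdout_fraction=fraction,
        holdout_size=holdout,
        scheme=scheme,
        repeats=repeats,
        seed=int(seed),
        press_cv=press_cv,
        q2_cv=1.0 - press_cv / ss_total,
        ss_total=ss_total,
        per_fold=per_fold,
    )


def cv_stability(
    results_or_model,
    *,
    n_seeds: int = 50,
    seed0: int = 0,
    **cv_kwargs,
) -> CvStability:
    """Run :func:`leave_group_out_cv` over ``n_seeds`` seeds and summarise."""
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    runs = [
        leave_group_out_cv(results_or_model, seed=seed0 + i, **cv_kwargs)
        for i in range(n_seeds)
    ]
    q2 = np.array([r.q2_cv for r in runs])
    return CvStability(
        n_seeds=n_seeds,
        q2_mean=float(q2.mean()),
        q2_sd=float(q2.std(ddof=1)),
        press_cv_mean=float(np.mean([r.press_cv for r in runs])),
        all_pass_quality_bar=all(r.passes_quality_bar() for r in runs),
        results=runs,
    )
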