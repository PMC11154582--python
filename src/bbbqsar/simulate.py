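"""Synthetic compound panels and retention series with known ground truth.

The generator emulates the statistical structure of the study panel, not its
chemistry: a latent *size* factor drives MW and polarizability jointly
(strongly correlated), a latent *polarity* factor drives TPSA and the
hydrogen-bond counts, NRB is a small integer weakly coupled to both, the
lipophilicity index log k_w,IAM co-varies with molecular size, and the
response is generated from a known linear model

    log BB = b0 + b1 log k_w,IAM + b2 MW + b3 (HBD + HBA) + N(0, noise_sd)

whose default coefficients and noise level match the fitted study model
(noise_sd = sqrt(MSE) = sqrt(0.01355)).  Because ground truth is stored,
every pipeline stage — extrapolation, chemometrics, fitting, validation,
applicability domain — can be tested for parameter recovery.

All randomness flows from one integer seed through spawned child generators,
so sub-streams (descriptors, response noise, retention noise) are mutually
independent and individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .retention import RetentionMeasurement

__all__ = ["GeneratorConfig", "SyntheticPanel", "generate_panel",
           "generate_retention_series"]

#: Default true coefficients (intercept, log_kw_iam, mw, hb_total).
DEFAULT_COEFFICIENTS = {
    "const": -0.0004,
    "log_kw_iam": 0.0081,
    "mw": 0.0044,
    "hb_total": -0.2030,
}

DEFAULT_NOISE_SD = float(np.sqrt(0.01355))


class ConfigError(ValueError):
    """Infeasible generator configuration (e.g. impossible correlations)."""


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic panel generator.

    Descriptor location/scale and ranges mirror the study panel (MW in
    [186.21, 430.11] g/mol, TPSA in [33.95, 121.85] A^2, HBD in {0, 3},
    HBA in 4..10); correlation targets mirror the chemometric structure the
    pipeline must detect (corr(MW, alpha) ~ 0.9, corr(TPSA, HB) ~ 0.92).
    """

    n_compounds: int = 126
    seed: int = 0
    true_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    noise_sd: float = DEFAULT_NOISE_SD
    size_corr: float = 0.90          # target corr(MW, alpha)
    polarity_corr: float = 0.92      # target corr(TPSA, HB_total latent)
    factor_corr: float = 0.15        # corr(size factor, polarity factor)
    lipophilicity_corr: float = 0.70  # corr(log_kw, size factor)
    mw_loc: float = 320.0
    mw_scale: float = 45.0
    mw_range: tuple[float, float] = (186.21, 430.11)
    alpha_loc: float = 33.0
    alpha_scale: float = 4.5
    alpha_range: tuple[float, float] = (21.80, 41.43)
    tpsa_loc: float = 65.0
    tpsa_scale: float = 22.0
    tpsa_range: tuple[float, float] = (33.95, 121.85)
    hba_loc: float = 6.0
    hba_scale: float = 1.5
    hbd_threshold: float = 1.45      # polarity z above this -> HBD = 3
    logkw_loc: float = 1.7
    logkw_scale: float = 0.9
    logkw_range: tuple[float, float] = (-0.27, 3.40)
    # retention design (isocratic series)
    phi_levels: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5)
    replicates: int = 3
    retention_noise_sd: float = 0.02

    def validate(self) -> None:
        p = len(self.true_coefficients) - 1
        if self.n_compounds < p + 2:
            raise ConfigError(f"n_compounds must be >= {p + 2}")
        if self.noise_sd < 0 or self.retention_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        for name in ("size_corr", "polarity_corr", "lipophilicity_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.factor_corr <= 1.0:
            raise ConfigError("factor_corr must be in [-1, 1]")
        # 2x2 latent factor covariance must be positive semi-definite
        if 1.0 - self.factor_corr**2 < 0:
            raise ConfigError("latent factor covariance is not PSD")


@dataclass
class SyntheticPanel:
    """Generated panel plus the ground truth that produced it."""

    frame: pd.DataFrame
    true_coefficients: dict
    noise_sd: float
    config: GeneratorConfig

    def truth_dict(self) -> dict:
        return {
            "true_coefficients": self.true_coefficients,
            "noise_sd": self.noise_sd,
            "seed": self.config.seed,
            "n_compounds": self.config.n_compounds,
        }


def _mix(rng, factor: np.ndarray, loading: float) -> np.ndarray:
    """loading*factor + orthogonal Gaussian noise, unit marginal variance."""
    return loading * factor + np.sqrt(1.0 - loading**2) * rng.standard_normal(factor.size)


def generate_panel(config: Optional[GeneratorConfig] = None) -> SyntheticPanel:
    """Draw a synthetic compound panel from the configured latent structure."""
    config = config or GeneratorConfig()
    config.validate()
    n = config.n_compounds
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(4)]
    rng_factor, rng_desc, rng_kw, rng_noise = streams

    size = rng_factor.standard_normal(n)
    polarity = _mix(rng_factor, size, config.factor_corr)

    # corr(MW, alpha) = l_mw * l_alpha; split the target evenly
    l_size = np.sqrt(config.size_corr)
    mw_z = _mix(rng_desc, size, l_size)
    alpha_z = _mix(rng_desc, size, l_size)
    l_pol = np.sqrt(config.polarity_corr)
    tpsa_z = _mix(rng_desc, polarity, l_pol)
    hb_z = _mix(rng_desc, polarity, l_pol)

    mw = np.clip(config.mw_loc + config.mw_scale * mw_z, *config.mw_range)
    alpha = np.clip(config.alpha_loc + config.alpha_scale * alpha_z,
                    *config.alpha_range)
    tpsa = np.clip(config.tpsa_loc + config.tpsa_scale * tpsa_z,
                   *config.tpsa_range)
    hba = np.clip(np.rint(config.hba_loc + config.hba_scale * hb_z), 4, 10).astype(int)
    hbd = np.where(hb_z > config.hbd_threshold, 3, 0)
    nrb = np.clip(
        np.rint(3.0 + 1.2 * (0.5 * size + 0.5 * polarity)
                + 0.8 * rng_desc.standard_normal(n)),
        0, 7,
    ).astype(int)
    log_kw = np.clip(
        config.logkw_loc + config.logkw_scale * _mix(rng_kw, size, config.lipophilicity_corr),
        *config.logkw_range,
    )

    frame = pd.DataFrame(
        {
            "compound_id": np.arange(1, n + 1),
            "class": "SYN",
            "mw": mw,
            "nrb": nrb,
            "hbd": hbd,
            "hba": hba,
            "tpsa": tpsa,
            "alpha": alpha,
            "log_kw_iam": log_kw,
        }
    )
    frame["hb_total"] = frame["hbd"] + frame["hba"]
    beta = config.true_coefficients
    truth = (
        beta["const"]
        + beta["log_kw_iam"] * frame["log_kw_iam"]
        + beta["mw"] * frame["mw"]
        + beta["hb_total"] * frame["hb_total"]
    )
    frame["log_bb_true"] = truth
    frame["log_bb"] = truth + config.noise_sd * rng_noise.standard_normal(n)
    return SyntheticPanel(
        frame=frame,
        true_coefficients=dict(beta),
        noise_sd=config.noise_sd,
        config=config,
    )


def generate_retention_series(
    log_kw_true: float,
    s_true: float,
    *,
    phi_levels: Sequence[float] = (0.2, 0.3, 0.4, 0.5),
    replicates: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
    compound_id: int = 1,
    as_times: bool = False,
    t_0: float = 1.0,
) -> list[RetentionMeasurement]:
    """Simulate isocratic measurements log k = log_kw - s*phi + noise.

    With ``as_times=True`` the measurements are emitted as (t_r, t_0) pairs
    with the fixed dead time ``t_0`` (t_r = t_0 (1 + 10**log_k)), which
    round-trips exactly through the retention-factor computation.
    """
    if len(phi_levels) < 2:
        raise ValueError("need at least 2 phi levels")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[RetentionMeasurement] = []
    for phi in phi_levels:
        for _ in range(replicates):
            log_k = log_kw_true - s_true * phi + noise_sd * rng.standard_normal()
            if as_times:
                out.append(
                    RetentionMeasurement(
                        compound_id=compound_id, phi=float(phi),
                        t_r=t_0 * (1.0 + 10.0**log_k), t_0=t_0,
                    )
                )
            else:
                out.append(
                    RetentionMeasurement(
                        compound_id=compound_id, phi=float(phi), log_k=float(log_k)
                    )
                )
    return out
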