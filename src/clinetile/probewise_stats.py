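"""Per-probe North-vs-South tests with empirical-Bayes variance moderation.

Each larval stage is analysed separately as a two-group comparison. Per probe,
the effect is the North-minus-South mean difference on the normalized scale
and s2 the pooled within-group variance on d = n_N + n_S - 2 degrees of
freedom. The probe variances are then shrunk toward a prior: the hierarchical
model places a scaled inverse chi-square prior (d0, s0^2) on the true residual
variances, estimated across probes by matching the moments of log s2
(digamma/trigamma identities for the log of a chi-square variate). The
moderated variance is the posterior mean

    s2_tilde = (d0*s0^2 + d*s2) / (d0 + d)

and the moderated t = effect / sqrt(s2_tilde * (1/n_N + 1/n_S)) is referred to
a Student t distribution with d0 + d degrees of freedom (Normal when d0 is
infinite, i.e. when the observed log-variances spread no more than chi-square
sampling noise alone would).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass(frozen=True)
class ModerationPrior:
    """Hyperparameters of the variance prior: prior df d0 (may be inf) and
    prior variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0 and math.isfinite(self.s0_sq)):
            raise ValueError("s0_sq must be positive and finite")


def fit_probe_model(normalized: pd.DataFrame, design: pd.DataFrame,
                    stage: str) -> pd.DataFrame:
    """Per-probe effect, pooled variance and residual df for one stage.

    Returns a DataFrame indexed like ``normalized`` with columns
    ``effect, s2, df, n_north, n_south``; effect is North minus South.
    """
    sub = design[design["stage"] == stage]
    north = sub[sub["cline_end"] == "North"]["array_id"].tolist()
    south = sub[sub["cline_end"] == "South"]["array_id"].tolist()
    if len(north) < 2 or len(south) < 2:
        raise ValueError(f"stage {stage}: need >= 2 arrays per cline end")
    xn = normalized[north].to_numpy(dtype=float)
    xs = normalized[south].to_numpy(dtype=float)
    n1, n2 = xn.shape[1], xs.shape[1]
    effect = xn.mean(axis=1) - xs.mean(axis=1)
    ss = ((xn - xn.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((xs - xs.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    return pd.DataFrame(
        {"effect": effect, "s2": ss / d, "df": float(d),
         "n_north": n1, "n_south": n2},
        index=normalized.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: float) -> ModerationPrior:
    """Method-of-moments empirical-Bayes fit of the variance prior.

    With z = log s2, E[z] = log s0^2 + psi(d/2) - psi(d0/2) - log(d/d0) and
    Var[z] = psi'(d/2) + psi'(d0/2); the excess of var(z) over the chi-square
    sampling term psi'(d/2) identifies d0, the mean then identifies s0^2.
    When there is no excess spread, d0 = inf and s2_tilde = s0^2 for all probes.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all probe variances are zero; no variance structure")
    if positive.size < 10:
        raise ValueError("need >= 10 probes with positive variance")
    z = np.log(positive)
    mean_z = float(np.mean(z))
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        s0_sq = math.exp(mean_z - special.digamma(d / 2.0) + math.log(d / 2.0))
        return ModerationPrior(d0=math.inf, s0_sq=s0_sq)
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0 = (mean_z - special.digamma(d / 2.0) + special.digamma(d0 / 2.0)
              + math.log(d / d0))
    return ModerationPrior(d0=d0, s0_sq=math.exp(log_s0))


def moderated_t(effect: np.ndarray, s2: np.ndarray, d: float,
                prior: ModerationPrior, n_north: int, n_south: int) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values.

    Returns ``s2_tilde, t, df_total, p, degenerate``; probes where the
    moderated variance is exactly zero cannot be referred to a t distribution
    and are flagged ``degenerate`` with p = 0.
    """
    effect = np.asarray(effect, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(prior.d0):
        s2_tilde = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_tilde = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    scale = 1.0 / n_north + 1.0 / n_south
    degenerate = s2_tilde == 0
    se = np.sqrt(np.where(degenerate, np.nan, s2_tilde) * scale)
    t = effect / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    t = np.where(degenerate, np.where(effect == 0, 0.0, np.sign(effect) * np.inf), t)
    p = np.where(degenerate, 0.0, p)
    return pd.DataFrame(
        {"s2_tilde": s2_tilde, "t": t, "df_total": df_total, "p": p,
         "degenerate": degenerate}
    )


def probe_statistics(normalized: pd.DataFrame, design: pd.DataFrame,
                     stage: str) -> pd.DataFrame:
    """Fit, moderate and test all probes for one stage.

    Returns a DataFrame indexed by probe with columns ``effect, s2, df,
    s2_tilde, t, df_total, p, degenerate``.
    """
    fit = fit_probe_model(normalized, design, stage)
    prior = estimate_prior(fit["s2"].to_numpy(), float(fit["df"].iloc[0]))
    mod = moderated_t(fit["effect"].to_numpy(), fit["s2"].to_numpy(),
                      float(fit["df"].iloc[0]), prior,
                      int(fit["n_north"].iloc[0]), int(fit["n_south"].iloc[0]))
    mod.index = fit.index
    return pd.concat([fit[["effect", "s2", "df"]], mod], axis=1)
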