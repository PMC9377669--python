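"""Moderated-t differential expression with BH-FDR and significance flags.

Per condition (compound × concentration tier), treated replicates are
compared against the matched batch controls with an empirical-Bayes
moderated two-sample t-statistic: per-probe residual variances s_g^2 (pooled
two-group, d = n_t + n_c - 2 df) are shrunk toward a prior (d0, s0^2) fitted
across the complete set of probe sets by the classical method of moments on
log variances.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the t-statistic, which is referred to a Student t
distribution with d0 + d degrees of freedom (standard normal when d0 is
infinite).  P-values are BH-adjusted, and a probe set counts as
significantly deregulated (SPS) when the adjusted p-value is < 0.05 and the
absolute fold change exceeds 2 (|log2 FC| > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from . import preprocess

__all__ = [
    "FDR_CUTOFF",
    "LOG2FC_CUTOFF",
    "ModerationParams",
    "estimate_moderation",
    "moderated_t",
    "bh_adjust",
    "flag_significant",
    "flag_and_count",
    "run_condition",
]

FDR_CUTOFF = 0.05
LOG2FC_CUTOFF = 1.0  # |FC| > 2
MIN_PROBES_FOR_MODERATION = 10


@dataclass(frozen=True)
class ModerationParams:
    """Prior for the per-probe variances: s_g^2 ~ s0^2 * d0 / chi2_{d0}."""

    d0: float  # prior degrees of freedom, may be +inf
    s0_sq: float  # prior variance, log2^2 units

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("prior variance s0_sq must be > 0")


def _trigamma_inverse(target: float, rel_tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = target for y > 0 (Newton on 1/trigamma)."""
    if target <= 0:
        return np.inf
    y = 0.5 + 1.0 / target
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        delta = tri * (1.0 - tri / target) / special.polygamma(2, y)
        y += delta
        if abs(delta) < rel_tol * y:
            break
    return float(y)


def estimate_moderation(sample_variances: np.ndarray, d: float) -> ModerationParams:
    """Method-of-moments fit of (d0, s0^2) from per-probe variances.

    Works on e_g = log s_g^2 - digamma(d/2) + log(d/2), whose mean estimates
    log sigma^2 under the scaled-chi-square sampling model and whose excess
    spread over trigamma(d/2) estimates trigamma(d0/2).  Zero variances are
    excluded from the fit; at least ``MIN_PROBES_FOR_MODERATION`` positive
    variances are required.
    """
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    v = np.asarray(sample_variances, dtype=float)
    v = v[np.isfinite(v)]
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("all sample variances are zero: degenerate input")
    if pos.size < MIN_PROBES_FOR_MODERATION:
        raise ValueError(
            f"need >= {MIN_PROBES_FOR_MODERATION} probes with positive variance, "
            f"got {pos.size}"
        )
    e = np.log(pos) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    target = float(np.var(e, ddof=1) - special.polygamma(1, d / 2.0))
    if target <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(target)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    treated: pd.DataFrame | np.ndarray,
    control: pd.DataFrame | np.ndarray,
    params: ModerationParams,
) -> pd.DataFrame:
    """Per-probe moderated t against matched controls.

    ``treated`` and ``control`` are probe × replicate arrays on the log2
    scale.  Returns a frame with log2fc, fc (signed, |fc| = 2^|log2fc|),
    t_mod and two-sided p_raw.
    """
    index = treated.index if isinstance(treated, pd.DataFrame) else None
    t_arr = np.asarray(treated, dtype=float)
    c_arr = np.asarray(control, dtype=float)
    if t_arr.ndim != 2 or c_arr.ndim != 2 or t_arr.shape[0] != c_arr.shape[0]:
        raise ValueError("treated and control must be probe x replicate arrays")
    n_t, n_c = t_arr.shape[1], c_arr.shape[1]
    d = n_t + n_c - 2
    if d < 1:
        raise ValueError("fewer than 1 residual degree of freedom")

    log2fc = t_arr.mean(axis=1) - c_arr.mean(axis=1)
    ss = ((t_arr - t_arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (c_arr - c_arr.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = ss / d

    if np.isinf(params.d0):
        s_tilde_sq = np.full_like(s_sq, params.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (params.d0 * params.s0_sq + d * s_sq) / (params.d0 + d)
        df_total = params.d0 + d

    se = np.sqrt(s_tilde_sq * (1.0 / n_t + 1.0 / n_c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    fc = np.sign(log2fc) * 2.0 ** np.abs(log2fc)
    fc = np.where(log2fc == 0, 1.0, fc)

    out = pd.DataFrame(
        {"log2fc": log2fc, "fc": fc, "t_mod": t_mod, "p_raw": p_raw}, index=index
    )
    out.index.name = "probe_id"
    return out


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_significant(table: pd.DataFrame) -> pd.DataFrame:
    """Add p_fdr / significant / direction columns to a moderated-t frame."""
    out = table.copy()
    if "p_fdr" not in out.columns:
        out["p_fdr"] = bh_adjust(out["p_raw"].to_numpy())
    sig = (out["p_fdr"] < FDR_CUTOFF) & (out["log2fc"].abs() > LOG2FC_CUTOFF)
    out["significant"] = sig
    direction = np.where(
        sig & (out["log2fc"] > 0), "up", np.where(sig & (out["log2fc"] < 0), "down", "none")
    )
    out["direction"] = direction
    return out


def flag_and_count(table: pd.DataFrame) -> tuple[int, int, set]:
    """(n_up, n_down, SPS id set) from a flagged differential-expression table."""
    if "significant" not in table.columns or "direction" not in table.columns:
        table = flag_significant(table)
    up = table.index[table["direction"] == "up"]
    down = table.index[table["direction"] == "down"]
    return len(up), len(down), set(up) | set(down)


def run_condition(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    compound: str,
    tier: str,
    annotations: pd.DataFrame | None = None,
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Full differential-expression table for one condition.

    Splits the matrix into treated replicates and matched batch controls,
    fits the variance prior on the complete probe-set collection of this
    contrast (unless ``params`` is supplied), and returns the flagged table.
    """
    treated, control = preprocess.split_condition(
        matrix, sheet, compound, tier, annotations=annotations
    )
    n_t, n_c = treated.shape[1], control.shape[1]
    d = n_t + n_c - 2
    if params is None:
        t_arr = treated.to_numpy(dtype=float)
        c_arr = control.to_numpy(dtype=float)
        ss = ((t_arr - t_arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (c_arr - c_arr.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        params = estimate_moderation(ss / d, d)
    table = moderated_t(treated, control, params)
    return flag_significant(table)
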