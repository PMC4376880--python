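"""Transient-reporter mixed-model analysis.

Background-subtracted luminescence from promoter-reporter / driver-plasmid
co-transfections is fitted, after log10 transformation, to

    log10(RLU) ~ promoter + promoter:driver + (1 | set:replicate)

with the empty-vector (control) driver as the reference level, so each
promoter:driver interaction coefficient is the log10 fold-change the driver
induces on that promoter relative to its basal activity.  Wald p-values on
the interaction coefficients are Benjamini-Hochberg adjusted jointly across
all tested promoter x driver relationships, and each relationship is called
positive, negative, or none at FDR threshold ``alpha``.

With only a handful of set:replicate groups the random-intercept variance is
frequently estimated at zero; the fit then falls back to ordinary least
squares with set:replicate as a fixed blocking factor, recorded in the
``method`` column of the output.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from . import constants as cst

__all__ = [
    "preprocess_measurements",
    "fit_reporter_model",
    "bh_adjust",
    "classify_regulation",
]


def preprocess_measurements(
    raw: pd.DataFrame,
    background: float = 0.0,
    floor: float = 1.0,
    value_column: str = "rlu",
) -> pd.DataFrame:
    """Subtract the background signal, flooring at ``floor`` to keep log10
    defined downstream.

    Rejects input in which every reading is at or below background, since no
    signal survives the subtraction.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    vals = raw[value_column].astype(float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite luminescence values")
    if (vals <= background).all():
        raise ValueError("all readings at or below background")
    out = raw.copy()
    out[value_column] = np.maximum(vals - background, floor)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    For sorted p-values p_(1) <= ... <= p_(m), q_(i) = min_{j>=i} m*p_(j)/j,
    clipped at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _wald_pvalues(estimates: np.ndarray, ses: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation Wald p-values with a zero-SE guard.

    Zero residual variance (exactly reproduced cell means, e.g. noiseless
    synthetic data) gives SE = 0: a non-zero estimate is then unambiguous
    (p = 0) and a zero estimate carries no evidence (p = 1).
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    p = np.ones_like(est)
    degenerate = se < 1e-12
    ok = ~degenerate
    p[ok] = 2.0 * stats.norm.sf(np.abs(est[ok]) / se[ok])
    p[degenerate & (np.abs(est) > 1e-10)] = 0.0
    return p


_INTERACTION_RE = re.compile(
    r"C\(promoter\)\[(?P<promoter>[^\]]+)\]:"
    r"C\(driver, Treatment\('control'\)\)\[T\.(?P<driver>[^\]]+)\]"
)

_FORMULA = (
    "log10_rlu ~ 0 + C(promoter) + C(promoter):C(driver, Treatment('control'))"
)


def fit_reporter_model(
    measurements: pd.DataFrame,
    alpha: float = cst.DEFAULT_ALPHA,
    use_mixed: bool = True,
) -> pd.DataFrame:
    """Estimate promoter:driver interaction effects from a reporter table.

    Expects columns ``promoter, driver, set, replicate, rlu`` with every
    promoter measured under the control driver; readings must already be
    background-subtracted and positive.  Returns one row per (promoter,
    driver != control): ``promoter, driver, effect_log10, se, p, q, call,
    method``.
    """
    df = measurements.copy()
    required = {"promoter", "driver", "set", "replicate", "rlu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (df["rlu"] <= 0).any():
        raise ValueError("non-positive rlu; run preprocess_measurements first")
    if cst.CONTROL_DRIVER not in set(df["driver"]):
        raise ValueError("control-driver measurements are required")
    cells = df.groupby(["promoter", "driver"], sort=False).size()
    n_expected = df["promoter"].nunique() * df["driver"].nunique()
    if len(cells) < n_expected:
        raise ValueError("incomplete promoter x driver factorial")

    df["log10_rlu"] = np.log10(df["rlu"].astype(float))
    df["set_rep"] = df["set"].astype(str) + ":" + df["replicate"].astype(str)
    if df["set_rep"].nunique() < 2:
        raise ValueError("need >= 2 set:replicate groups")

    params = se = None
    method = "mixedlm"
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(_FORMULA, df, groups=df["set_rep"]).fit(reml=True)
            if np.all(np.isfinite(res.bse_fe)) and res.cov_re.iloc[0, 0] > 1e-8:
                params, se = res.fe_params, res.bse_fe
        except Exception:
            pass
    if params is None:
        method = "ols_block"
        res = smf.ols(_FORMULA + " + C(set_rep)", df).fit()
        params, se = res.params, res.bse

    rows = []
    for name, est in params.items():
        m = _INTERACTION_RE.fullmatch(name)
        if not m:
            continue
        rows.append(
            (m["promoter"], m["driver"], float(est), float(se[name]))
        )
    out = pd.DataFrame(rows, columns=["promoter", "driver", "effect_log10", "se"])
    out = out.sort_values(["promoter", "driver"], ignore_index=True)
    out["p"] = _wald_pvalues(out["effect_log10"].to_numpy(), out["se"].to_numpy())
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["method"] = method
    return classify_regulation(out, alpha=alpha)


def classify_regulation(
    estimates: pd.DataFrame, alpha: float = cst.DEFAULT_ALPHA
) -> pd.DataFrame:
    """Call each relationship positive/negative/none at FDR threshold alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out = estimates.copy()
    sig = out["q"] < alpha
    out["call"] = "none"
    out.loc[sig & (out["effect_log10"] > 0), "call"] = "positive"
    out.loc[sig & (out["effect_log10"] < 0), "call"] = "negative"
    return out
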