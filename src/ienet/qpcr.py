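"""Absolute qPCR quantitation and knockout genotype-effect estimation.

A dilution series of known template amounts yields a standard curve,
Ct = intercept + slope * log10(copies); unknown Cts are inverted through it
to absolute copy numbers, scaled per 1e6 cells.  Technical replicates are
averaged on the linear copy scale (Ct-scale averaging is available by flag),
then log2-transformed.  Per target, log2 copy numbers are fitted to

    log2(copies) ~ genotype + (1 | biological replicate)

with the control (unmodified) genotype as reference; the negated genotype
effect of a knockout is reported as the implied regulatory activity of the
deleted wild-type gene on the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from . import constants as cst
from .reporter_effects import bh_adjust, _wald_pvalues

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "estimate_copy_numbers",
    "collapse_technical",
    "fit_genotype_model",
    "regulatory_activity",
]


@dataclass
class StandardCurve:
    intercept: float   # Ct at log10(copies) = 0, i.e. a single copy
    slope: float       # Ct per log10 copies, < 0
    r_squared: float
    ct_min: float      # Ct range spanned by the standards
    ct_max: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies_from_ct(self, ct) -> np.ndarray:
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(
    standards: pd.DataFrame, min_r_squared: float = 0.98
) -> StandardCurve:
    """Least-squares line of Ct on log10(copies) from a dilution table.

    Requires >= 3 dilution points spanning >= 2 orders of magnitude; a
    positive slope is an error, and a weak fit (R^2 below ``min_r_squared``)
    only warns.
    """
    copies = standards["copies"].astype(float)
    ct = standards["ct"].astype(float)
    if (copies <= 0).any():
        raise ValueError("standard amounts must be positive")
    if copies.nunique() < 3:
        raise ValueError("need >= 3 distinct dilution points")
    span = np.log10(copies.max() / copies.min())
    if span < 2:
        raise ValueError(f"standards span {span:.2f} < 2 orders of magnitude")
    res = stats.linregress(np.log10(copies), ct)
    if res.slope >= 0:
        raise ValueError("standard curve slope must be negative")
    r2 = float(res.rvalue**2)
    if r2 < min_r_squared:
        warnings.warn(f"standard curve R^2 = {r2:.4f} below {min_r_squared}")
    return StandardCurve(
        float(res.intercept), float(res.slope), r2, float(ct.min()), float(ct.max())
    )


def estimate_copy_numbers(
    ct_table: pd.DataFrame,
    curve: StandardCurve,
    cells_assayed: float = 1e6,
    per_cells: float = 1e6,
    technical_rule: str = "copies_mean",
) -> pd.DataFrame:
    """Convert a (target, genotype, bio_rep, tech_rep, ct) table to one
    log2 copy number per (target, genotype, biological replicate).

    Technical replicates are collapsed by their mean on the copy scale
    (default) or on the Ct scale (``technical_rule="ct_mean"``).  Cts outside
    the fitted standards' range are flagged ``extrapolated`` with a warning,
    not rejected.
    """
    if cells_assayed <= 0 or per_cells <= 0:
        raise ValueError("cell counts must be positive")
    if technical_rule not in ("copies_mean", "ct_mean"):
        raise ValueError("technical_rule must be 'copies_mean' or 'ct_mean'")
    df = ct_table.copy()
    scale = per_cells / cells_assayed
    out_of_range = (df["ct"] < curve.ct_min) | (df["ct"] > curve.ct_max)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} Ct value(s) outside the standard range "
            f"[{curve.ct_min:.2f}, {curve.ct_max:.2f}]; extrapolating"
        )
    df["_extrapolated"] = out_of_range

    rows = []
    for (target, genotype, bio), grp in df.groupby(
        ["target", "genotype", "bio_rep"], sort=True
    ):
        if technical_rule == "copies_mean":
            copies = float(np.mean(curve.copies_from_ct(grp["ct"]))) * scale
        else:
            copies = float(curve.copies_from_ct(np.mean(grp["ct"]))) * scale
        rows.append(
            (target, genotype, bio, copies, np.log2(copies), bool(grp["_extrapolated"].any()))
        )
    return pd.DataFrame(
        rows,
        columns=["target", "genotype", "bio_rep", "copies", "log2_copies", "extrapolated"],
    )


def collapse_technical(panel: pd.DataFrame) -> pd.DataFrame:
    """Collapse simulated copy-scale technical replicates without a curve.

    Mean of the technical replicates on the copy scale, then log2; used when
    the table already carries true copy numbers (e.g. synthetic panels).
    """
    grouped = (
        panel.groupby(["target", "genotype", "bio_rep"], sort=True)["copies"]
        .mean()
        .reset_index()
    )
    grouped["log2_copies"] = np.log2(grouped["copies"])
    return grouped


def fit_genotype_model(
    records: pd.DataFrame,
    target: str | None = None,
    control: str = cst.CONTROL_GENOTYPE,
    alpha: float = cst.DEFAULT_ALPHA,
    use_mixed: bool = True,
) -> pd.DataFrame:
    """Fit the per-target genotype-effect model on log2 copy numbers.

    ``records`` needs columns ``target, genotype, bio_rep, log2_copies`` for
    a single target (or pass ``target=`` to subset).  Fixed genotype effects
    are contrasts against the control genotype; the biological replicate is
    a random intercept with an OLS fixed-block fallback on singular fits.
    BH adjustment is applied within the target across its genotype
    contrasts.  Returns ``target, genotype, effect_log2, se, p, q, call,
    regulatory_activity, method`` (the control row has effect 0 and call
    "reference").
    """
    df = records.copy()
    if target is not None:
        df = df[df["target"] == target]
    else:
        uniq = df["target"].unique()
        if len(uniq) != 1:
            raise ValueError("records span multiple targets; pass target=")
        target = uniq[0]
    genos = df["genotype"].unique()
    if control not in genos:
        raise ValueError(f"control genotype {control!r} absent")
    if len(genos) < 2:
        raise ValueError("need >= 2 genotypes including control")
    if df["bio_rep"].nunique() < 2:
        raise ValueError("need >= 2 biological replicates")

    formula = f"log2_copies ~ C(genotype, Treatment({control!r}))"
    params = se = None
    method = "mixedlm"
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(formula, df, groups=df["bio_rep"]).fit(reml=True)
            if np.all(np.isfinite(res.bse_fe)) and res.cov_re.iloc[0, 0] > 1e-8:
                params, se = res.fe_params, res.bse_fe
        except Exception:
            pass
    if params is None:
        method = "ols_block"
        res = smf.ols(formula + " + C(bio_rep)", df).fit()
        params, se = res.params, res.bse

    prefix = f"C(genotype, Treatment({control!r}))[T."
    rows = []
    for name, est in params.items():
        if name.startswith(prefix):
            rows.append((name[len(prefix):-1], float(est), float(se[name])))
    out = pd.DataFrame(rows, columns=["genotype", "effect_log2", "se"])
    out = out.sort_values("genotype", ignore_index=True)
    out["p"] = _wald_pvalues(out["effect_log2"].to_numpy(), out["se"].to_numpy())
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["call"] = "none"
    out.loc[(out["q"] < alpha) & (out["effect_log2"] > 0), "call"] = "positive"
    out.loc[(out["q"] < alpha) & (out["effect_log2"] < 0), "call"] = "negative"
    ref = pd.DataFrame(
        [{"genotype": control, "effect_log2": 0.0, "se": 0.0, "p": 1.0, "q": 1.0,
          "call": "reference"}]
    )
    out = pd.concat([ref, out], ignore_index=True)
    out.insert(0, "target", target)
    out["regulatory_activity"] = -out["effect_log2"]
    out["method"] = method
    return out


def regulatory_activity(effects: pd.DataFrame) -> pd.DataFrame:
    """Negate knockout genotype effects into wild-type regulatory activities.

    A knockout that lowers a transcript (negative effect) implies the
    deleted wild-type gene activates it (positive activity), and vice versa.
    """
    out = effects.copy()
    out["regulatory_activity"] = -out["effect_log2"].astype(float)
    return out
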