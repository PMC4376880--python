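"""Combinatorial knockout decomposition of IE gene expression.

Expression of a target IE gene across a panel of knockout viral genotypes is
modelled as an additive combination of factor contributions on the log2
scale::

    E ~ IE0 + IE1 + IE0:IE1 + IE2 + ME53 + PE38 + REST + (1 | replicate)

where each single-gene factor is a 0/1 presence indicator for the genotype,
the IE0:IE1 epistatic interaction indicator is the product of the IE0 and
IE1 indicators, and REST is an all-ones column absorbing host-factor and
basal contributions (there is no separate global intercept).  The target's
own gene never appears among its regressors, since its transcript cannot be
measured in genotypes that delete it.

A caveat inherent to the design: with single and double knockouts only, the
"IE0:IE1 interaction" coefficient absorbs every higher-order interaction
involving both IE0 and IE1 (e.g. IE0:IE1:IE2); the model cannot separate
them.  The same holds for the single-gene factors and their interactions
with untested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import constants as C
from .reporter_effects import bh_adjust, _wald_pvalues

__all__ = [
    "design_row",
    "build_design",
    "check_identifiability",
    "fit_contribution_model",
    "recovery_experiment",
]


def target_factors(target: str) -> list[str]:
    """Factor columns for one target: all factors minus the target's own."""
    own = C.GENE_TO_DRIVER.get(target)
    return [f for f in C.FACTORS if f != own]


def design_row(deleted: frozenset[str] | set[str], target: str) -> dict[str, float]:
    """Presence-indicator row for one genotype.

    1 iff the factor's gene is present in the genome; the IE0:IE1 indicator
    is the product of the IE0 and IE1 indicators; REST is always 1.
    """
    if target in deleted:
        raise ValueError(f"target {target!r} deleted in this genotype")
    present = {g: (0.0 if g in deleted else 1.0) for g in C.GENES}
    row: dict[str, float] = {}
    for f in target_factors(target):
        if f == C.REST_FACTOR:
            row[f] = 1.0
        elif f == C.INTERACTION_FACTOR:
            row[f] = present["ie0"] * present["ie1"]
        else:
            row[f] = present[f.lower()]
    return row


def build_design(
    genotypes: dict[str, frozenset[str]] | list[str],
    target: str,
) -> pd.DataFrame:
    """Design matrix (genotype x factor) for one target.

    ``genotypes`` is either a mapping genotype id -> set of deleted genes, or
    a list of canonical genotype names.  Raises on duplicate genotypes and on
    genotypes that delete the target.
    """
    if not isinstance(genotypes, dict):
        names = list(genotypes)
        if len(set(names)) != len(names):
            raise ValueError("duplicate genotypes")
        genotypes = {g: C.GENOTYPES[g] for g in names}
    rows = {g: design_row(deleted, target) for g, deleted in genotypes.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=target_factors(target))
    df.index.name = "genotype"
    return df


@dataclass
class RankReport:
    rank: int
    n_columns: int
    full_rank: bool
    collinear: list[str]


def check_identifiability(design: pd.DataFrame, strict: bool = False) -> RankReport:
    """Column-rank report for a design matrix.

    When rank-deficient, reports a set of columns whose removal restores full
    rank (greedy, in reverse column order).  With ``strict`` a deficient
    design raises.
    """
    X = design.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(X))
    collinear: list[str] = []
    if rank < design.shape[1]:
        keep = list(design.columns)
        for col in reversed(design.columns.tolist()):
            trial = [c for c in keep if c != col]
            if np.linalg.matrix_rank(design[trial].to_numpy(dtype=float)) == rank:
                keep = trial
                collinear.append(col)
            if len(keep) == rank:
                break
    report = RankReport(rank, design.shape[1], rank == design.shape[1], collinear)
    if strict and not report.full_rank:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {design.shape[1]} columns "
            f"(collinear: {', '.join(collinear)})"
        )
    return report


def fit_contribution_model(
    records: pd.DataFrame,
    design: pd.DataFrame,
    target: str | None = None,
    use_mixed: bool = True,
) -> pd.DataFrame:
    """Fit the no-intercept contribution model for one target.

    ``records`` needs columns ``genotype, bio_rep, log2_copies`` (a
    ``target`` column is used to subset when ``target`` is given).  Fixed
    effects are the indicator columns of ``design``; the biological
    replicate enters as a random intercept, falling back to a fixed blocking
    factor via OLS when the random-effect fit is singular.

    Returns one row per factor: ``target, factor, estimate, se, p, q,
    method``.  q-values are BH-adjusted across the target's factors.
    """
    df = records.copy()
    if target is not None and "target" in df.columns:
        df = df[df["target"] == target]
    elif target is None:
        targets = df["target"].unique() if "target" in df.columns else [None]
        if len(targets) == 1:
            target = targets[0]
        else:
            raise ValueError("records span multiple targets; pass target=")
    if df.empty:
        raise ValueError(f"no records for target {target!r}")
    if df["bio_rep"].nunique() < 2:
        raise ValueError("need >= 2 biological replicates")
    unknown = set(df["genotype"]) - set(design.index)
    if unknown:
        raise ValueError(f"genotypes missing from design: {sorted(unknown)}")
    check_identifiability(design, strict=True)

    X = design.loc[df["genotype"]].reset_index(drop=True)
    y = df["log2_copies"].reset_index(drop=True).astype(float)
    groups = df["bio_rep"].reset_index(drop=True)

    params = se = None
    method = "mixedlm"
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
            if np.all(np.isfinite(res.bse_fe)) and res.cov_re.iloc[0, 0] > 1e-8:
                params, se = res.fe_params, res.bse_fe
        except Exception:
            pass
    if params is None:
        method = "ols_block"
        block = pd.get_dummies(groups, prefix="rep", drop_first=True, dtype=float)
        res = sm.OLS(y, pd.concat([X, block], axis=1)).fit()
        params, se = res.params[design.columns], res.bse[design.columns]

    est = pd.Series(params, index=design.columns)[design.columns]
    ses = pd.Series(se, index=est.index)
    p = _wald_pvalues(est.to_numpy(), ses.to_numpy())
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "target": target,
            "factor": est.index,
            "estimate": est.to_numpy(dtype=float),
            "se": ses.to_numpy(dtype=float),
            "p": p,
            "q": q,
            "method": method,
        }
    ).reset_index(drop=True)


def decompose_all(records: pd.DataFrame, use_mixed: bool = True) -> pd.DataFrame:
    """Fit the contribution model separately per target present in ``records``.

    Targets without a published factor decomposition (ie0, ie1) are skipped.
    """
    out = []
    for target in sorted(records["target"].unique()):
        if target not in C.DECOMPOSITION_TARGETS:
            continue
        sub = records[records["target"] == target]
        design = build_design(list(C.decomposition_panel(target)), target)
        design = design.loc[[g for g in design.index if g in set(sub["genotype"])]]
        out.append(fit_contribution_model(sub, design, target, use_mixed=use_mixed))
    if not out:
        raise ValueError("no decomposable targets in records")
    return pd.concat(out, ignore_index=True)


def recovery_experiment(
    truth,
    n_sims: int = 200,
    seed: int = 0,
    targets: list[str] | None = None,
    use_mixed: bool = False,
) -> pd.DataFrame:
    """Repeated simulate-and-refit parameter recovery for the decomposition.

    For each simulation the knockout panel is regenerated from ``truth``
    (a :class:`~ienet.synthetic_data.DecompositionTruth`) with a per-run
    seed, copy records are rebuilt from the panel, and the contribution
    model is refitted per target.  Returns a per-(target, factor) summary:
    truth, mean estimate, bias, empirical SD of the estimates, mean model
    SE, coverage of +/-2*SE intervals, and the fraction of runs with a
    negative estimate.
    """
    from .synthetic_data import simulate_knockout_panel
    from .qpcr import collapse_technical

    if targets is None:
        targets = list(truth.coefficients)
    designs = {
        t: build_design(
            [g for g in C.decomposition_panel(t)], t
        )
        for t in targets
    }
    rows: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for i in range(n_sims):
        panel = simulate_knockout_panel(truth, seed=seed * 100003 + i, targets=targets)
        records = collapse_technical(panel)
        for t in targets:
            fit = fit_contribution_model(
                records[records["target"] == t], designs[t], t, use_mixed=use_mixed
            )
            for _, r in fit.iterrows():
                rows.setdefault((t, r["factor"]), []).append(
                    (r["estimate"], r["se"])
                )
    out = []
    for (t, fac), pairs in rows.items():
        est = np.array([e for e, _ in pairs])
        ses = np.array([s for _, s in pairs])
        true = truth.coefficients[t][fac]
        cover = float(np.mean(np.abs(est - true) <= 2.0 * ses))
        out.append(
            {
                "target": t,
                "factor": fac,
                "truth": true,
                "mean_estimate": float(est.mean()),
                "bias": float(est.mean() - true),
                "empirical_sd": float(est.std(ddof=1)) if len(est) > 1 else 0.0,
                "mean_se": float(ses.mean()),
                "coverage_2se": cover,
                "frac_negative": float(np.mean(est < 0)),
                "n_sims": len(est),
            }
        )
    return pd.DataFrame(out)
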