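"""Seeded synthetic datasets for the immediate-early (IE) gene pipeline.

Real measurements behind this kind of study are transient-reporter
luminescence tables, knockout-virus qPCR tables, and standard-curve dilution
series; none are bundled here, so this module generates statistically
faithful stand-ins.  Each generator draws from the same additive log-scale
models the downstream estimators assume:

* reporter assay (log10 RLU):  basal promoter effect + promoter:driver
  interaction + set:replicate random intercept + residual;
* knockout qPCR (log2 copies per 1e6 cells):  design-row dot factor
  coefficients + biological-replicate intercept + residual, with technical
  replicates sharing the biological draw;
* standard dilutions:  Ct linear in log10 copies.

All generators are deterministic given their seed; independent substreams are
derived per factor level, so adding a level never perturbs the draws of the
others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import constants as C

__all__ = [
    "ReporterTruth",
    "QpcrTruth",
    "DecompositionTruth",
    "default_truth",
    "simulate_reporter_dataset",
    "simulate_knockout_panel",
    "simulate_standard_dilution",
    "mass_to_copies",
]


def _rng(seed: int, *labels: object) -> np.random.Generator:
    """Deterministic substream keyed by ``seed`` and a tuple of labels."""
    digest = hashlib.sha256(repr(labels).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng([int(seed)] + words)


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------


@dataclass
class ReporterTruth:
    """Ground truth for the transient-reporter generator (log10 scale)."""

    basal_promoter_effects: dict[str, float]
    interaction_effects: dict[tuple[str, str], float]
    set_replicate_sd: float = C.DEFAULT_REPORTER_SET_REPLICATE_SD
    residual_sd: float = C.DEFAULT_REPORTER_RESIDUAL_SD

    def __post_init__(self) -> None:
        allowed_p = set(C.PROMOTERS) | {C.EMPTY_VECTOR}
        allowed_d = set(C.DRIVERS) | {C.CONTROL_DRIVER}
        for p in self.basal_promoter_effects:
            if p not in allowed_p:
                raise ValueError(f"unknown promoter {p!r}")
        for (p, d), eff in self.interaction_effects.items():
            if p not in allowed_p or d not in allowed_d:
                raise ValueError(f"unknown promoter/driver pair {(p, d)!r}")
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect for {(p, d)!r}")
        if self.set_replicate_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def promoters(self) -> list[str]:
        return [p for p in self.basal_promoter_effects if p != C.EMPTY_VECTOR]

    def to_json(self) -> str:
        d = asdict(self)
        d["interaction_effects"] = {
            f"{p}|{drv}": v for (p, drv), v in self.interaction_effects.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class QpcrTruth:
    """Ground truth for qPCR generation given per-genotype mean expression.

    ``genotype_means`` maps target gene -> {genotype -> true mean log2 copies
    per 1e6 cells}.  The Ct calibration fields let the generator emit raw Ct
    values alongside copy numbers.
    """

    genotype_means: dict[str, dict[str, float]]
    replicate_sd: float = C.DEFAULT_QPCR_REPLICATE_SD
    residual_sd: float = C.DEFAULT_QPCR_RESIDUAL_SD
    ct_intercept: float = C.DEFAULT_CT_INTERCEPT
    ct_slope: float = C.DEFAULT_CT_SLOPE

    def __post_init__(self) -> None:
        if self.ct_slope >= 0:
            raise ValueError("ct_slope must be negative")
        if self.replicate_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class DecompositionTruth:
    """Factor-level ground truth for the combinatorial knockout model.

    ``coefficients`` maps target gene -> {factor -> log2 contribution}; the
    REST factor (host/basal contribution) is always present and the target's
    own factor never is.
    """

    coefficients: dict[str, dict[str, float]]
    replicate_sd: float = C.DEFAULT_QPCR_REPLICATE_SD
    residual_sd: float = C.DEFAULT_QPCR_RESIDUAL_SD
    ct_intercept: float = C.DEFAULT_CT_INTERCEPT
    ct_slope: float = C.DEFAULT_CT_SLOPE

    def __post_init__(self) -> None:
        for target, coefs in self.coefficients.items():
            if C.REST_FACTOR not in coefs:
                raise ValueError(f"REST factor missing for target {target!r}")
            own = C.GENE_TO_DRIVER.get(target)
            if own in coefs:
                raise ValueError(f"target {target!r} lists its own factor")
            for fac, val in coefs.items():
                if fac not in C.FACTORS:
                    raise ValueError(f"unknown factor {fac!r}")
                if not np.isfinite(val):
                    raise ValueError(f"non-finite coefficient for {fac!r}")
        if self.ct_slope >= 0:
            raise ValueError("ct_slope must be negative")
        if self.replicate_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def genotype_mean(self, target: str, genotype: str) -> float:
        """Linear-predictor mean: design row dotted with the coefficients."""
        from .decomposition import design_row

        row = design_row(C.GENOTYPES[genotype], target)
        coefs = self.coefficients[target]
        return float(sum(coefs[f] * row[f] for f in coefs))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def default_truth() -> tuple[ReporterTruth, QpcrTruth, DecompositionTruth]:
    """Canonical ground truth matching the reconstructed network and the
    published contribution estimates.

    The decomposition coefficients are the published per-target estimates;
    the reporter interaction signs match the 15-edge canonical network, with
    documented default magnitudes; the qPCR genotype means are the linear
    predictors implied by the decomposition coefficients.
    """
    reporter = ReporterTruth(
        basal_promoter_effects=dict(C.BASAL_PROMOTER_LOG10),
        interaction_effects=dict(C.REPORTER_INTERACTIONS),
    )
    decomposition = DecompositionTruth(
        coefficients={t: dict(v) for t, v in C.CONTRIBUTION_COEFFICIENTS.items()}
    )
    means: dict[str, dict[str, float]] = {}
    for target in C.DECOMPOSITION_TARGETS:
        means[target] = {
            g: decomposition.genotype_mean(target, g)
            for g, deleted in C.GENOTYPES.items()
            if target not in deleted
        }
    qpcr = QpcrTruth(genotype_means=means)
    return reporter, qpcr, decomposition


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def simulate_reporter_dataset(
    truth: ReporterTruth,
    n_sets: int = 2,
    n_replicates: int = 2,
    seed: int = 0,
    promoters: list[str] | None = None,
    drivers: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate one transient-reporter factorial: every promoter crossed with
    every driver condition (including the empty-vector control driver) in
    each set x biological replicate.

    Returns a table with columns ``promoter, driver, set, replicate, rlu``;
    ``rlu`` is on the raw (linear) luminescence scale,
    ``10 ** (basal + interaction + set:replicate + residual)``.
    """
    if n_sets < 1 or n_replicates < 1:
        raise ValueError("n_sets and n_replicates must be >= 1")
    if promoters is None:
        promoters = truth.promoters
    if drivers is None:
        drivers = [C.CONTROL_DRIVER] + list(C.DRIVERS)

    rows = []
    for s in range(1, n_sets + 1):
        for r in range(1, n_replicates + 1):
            sr_draw = float(
                _rng(seed, "set_rep", s, r).normal(0.0, truth.set_replicate_sd)
            )
            for p in promoters:
                basal = truth.basal_promoter_effects[p]
                for d in drivers:
                    inter = truth.interaction_effects.get((p, d), 0.0)
                    resid = float(
                        _rng(seed, "resid", p, d, s, r).normal(0.0, truth.residual_sd)
                    )
                    log10v = basal + inter + sr_draw + resid
                    rows.append((p, d, f"set{s}", f"rep{r}", 10.0 ** log10v))
    return pd.DataFrame(rows, columns=["promoter", "driver", "set", "replicate", "rlu"])


def _panel_targets(truth: DecompositionTruth | QpcrTruth) -> list[str]:
    if isinstance(truth, DecompositionTruth):
        return list(truth.coefficients)
    return list(truth.genotype_means)


def _panel_mean(truth: DecompositionTruth | QpcrTruth, target: str, genotype: str) -> float:
    if isinstance(truth, DecompositionTruth):
        return truth.genotype_mean(target, genotype)
    return truth.genotype_means[target][genotype]


def simulate_knockout_panel(
    truth: DecompositionTruth | QpcrTruth,
    genotypes: list[str] | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
    targets: list[str] | None = None,
    emit_ct: bool = True,
) -> pd.DataFrame:
    """Simulate the knockout-virus qPCR panel.

    One row per (target, genotype, biological replicate, technical
    replicate); a target is only measured in genotypes that retain it.
    Technical replicates share the biological intercept draw and differ by
    residual noise.  Columns: ``target, genotype, bio_rep, tech_rep, ct,
    copies`` (copies per 1e6 cells, linear scale).
    """
    if n_bio < 1 or n_tech < 1:
        raise ValueError("n_bio and n_tech must be >= 1")
    if genotypes is None:
        genotypes = list(C.GENOTYPES)
    if targets is None:
        targets = _panel_targets(truth)
    for g in genotypes:
        if g not in C.GENOTYPES:
            raise ValueError(f"unknown genotype {g!r}")

    rows = []
    for target in targets:
        for g in genotypes:
            if target in C.GENOTYPES[g]:
                continue  # transcript absent from the genome: never measured
            mean = _panel_mean(truth, target, g)
            for b in range(1, n_bio + 1):
                bio_draw = float(
                    _rng(seed, "bio", target, g, b).normal(0.0, truth.replicate_sd)
                )
                for t in range(1, n_tech + 1):
                    resid = float(
                        _rng(seed, "tech", target, g, b, t).normal(
                            0.0, truth.residual_sd
                        )
                    )
                    log2c = mean + bio_draw + resid
                    copies = 2.0 ** log2c
                    ct = (
                        truth.ct_intercept + truth.ct_slope * np.log10(copies)
                        if emit_ct
                        else np.nan
                    )
                    rows.append((target, g, f"bio{b}", f"tech{t}", ct, copies))
    return pd.DataFrame(
        rows, columns=["target", "genotype", "bio_rep", "tech_rep", "ct", "copies"]
    )


def measure_target(truth, target: str, genotype: str) -> float:
    """True mean log2 copies for a (target, genotype); raises if deleted."""
    if target in C.GENOTYPES[genotype]:
        raise ValueError(f"target {target!r} is deleted in genotype {genotype!r}")
    return _panel_mean(truth, target, genotype)


def mass_to_copies(mass_g: float, template_length_bp: float, da_per_bp: float = C.DA_PER_BP) -> float:
    """Convert a double-stranded template mass (grams) to molecule count."""
    if mass_g <= 0 or template_length_bp <= 0:
        raise ValueError("mass and template length must be positive")
    return mass_g / (template_length_bp * da_per_bp) * C.AVOGADRO


def simulate_standard_dilution(
    ct_intercept: float = C.DEFAULT_CT_INTERCEPT,
    ct_slope: float = C.DEFAULT_CT_SLOPE,
    amounts: list[float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    template_length_bp: float | None = None,
) -> pd.DataFrame:
    """Simulate a standard-curve dilution series.

    ``amounts`` are template copies, or masses in grams when
    ``template_length_bp`` is given (the conversion assumes 650 Da per base
    pair).  Defaults to eight ten-fold dilutions from 1e8 copies down to 10.
    Returns columns ``copies, ct`` with Ct = intercept + slope*log10(copies)
    plus optional Gaussian noise.
    """
    if ct_slope >= 0:
        raise ValueError("ct_slope must be negative")
    if amounts is None:
        amounts = [10.0 ** k for k in range(8, 0, -1)]
    if len(set(amounts)) < 2:
        raise ValueError("need at least 2 distinct amounts")
    if any(a <= 0 for a in amounts):
        raise ValueError("amounts must be positive")
    copies = [
        mass_to_copies(a, template_length_bp) if template_length_bp else float(a)
        for a in amounts
    ]
    cts = []
    for i, c in enumerate(copies):
        noise = float(_rng(seed, "std", i).normal(0.0, noise_sd)) if noise_sd else 0.0
        cts.append(ct_intercept + ct_slope * np.log10(c) + noise)
    return pd.DataFrame({"copies": copies, "ct": cts})
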