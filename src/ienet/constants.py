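"""Shared constants: gene panels, genotype definitions, and documented defaults.

All unpublished magnitudes used by the synthetic-data generator live here so
they are versioned in one place.  Signs of the reporter interaction effects
follow the reconstructed 15-edge regulatory network; their magnitudes (and the
noise standard deviations) are conventions, not measurements.
"""

from __future__ import annotations

#: The five canonical regulatory immediate-early genes of AcMNPV, in canonical
#: order.  Node ids (and promoter ids) are lower case; driver/regulator labels
#: are upper case.
GENES: tuple[str, ...] = ("ie0", "ie1", "ie2", "me53", "pe38")

#: Driver (effector-plasmid) labels, upper case by convention, plus the
#: empty-vector control condition.
DRIVERS: tuple[str, ...] = ("IE0", "IE1", "IE2", "ME53", "PE38")
CONTROL_DRIVER = "control"

#: Reporter-plasmid promoter labels.  ``empty_vector`` is the promoterless
#: luciferase construct; it is a legal level but not part of the default
#: factorial (the background subtraction step plays its role).
PROMOTERS: tuple[str, ...] = GENES
EMPTY_VECTOR = "empty_vector"

#: Map driver label -> gene node id.
DRIVER_TO_GENE: dict[str, str] = {d: d.lower() for d in DRIVERS}
GENE_TO_DRIVER: dict[str, str] = {g: g.upper() for g in GENES}

# ---------------------------------------------------------------------------
# Knockout genotypes
# ---------------------------------------------------------------------------

CONTROL_GENOTYPE = "control"

#: Viral genotypes: name -> frozenset of deleted genes.  The seven genotypes
#: are the polh-rescued control, the five single knockouts, and the ie0/ie1
#: double knockout.
GENOTYPES: dict[str, frozenset[str]] = {
    CONTROL_GENOTYPE: frozenset(),
    "delta_ie0": frozenset({"ie0"}),
    "delta_ie1": frozenset({"ie1"}),
    "delta_ie0_ie1": frozenset({"ie0", "ie1"}),
    "delta_ie2": frozenset({"ie2"}),
    "delta_me53": frozenset({"me53"}),
    "delta_pe38": frozenset({"pe38"}),
}

#: Decomposition factor labels, in display order.
FACTORS: tuple[str, ...] = ("IE0", "IE1", "IE0:IE1", "IE2", "ME53", "PE38", "REST")
INTERACTION_FACTOR = "IE0:IE1"
REST_FACTOR = "REST"

#: Per-target minimal full-rank genotype panels for the decomposition model:
#: control, the ie0/ie1 single and double knockouts, and the single knockouts
#: of the remaining non-target genes.
def decomposition_panel(target: str) -> tuple[str, ...]:
    base = ["control", "delta_ie0", "delta_ie1", "delta_ie0_ie1"]
    for g in ("ie2", "me53", "pe38"):
        if g != target:
            base.append(f"delta_{g}")
    return tuple(base)


#: Targets for which single-gene + IE0:IE1 contributions are decomposed.
DECOMPOSITION_TARGETS: tuple[str, ...] = ("ie2", "me53", "pe38")

# ---------------------------------------------------------------------------
# Ground-truth contribution coefficients (log2 copies per 1e6 cells)
# ---------------------------------------------------------------------------

#: Per-target factor contributions used as simulation ground truth.  The
#: target's own factor never appears in its row; REST absorbs host/basal
#: contributions.
CONTRIBUTION_COEFFICIENTS: dict[str, dict[str, float]] = {
    "ie2": {
        "IE0": 2.688,
        "IE1": 4.250,
        "IE0:IE1": -3.652,
        "ME53": -0.350,
        "PE38": -0.085,
        "REST": 2.360,
    },
    "me53": {
        "IE0": 2.971,
        "IE1": 3.208,
        "IE0:IE1": -3.149,
        "IE2": -0.369,
        "PE38": -0.072,
        "REST": 2.495,
    },
    "pe38": {
        "IE0": 1.687,
        "IE1": 2.730,
        "IE0:IE1": -2.324,
        "IE2": -0.574,
        "ME53": -0.346,
        "REST": 2.703,
    },
}

# ---------------------------------------------------------------------------
# Canonical signed regulatory relationships (driver gene -> target promoter)
# ---------------------------------------------------------------------------

#: The 15 significant regulator -> promoter relationships out of the 25 tested:
#: 12 positive (one of them the ie2 auto-activation) and 3 negative (two of
#: them negative autoregulation of ie0 and pe38).  Keys are (regulator gene,
#: target gene) node ids.
CANONICAL_EDGE_SIGNS: dict[tuple[str, str], int] = {
    # activations of the ie0 promoter
    ("ie1", "ie0"): +1,
    ("ie2", "ie0"): +1,
    ("me53", "ie0"): +1,
    ("pe38", "ie0"): +1,
    # ie1 promoter: weak activation by PE38 only
    ("pe38", "ie1"): +1,
    # ie2 promoter
    ("ie1", "ie2"): +1,
    ("ie2", "ie2"): +1,   # auto-activation
    ("me53", "ie2"): -1,
    # me53 promoter
    ("ie0", "me53"): +1,
    ("ie2", "me53"): +1,
    # pe38 promoter
    ("ie0", "pe38"): +1,
    ("ie1", "pe38"): +1,
    ("ie2", "pe38"): +1,
    # negative autoregulation
    ("ie0", "ie0"): -1,
    ("pe38", "pe38"): -1,
}

#: Default promoter:driver interaction effects (log10 units) consistent in
#: sign with the canonical network.  Magnitudes are conventions: strong
#: transactivation ~1 log10, the weak PE38 -> ie1 activation 0.3, repression
#: ~0.5.  Pairs not listed have a zero effect (the 10 non-significant
#: relationships).
REPORTER_INTERACTIONS: dict[tuple[str, str], float] = {
    ("ie0", "IE0"): -0.6,
    ("ie0", "IE1"): 1.2,
    ("ie0", "IE2"): 1.0,
    ("ie0", "ME53"): 0.8,
    ("ie0", "PE38"): 0.9,
    ("ie1", "PE38"): 0.3,
    ("ie2", "IE1"): 1.1,
    ("ie2", "IE2"): 0.9,
    ("ie2", "ME53"): -0.5,
    ("me53", "IE0"): 0.9,
    ("me53", "IE2"): 0.7,
    ("pe38", "IE0"): 0.8,
    ("pe38", "IE1"): 1.0,
    ("pe38", "IE2"): 0.9,
    ("pe38", "PE38"): -0.5,
}

#: Basal promoter activities, log10 relative light units after background
#: subtraction (conventions).
BASAL_PROMOTER_LOG10: dict[str, float] = {
    "ie0": 3.0,
    "ie1": 3.5,
    "ie2": 3.2,
    "me53": 2.8,
    "pe38": 3.1,
    EMPTY_VECTOR: 1.5,
}

# Noise defaults.  Reporter scale is log10 RLU; qPCR scale is log2 copies.
DEFAULT_REPORTER_RESIDUAL_SD = 0.05
DEFAULT_REPORTER_SET_REPLICATE_SD = 0.05
DEFAULT_QPCR_RESIDUAL_SD = 0.3
DEFAULT_QPCR_REPLICATE_SD = 0.1

#: Standard-curve defaults: Ct at a single template copy, and the slope of a
#: perfectly efficient (doubling per cycle) reaction, -1/log10(2).
DEFAULT_CT_INTERCEPT = 38.0
DEFAULT_CT_SLOPE = -3.321928094887362

#: Average molar mass of a double-stranded DNA base pair, g/mol.
DA_PER_BP = 650.0
AVOGADRO = 6.02214076e23

#: FDR threshold used throughout.
DEFAULT_ALPHA = 0.1
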