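# Methods

## Models

### Transient-reporter model

Luminescence from co-transfections of a promoter-reporter plasmid with an
IE-gene driver plasmid (or the empty control plasmid) is background-
subtracted, floored at 1 RLU so the log10 transform is always defined, and
fitted to

    log10(RLU) ~ 0 + promoter + promoter:driver + (1 | set:replicate)

Coding: the control (empty-vector) driver is the reference level, so each
promoter main effect is that promoter's basal activity under the control
condition and each promoter:driver interaction is the log10 fold-change the
driver induces relative to it. The default factorial crosses the five IE
promoters with six driver conditions (five IE genes + control): 30 cells
per set × replicate, 60 measurements per set with two replicates, 25
interaction contrasts. The empty-vector reporter is supported as an extra
promoter level but is not part of the default factorial — its role
(measuring promoterless background) is played by the explicit background-
subtraction step.

Estimation is restricted maximum likelihood for the random set:replicate
intercept (statsmodels `MixedLM`). With only four groups the variance
component is frequently estimated at zero or the fit fails to converge; the
model then falls back to ordinary least squares with set:replicate as a
fixed blocking factor. Which route was taken is recorded in the `method`
column of every output and in the run report's provenance block. p-values
are two-sided Wald tests on the interaction coefficients; the
Benjamini–Hochberg step-up adjustment is applied jointly across all tested
interactions, and calls are made at FDR α = 0.1 (configurable). The
contrast coding and test type are conventions of this package; they are
flagged as such here because alternatives (e.g. likelihood-ratio tests)
would be equally defensible.

### Signed network and its statistics

Each significant call becomes a directed edge regulator → target promoter,
signed by the effect direction and weighted by |effect|. Connectivity
statistics deliberately ignore signs and self-loops: a repressive link is
still a regulatory route, and an autoregulatory loop is not a path between
two genes. Only under this convention does the canonical 15-edge network
simultaneously reproduce all of its printed summary statistics (mean
shortest path 1.45 over 20 ordered pairs, maximum 3 on me53 → ie1, 6 of 60
deletion comparisons changed, mean non-auto activating in-degree 2.2,
11 non-auto activations), which the acceptance suite checks as a block.

* Distances are breadth-first search on the unweighted digraph; the mean is
  taken over reachable ordered pairs of distinct nodes and unreachable
  pairs are counted separately (the canonical network has none).
* Normalized betweenness divides the directed pair-dependency sum by
  (n−1)(n−2); unreachable pairs contribute zero. Both routines are
  networkx-backed and are cross-checked in the test suite against an
  independent Floyd–Warshall oracle and an exhaustive path-enumeration
  oracle on random digraphs.
* Feed-forward loops are ordered triples (X, Y, Z) of distinct genes with
  edges X→Y, Y→Z, X→Z; the default mode keeps only all-positive loops
  (possible activation paths), and auto-edges never participate.
* The perturbation scan removes one node at a time and marks an ordered
  pair "changed" if its distance differs from baseline **or becomes
  unreachable** — loss of reachability is a change, and only this reading
  yields 6/60 on the canonical network.

One reading adopted for the canonical edge list: the ie2 auto-activation is
a cis effect, so "eleven transactivations" counts non-auto positive edges
only. The IE0 → pe38 edge is positive; that sign is the only one consistent
with the three printed graph statistics above.

### qPCR quantitation

Standard curves are ordinary least squares of Ct on log10(copies), requiring
at least three dilution points spanning two orders of magnitude; the
amplification efficiency 10^(−1/slope) − 1 is reported. Unknowns are
inverted through the curve, scaled to copies per 10⁶ cells, technical
triplicates averaged on the linear copy scale (a Ct-scale mean is available
by flag — the two differ by Jensen's inequality), then log2-transformed.
Cts outside the standards' range are flagged as extrapolation and warned
about rather than rejected, since real curves span 8+ orders of magnitude.
Genotype effects per target are contrasts against the control virus with a
biological-replicate random intercept (same singular-fit fallback as
above), BH-adjusted within target; negated effects are reported as implied
wild-type regulatory activities.

### Contribution decomposition

The combinatorial model regresses log2 copies on 0/1 presence indicators
(IE0, IE1, IE2, ME53, PE38 as applicable), the IE0·IE1 product indicator,
and an all-ones REST column, with **no global intercept** — REST is the
intercept-like term and absorbs host and basal contributions. The target's
own gene is excluded from its design (its transcript cannot be measured in
genotypes deleting it). Default per-target panels are the six measurable
genotypes {control, Δie0, Δie1, Δie0/ie1, and the two remaining single
knockouts}, the minimal full-rank panel; `check_identifiability` reports
the column rank and names a collinear set when deficient (e.g. ME53, PE38
and REST are indistinguishable if only the ie0/ie1 genotype subset is
supplied). With zero replicate variance the IE0:IE1 estimate equals the
classical epistasis contrast (control − Δie0 − Δie1 + Δie0/ie1 of genotype
means); the test suite verifies this closed form.

Caveat inherited by every fit: with single and double knockouts only, the
"IE0:IE1" coefficient includes any higher-order interaction involving both
genes (IE0:IE1:IE2, ...), and single-gene coefficients likewise absorb
their interactions with untested genes. Separating those would need the
full 32-genotype panel, which is out of scope.

## Synthetic data: what it emulates and what it does not

The generator draws from exactly the additive log-scale models above:

* reporter: log10 value = basal + interaction + set:replicate draw +
  residual, full factorial per set × replicate;
* knockout panel: log2 copies = design row · coefficients + biological
  intercept + residual, technical replicates sharing the biological draw;
  a target is never emitted for a genotype that deletes it;
* standards: Ct = intercept + slope·log10(copies) + optional noise, with a
  mass→copies conversion at 650 Da per base pair for mass-denominated
  dilutions.

Defaults are the study conditions: 5 promoters × 6 driver conditions × 2
sets × 2 replicates (120 reporter rows); 7 genotypes × 3 biological × 3
technical replicates; ground-truth contribution coefficients equal to the
published per-target estimates; reporter interaction signs matching the
canonical network. Magnitudes that were never printed (basal activities,
reporter effect sizes, noise SDs) are conventions versioned in
`constants.py`: strong activation ≈ 1 log10, the weak PE38→ie1 link 0.3,
repression ≈ 0.5, reporter residual and set:replicate SDs 0.05 log10, qPCR
residual 0.3 and replicate 0.1 log2 — the qPCR values chosen so the
implied coefficient SEs land near the published 0.14–0.28 range.

Because the generator satisfies the estimators' assumptions by
construction, passing tests demonstrate correctness of the implementation
and calibration under the assumed model — not robustness to the ways real
assays violate it (heteroscedastic luminescence, PCR inhibition,
plate-position effects, non-Gaussian outliers, promoter-sequence overlap
between neighbouring genes). Determinism: every generator takes an explicit
seed and derives an independent substream per factor level (SHA-256 keyed),
so outputs are byte-stable and adding a level never perturbs other draws.

## Numerical choices and degenerate inputs

* Zero-noise data give zero residual variance and hence zero standard
  errors; Wald p-values are then defined as 0 for non-zero estimates and 1
  for zero estimates (tolerance 1e-10), so noiseless pipelines still
  classify correctly.
* The mixed-model fallback triggers on exceptions, non-finite SEs, or a
  random-intercept variance below 1e-8.
* BH adjustment is the step-up rule q_(i) = min_{j≥i} m·p_(j)/j clipped at
  1; ties are handled by stable sorting and the suite checks equality with
  a direct threshold-scan oracle and statsmodels.
* Background subtraction floors at 1 RLU (configurable) to keep log10
  finite.
* Mean shortest path would be reported over reachable pairs with an
  explicit unreachable count if a network were disconnected.

## Problem sizes used by the validation suites

The stochastic acceptance checks use 200 simulations each: the
decomposition recovery experiment (bias ≤ 0.1 log2 per factor, pooled
2·SE interval coverage within Monte-Carlo error of nominal, IE0:IE1 sign
recovery ≥ 99%) and the reporter null calibration (pooled q < 0.1 rate
within the binomial bound of α). Interval coverage is compared at the
2·SE point of the normal approximation; with ~10 residual degrees of
freedom per fit the attained coverage sits a little below 95%, which the
Monte-Carlo band accommodates. Graph oracles run on 100 random 5–8-node
digraphs (betweenness enumeration capped at 6 nodes, where exhaustive
path enumeration is still cheap). BH is checked on 1,000 random p-vectors
of length ≤ 30.

## Known limitations

* The reporter and qPCR stages treat measurements as conditionally
  independent given their random intercepts; plate and batch structure
  beyond set:replicate is not modelled.
* The network is binary-signed: edge weights are carried but none of the
  connectivity statistics use them.
* No dynamical simulation on the network — the perturbation scan is purely
  topological.
* The decomposition model is linear on the log2 scale; saturation or
  threshold behaviour of real promoters is outside its vocabulary.
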