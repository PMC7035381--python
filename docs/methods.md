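# Methods

## The model and its assumptions

The package treats each gene in each tissue as a black box producing a
count per cell and summarizes it by two moment ratios: an activation
probability p = μ²/σ² and a peak activity α = σ²/μ, with logarithmic
companions I = −ln p (intermittency) and A = ln α (activity). The
motivation is a two-point on/off picture — a cell either expresses the
gene at level α (probability p) or not at all — under which μ = αp and
σ² = p(1−p)α², so the ratios equal p/(1−p) and α(1−p); for p ≪ 1 they are
p and α. No distributional assumption beyond the first two moments is
made, which is the point: mechanistic fits of switching-rate models are
ill-conditioned in parts of parameter space and sensitive to protocol,
while moment ratios are cheap, transparent, and comparable across genes
within one dataset. The estimators are *comparative*, not absolute: they
inherit all technical noise of the protocol.

Moments use the population (1/N) convention; an `ddof=1` flag gives the
sample convention. The estimator identity p·α = μ holds exactly whenever
no clipping occurs.

Degenerate cases are flagged, not hidden: μ = 0 (gene absent in a tissue)
is excluded from that tissue's tables rather than mapped to I = ∞;
σ² = 0 (constant expression, the ideal spike-in) gives p = 1, I = 0,
α = μ; sub-Poissonian ratios μ²/σ² > 1 are clipped to p = 1 so I ≥ 0
always. A gene is *intermittent* when I > ln 5 strictly, i.e. active
with probability below 0.2 — the level below which high-concentration
spike-ins are rarely found, making it a natural technical-noise floor.

## Discrimination of the two hypotheses

For a gene pair, K = ⟨M M′⟩/(μμ′) − 1. Genes expressed in disjoint sets
of cells have ⟨M M′⟩ = 0, hence K = −1 exactly — an algebraic identity,
not an asymptotic statement, which is why the acceptance tolerance on it
is 1e−6 rather than statistical. Conversely, genes sharing an activation
program correlate positively. The survey computes all pairs among
non-degenerate endogenous genes of a tissue (optionally a seeded
subsample capped at `max_pairs`, which preserves the sign-split
distributions), and reports the fraction of K within ε of −1 (default
ε = 0.05, configurable — no canonical value exists) and the sign split
among pairs with |C| above a threshold (default 0.1, also a free
parameter: correlation coefficients of order 1/√N carry no signal). The
pipeline verdict is judged on the significant pairs only: at desk-scale
cell numbers, two *independent* rare genes are frequently disjoint by
chance and give K = −1 with negligible |C|, so an all-pairs vote would
misread case B.

## Cross-tissue persistence

Per gene, Ā and Ī are simple (unweighted) means over the tissues where
the gene is present and non-degenerate — unweighted so that large
tissues do not dominate the cross-tissue comparison. Deviations
ΔA = A − Ā and ΔI = I − Ī are pooled over all (gene, tissue) points, and
their population variances plus a 20×20 2-D histogram summarize how much
each parameter moves between tissues. The headline qualitative claim the
synthetic data reproduce is Var(ΔA) ≪ Var(ΔI) when tissues share α and
modulate p.

## Spike-in normalization assessment

Normalized counts M′ = M/Σ M (per cell; spike-in reads excluded from the
denominator by default, since the endogenous fraction is the quantity of
interest — a flag includes them). For each spike-in, Var(ln M) over
cells with M > 0 is compared with Var(ln M′); logs are taken only over
positive counts because ln 0 is undefined and absent reads carry no
fractional-error information. If cell-total variation is biological,
normalization *injects* it into the constant-concentration spike-ins and
the ratio Var(ln M′)/Var(ln M) exceeds 1; the optional lower-quartile
exclusion (by raw cell total, computed before normalization) tests
whether low-total cells alone drive the effect. The tissue-mean activity
equalization shifts each tissue's A additively so all tissue means equal
the unweighted grand mean of tissue means — additive in log space, hence
exactly variance-preserving within tissues.

## Telegraph model

Stationary moments follow the Peccoud–Ycart closed form; sampling uses
the exact Poisson–Beta representation (Poisson rate M₀·B with
B ~ Beta(k_on/k_deg, k_off/k_deg)) rather than Gillespie burn-in: it is
the exact stationary law, O(n), and free of burn-in bias. Limits are
handled explicitly: k_tr = 0 gives all zeros, k_off = 0 gives
Poisson(M₀). The asymptotic map (valid for M₀ ≫ 1, which drops the
Poisson shot-noise term from σ²) is

p ~ p₀/(1−p₀) · (k_deg+k_on+k_off)/k_deg,  α ~ M₀(1−p₀) · k_deg/(k_deg+k_on+k_off),

whose product telescopes to p₀M₀ = ⟨M⟩ exactly. `verify_identification`
compares simulated estimates against both this asymptotic form and
(p₀, M₀); it reports the *unclipped* ratio μ²/σ² so the product identity
p̂·α̂ = μ̂ holds even for fast-switching parameters where the ratio
exceeds 1. The documented recovery regime is p₀ ≤ 0.05 with
k_deg ≥ 20(k_on+k_off), where both relative errors stay below 10%.

## Tail fitting

The tail of Ā is fitted by maximum likelihood on the excesses over a
lower cutoff: rate m̂ = 1/mean(Ā − cutoff), stderr m̂/√n — the
exponential MLE, identical to the Hill estimator on α = e^A. The implied
power-law exponent of α is m̂ + 1 exactly (change of variables). MLE is
the default because histogram-slope fits depend on binning; a log-binned
regression mode exists for figure-style replication. The cutoff is
manual by default (reproducibility); at n = 10⁵ tail points the bias is
well under 2%.

## Synthetic data: what it emulates and what it does not

The generator produces (a) intermittent genes with per-tissue p,
tissue-shared α, optional shared activation programs, and a lognormal
per-cell size factor reproducing the ~two-decade spread of real cell
totals; (b) disjoint rare cell types with exclusive, continuously
expressed genes; (c) telegraph stationary counts; (d) ERCC-style
spike-in panels with log-uniform concentrations, a capture efficiency,
and multiplicative lognormal technical noise (deterministic rounding, so
a noise-free panel is exactly constant across cells).

Within the active state two count modes exist: `"fixed"` (exactly
round(α) — the two-point schematic under which the estimator algebra is
exact, used for oracle tests) and `"poisson"` (mean α, the realistic
default). Real data differ in ways deliberately not modelled: no PCR
amplification cascade, no read-level simulation, no doublets or ambient
RNA, no gene-length or GC effects, and activation programs are binary
rather than graded. Passing tests therefore validate the estimators and
the discrimination logic under the stated generative assumptions; they
do not certify the biological conclusions on any real dataset.

## Quality filters

Plate/FACS: entries below 10 are zeroed first, then genes whose
remaining total is not *strictly* above 500 are dropped ("more than 500"
read strictly); spike-ins are never dropped. The gene total is evaluated
per tissue by default — every downstream statistic is per-tissue — with
a `scope="global"` alternative. Droplet: cells need at least 1000
endogenous reads *and* at least 500 endogenous genes detected
(inclusive); spike-ins are excluded from both counts. Both filters are
idempotent.

## Problem sizes and numerical choices

Default verification sizes were chosen so each check is decisively
powered while remaining quick: estimator recovery and telegraph moments
at 10⁵ cells (mean/variance checks at 3 standard errors, with the
variance SE estimated by plug-in fourth moments), identification at 10⁶
cells (relative errors ≲ a few %), discrimination at 2000–3000 cells,
tail fits at 10⁵ points. All randomness flows through
`numpy.random.default_rng` seeds recorded in outputs; reruns with the
same seed are byte-identical. Monte-Carlo tolerances for the estimator
oracle use exact delta-method standard errors of the moment ratios under
the two-point law rather than ad-hoc bands.

## Known limitations

- p and α estimates are undefined or clipped for genes observed in a
  single cell; droplet data dominated by single-count genes will pile up
  at the degenerate boundary (no exclusion rule beyond the protocol
  filters is applied).
- The K = −1 signature is exact only for *strictly* exclusive genes;
  partial lineage overlap yields intermediate negative K, and the ε
  tolerance is a free parameter.
- The spike-in variance comparison assumes enough positive counts per
  sequence; very low-concentration spike-ins contribute NaN variances
  and are averaged out.
- The tail fit assumes a genuinely exponential tail above the chosen
  cutoff; no automatic model comparison against lognormal alternatives
  is performed.
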