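# Methods

## The generative model of a cell

A recording is discretised on a 120 ms grid (the flash period: 40 ms flash
+ 80 ms gap). Each bin carries a binary stimulus symbol `x_t` (1 = flash)
and a spike count `n_t`. A cell is modelled as a Poisson encoder of
surprise:

- surprise `s_t = −log p(x_t | x_{<t}, θ)` under the cell's internal model;
- rate `λ_t = softplus(a·s_t + b)` with the softplus `log(1+e^x)` fixed;
- counts `n_t ~ Poisson(λ_t)`, independent across bins and repeats.

Predictive probabilities are clamped to `[1e−12, 1−1e−12]` before the log
so surprise stays finite at degenerate transition probabilities; rates are
floored at `1e−10` inside likelihoods. The first bin (first two for the
order-2 Markov model) has no full context; its rate is computed from a
zero-padded context / prior-mean predictive and excluded from all
likelihoods and history-conditioned analyses.

## Internal models

**Fixed Markov (order 1, 2).** Transition probabilities are free
parameters: θ₀, θ₁ for order 1; θ_{ij} over the four two-bin contexts for
order 2. By construction the order-k model's rates depend only on the last
k+1 bins.

**Adaptive leaky beta-Bernoulli.** The cell treats each context's
transition probability as unknown, with a conjugate beta prior
Beta(α₀ⁱ, β₀ⁱ), and integrates evidence leakily: after observing the
transition ending at bin t, both contexts' pseudo-counts decay toward the
prior, `v ← (1−η)·v + η·v₀`, and the active context (i = x_{t−1}) gains the
unit count of the observed outcome. This is equivalent to discounted
transition counts `ñ_{i→j} = Σ_k (1−η)^k [x_{t−k}=j][x_{t−1−k}=i]` (a test
asserts the recursion/sum identity to 1e−10), and the posterior-predictive
is the pseudo-count ratio `(ñ_{i→1}+α₀ⁱ)/(ñ_{i→1}+ñ_{i→0}+α₀ⁱ+β₀ⁱ)` — the
conjugate beta posterior mean, verified against quadrature.

Design choices on points the update rules leave open:

- *Inactive-context decay.* Both contexts decay every step (pure
  exponential forgetting, so the discounted-sum form depends only on
  elapsed time). Decaying only the active context would make forgetting
  depend on context occupancy.
- *First observation.* No transition exists before the second bin; the
  first observation only sets the context and triggers no count update.
- *Leak.* η = 0.2 by default, shared across cells, overridable. At η = 0
  the updates reduce to plain conjugate counting; at strong priors
  (α₀+β₀ → ∞) the predictive converges uniformly to the fixed Markov model
  with θᵢ = α₀ⁱ/(α₀ⁱ+β₀ⁱ) (asserted at scale 10⁶, tolerance 1e−3).

**Dynamic belief reference.** Exact Bayesian filtering for a world whose
transition probabilities redraw from the prior with probability
`change_prob` each step, on a per-context grid of θ values (cell-midpoint
support, beta-CDF cell masses). Defaults `change_prob = 0.01`,
`grid_size = 200` are this package's own choices. With `change_prob = 0`
the filter reduces to conjugate updating (within grid error); with
`change_prob = 1` the predictive pins to the prior mean. On stochastic
flash sequences its predictive correlates > 0.9 with the leaky model's,
which is why the cheaper leaky model is the default.

## Stimulus generator

Flash-run lengths are `1 + NB(r, p)` (number-of-failures form), with `r`
set by the mean-matching rule `r = (mean−1)·p/(1−p)` so the mean run is 7
flashes for every clustering condition p ∈ {0.98, 0.8, 0.01}; silence runs
are geometric on {1, 2, ...} with mean 9. The +1 shift guarantees no
zero-length runs; the convention is recorded here because the
parameterization is otherwise ambiguous. The three conditions are
generated as consecutive blocks and concatenated, and responses are pooled
across them. Binary histories are enumerated in binary-counting order with
the oldest bin as the most significant digit; bins are half-open
`[t·120, (t+1)·120)` ms. The nominal flash repetition period is the 120 ms
bin throughout.

## Fitting

Maximum likelihood under the Poisson model, `L = Σ_t n_t log f_t − f_t`
(constant omitted), computed on raw per-bin counts summed across repeats.
Parameters are optimized in unconstrained space (logit for θ, log for
pseudo-counts) with L-BFGS-B from 50 random starts: θ ~ U(0.05, 0.95),
log α₀, log β₀ ~ U(log 0.1, log 10⁴), a ~ U(0, 5), b ~ U(−5, 2). The start
stream is sequential in the seed, so the best likelihood is monotone in
the number of starts. η is held fixed (shared across cells) during
fitting. The reduced adaptive variant fixes α₀ⁱ = β₀ⁱ (prior mean ½),
leaving one strength parameter per context.

The leaky transition counts depend only on the stimulus and η — not on the
fitted prior — so they are precomputed once per fit (IIR filter) and each
likelihood evaluation is pure vectorized arithmetic; a test pins this fast
path to the sequential public predictor.

Model comparison uses, per cell, the Pearson correlation between the
history-conditioned mean counts and mean model rates on the depth-8
(2⁸ = 256 histories) tree level, then a two-sided Wilcoxon signed-rank
test on the paired per-cell correlations (zero differences discarded;
fewer than 6 cells flags the p-value unreliable). Whether such
correlations are better computed on 5 ms PSTH bins or on the 120 ms
history-conditioned means is a genuinely open choice; the 120 ms version
is primary here because it is the scale on which the models are defined,
and the PSTH machinery is available separately.

## Tree-plots and diagnostics

A tree-plot maps each terminal history (the most recent d ≤ n bins,
oldest first) to the mean response over all bins showing that history. All
depths are computed over the common bin range t ≥ n so that the
conservation invariants — parent mean is the count-weighted mean of its
children, parent n is the children's sum — hold exactly. Unobserved
histories are reported missing, never imputed; correlations use
pairwise-complete nodes, and tree levels with fewer than 3 common nodes
yield no correlation. Trees for histories ending in silence and in flash
are both available (`TreePlot.ending_in`).

The OSR curve is the top branch: the node (k flashes, then one silence) as
a function of k. Branching distance at depth d is the mean over sibling
pairs (same recent d−1 bins, different d-th-past bin) of the absolute
difference of their means; the signed variant is available, absolute +
mean is the default for noise robustness.

OSR detection on a 5 ms PSTH: positive when the maximum in a 60–180 ms
window after the omitted flash exceeds 2× the baseline (mean over the
preceding 120 ms inter-flash interval). The window and factor are this
package's operationalisation of "a peak around 120 ms" and are config
keys. Refractory QC keeps cells with < 1% of inter-spike intervals below
2 ms.

## Synthetic populations and what they do (not) show

`PopulationSpec` defaults define the simulated study: ~10⁴ stimulus bins
(20 minutes, three equal condition blocks), 70 repeats per cell, adaptive
cells with prior-mean ratio lognormal around 1 (log-sd 0.1) and prior
strength bimodal across cells — log-strength modes 4 (weak) and 8
(strong), log-sd 0.3, equal mix — with η = 0.2, gain ~ U(1, 3), bias ~
U(−2, 0) giving rates of roughly 0.5–2.5 spikes per 120 ms bin. The
strong/weak threshold log(α₁+β₁) = 7 matches the bimodal split.

The generator emulates the statistical structure the analyses assume:
Poisson counts (Fano ≈ 1), no cross-cell or cross-repeat correlations, no
refractoriness, no latency or burst structure within bins, and a stimulus
drawn exactly from the declared run-length model. Passing recovery tests
therefore demonstrates the estimators and analyses are correct and
well-calibrated *under the model*; they cannot certify behaviour on real
recordings with adaptation, non-Poisson variability or drifting
responsivity. The millisecond spike-time fixture (Gaussian profile peaked
120 ms after an omitted flash) exists only so the PSTH/OSR-detection path
has realistic input; it is a labelled synthetic convenience, not part of
the generative model.

## Known limitations

- **Prior strength is weakly identified.** The likelihood profile over
  log(α₀¹+β₀¹) is shallow: prior strength trades off against encoder gain
  (weaker prior → larger surprise excursions → smaller gain compensates),
  and the softplus only partly breaks the degeneracy. At the default study
  size (10⁴ bins × 70 repeats) the median absolute error of the recovered
  log-strength is ≈ 0.8 (≈ 0.5 at 2×10⁴ bins); fits sit at their
  asymptotic likelihood optimum (best-fit log-likelihood exceeds the
  truth's by ≈ χ²/2 per parameter), so this is a property of the
  experiment's information content, not of the optimizer. Strong/weak
  classification and model-comparison direction are robust to it.
- Strong-prior cells (strength ≫ leaky-count scale 1/η) are nearly
  memoryless, so their exact strength is unidentifiable beyond "large";
  estimates for them localise only to within ~1 log-unit.
- The dynamic-belief grid filter is quadratic in grid size and linear in
  time; it is a reference implementation, not tuned for speed.
- η is global and not fitted; cells whose true integration time-scale
  differs will absorb the mismatch into their fitted prior.
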