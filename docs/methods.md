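# Methods

## The model

`pauseflux` implements a deterministic two-compartment model of RNA
polymerase II distribution at a gene. Pol II density (polymerases per bp)
in the promoter-proximal pause region, `p`, and in the gene body, `b`,
evolve as

```
dp/dt = k_init − (k_pre + k_rel) p
db/dt = r k_rel p − k_term b,        r = l_p / l_b
```

with `k_init` the initiation rate (absorbing free-Pol II concentration),
`k_pre` the premature (non-productive) pause-release rate constant,
`k_rel` the productive pause-release rate constant, `k_term` the
termination rate constant, and `l_p`, `l_b` the pause-region and gene-body
lengths. The length ratio `r` rescales the flux of polymerases leaving the
short pause region for the much longer body. All quantities are treated as
dimensionless: the model is used to reason about ratios and relative
changes, never absolute rates, so no unit layer is provided. `r` is always
derived from the stored lengths and cannot be set independently, which
rules out inconsistent parameter states.

The system is linear, so the steady state is closed-form:

```
p_ss = k_init / (k_pre + k_rel)
b_ss = r k_rel p_ss / k_term
P_i  = p_ss / b_ss = k_term / (r k_rel)
```

The pause index `P_i` depends only on `k_term`, `k_rel` and the length
ratio. This is the model's central observation: perturbations of
initiation or premature release move both densities proportionally and
leave the pause index fixed, whereas termination and productive-release
changes reshape it.

Domain conventions: `k_init ≥ 0` and `k_pre ≥ 0` are permitted (both
zero-rate limits are analyzed); `k_rel > 0` and `k_term > 0` are required
so the steady state and pause index exist.

### Dynamics

`simulate_dynamics` integrates the system with SciPy's LSODA at
`rtol=1e-9`, `atol=1e-12`. The system is linear and non-stiff for
reasonable rates, but a stiff-safe adaptive method removes any solver
sensitivity and makes the closed-form steady state a machine-checkable
oracle: tests require the endpoint at `t = 50/min(k)` to match the algebra
within 1e-6 relative.

## Sensitivity algebra

Because `p_ss` and `b_ss` are rational in each rate constant, the finite
change `Δp(k) = p_ss[k_hi] − p_ss[k_lo]` has an exact closed form for any
step size — the sensitivity analysis is not a linearization. The module
reports both the finite changes and the analytic partial derivatives; the
tests cross-validate the two (partials against central differences at
`h = 1e-6·k`, finite changes against direct steady-state differences).
Sign classification comes from the algebraic sign of the exact expression,
not from a numeric threshold, since the signs are never borderline.

The sign table under an *increase* of each parameter:

| parameter | p_ss | b_ss |
|-----------|------|------|
| k_init    | +    | +    |
| k_pre     | −    | −    |
| k_rel     | −    | + (0 if k_pre = 0) |
| k_term    | 0    | −    |

For `k_init` or `k_pre` steps of any magnitude the effect ratio obeys
`Δp/Δb = P_i` exactly, and `|Δp| > |Δb|` iff `k_rel/k_term < l_b/l_p` iff
`P_i > 1`. Since real pause regions (< 100 bp) are ~100× shorter than gene
bodies (~10 kb), this condition is essentially always met, which is why a
coordinate decrease in pause and body signal with a much larger absolute
pause change points at reduced initiation or increased premature release.

`effect_ratio` is restricted to `{k_init, k_pre}`. One source text
summarizing this identity names `k_init` and `k_rel`, but the derivation
it summarizes pairs `k_init` with `k_pre` (for `k_rel` the two densities
move in opposite directions, so a single ratio is not the meaningful
summary); we implement the derivation's pairing.

## Waveform visualization

To display a `(p_ss, b_ss)` pair as a recognizable nascent-transcription
profile we use a sum of exponentials in position `bp ≥ 0`:

```
density(bp) = (pk_pause/pk) [ (bp/τ) e^{−(bp−τ)/τ} + pk_body (1 − e^{−bp/τ}) ]
```

whose derivative has its root at `bp* = τ(pk_body + e)/e`; `pk` is the
bracket evaluated at `bp*`, so the maximum equals `pk_pause`, and the
asymptote is `pk_body·pk_pause/pk`. Choosing `pk_body` for a desired
plateau is implicit because `pk` depends on `pk_body`; `solve_pk_body`
solves `pk_body/pk(pk_body) = plateau/pk_pause` with Brent's method on
`[0, hi]`, growing `hi` geometrically until the root is bracketed (the
ratio increases from 0 toward 1, so a bracket always exists for a feasible
plateau), tolerance 1e-10. A plateau at or above the peak is rejected as
infeasible for this shape.

Defaults: `τ = 25` bp places the peak (~27–30 bp for small `pk_body`)
well inside a sub-100-bp pause window; profiles are rendered at 1-bp steps
over a configurable extent (default 2000 bp). Both are display choices
with no effect on any inference.

## Synthetic data generator

The generator emulates PRO-seq-like single-nucleotide count tracks — the
kind of data the model is meant to interpret — without simulating reads,
alignment, or library artifacts. What it does model:

- **Gene models.** `n_genes` (default 200) genes on one synthetic
  chromosome `chrS`, alternating strands, each with a 100-bp pause window
  at the TSS and a 10-kb body window starting 500 bp downstream (the gap
  keeps pause signal out of the body window). Coordinates are 0-based
  half-open throughout.
- **Per-gene rates.** Each gene's four rate constants are the reference
  set (`k_init=1, k_pre=0.5, k_rel=0.5, k_term=1`) times independent
  log-normal factors with log-SD `rate_sigma = 0.25` (~25% CV), a modest,
  realistic gene-to-gene heterogeneity that keeps every gene's pause peak
  detectable at the default depth.
- **Counts.** Expected counts per base are `D ×` model density (flat per
  window by default; optionally shaped by the calibrated waveform), with
  `D = 100` expected counts per unit density per bp. Observed counts are
  independent Poisson draws per base — the minimal count-noise model, with
  analytic standard errors. Negative-binomial overdispersion is not
  modeled.
- **Two conditions.** Condition A is the reference; condition B multiplies
  one rate (`k_pre` by 1.6 by default) in a 30% random subset of genes
  ("targets").
- **Decay courses.** One-phase decay
  `y(t) = (y0 − plateau) e^{−kt} + plateau` sampled every 15 min over 4 h
  (17 points), Gaussian noise optional — the sampling scheme of a rapid
  protein-degradation assay.

Everything is deterministic given the config seed.

What it deliberately does not emulate: mappability and sequence bias,
overdispersion between biological replicates, unequal library depths,
transcript isoforms and internal pause sites, or divergent transcription.
Passing the recovery tests therefore shows the quantification and
inference logic is correct under Poisson counting noise at realistic
depth; it does not certify performance on real libraries, where
normalization quality and overdispersion dominate.

## Quantification

`window_density` is the window count sum divided by window length and a
library scale factor. The default scale is counts-per-million of total
track counts — transparent and testable. Note its known caveat: CPM by
total counts has a composition bias when a substantial gene fraction
changes between conditions (the perturbation itself shifts the totals and
hence every fold change by a common offset; with 30% of genes down ~23%
the offset is ~0.1 log2). The synthetic generator produces depth-matched
libraries by construction, so recovery analyses on synthetic data use
`scale="none"`; for real unequal-depth data a robust size-factor method
(median-of-ratios) would be the right tool and is out of scope here.

Fold changes use a pseudocount of 0.25 counts per window before density
conversion to avoid log-of-zero on sparse windows;
`delta_pause_index = lfc_pause − lfc_body` is exactly antisymmetric under
condition swap. Composite profiles average depth-normalized density per
position relative to the TSS, flipping minus-strand genes so downstream is
positive.

## Mechanism inference

`classify_mechanism` thresholds the two log2 fold changes at
`tol = 0.2` (the "unchanged" band half-width; a round value standing in
for 'modest change', since no sharper operational threshold presents
itself) and maps the sign pattern through the sensitivity table:
`(0,−) → term_up`, `(0,+) → term_down`, `(−,+) → rel_up`,
`(+,−) → rel_down`, `(−,−) → init_down_or_pre_up`,
`(+,+) → init_up_or_pre_down`; `(0,0)` and pause-only patterns map to
`none` (no single-rate mechanism produces a pause-only change). The
both-move classes are reported as equivalence classes because initiation
and premature release are not separable from the two densities alone:
both scale `p_ss` and `b_ss` by a common factor. A consistency flag
records whether the observed absolute-density effect ratio matches the
reference pause index within 20% relative, as the identity `Δp/Δb = P_i`
predicts. The reference pause index defaults to the median condition-A
pause index of the analyzed genes.

`estimate_rate_change` inverts the closed forms under an assumed
mechanism: the `k_init` fold equals the pause-density ratio B/A; the
combined `(k_pre + k_rel)` fold equals the inverse ratio. No attempt is
made to split the pool.

`fit_one_phase_decay` is bounded nonlinear least squares
(`scipy.optimize.curve_fit`) on the parameterization
`(amplitude, plateau, k) ≥ 0` with `y0 = amplitude + plateau`, which
encodes `y0 ≥ plateau ≥ 0`, `k ≥ 0`. Three data-driven starts are tried
(amplitude/plateau from the first/last observations, `k` from a
log-linear fit of the early points, and ×10 above/below); the lowest-RSS
fit wins. A `fix_plateau_zero` variant pins the plateau for
full-degradation fits. Constant series degenerate cleanly (`k → 0` or
amplitude → 0, RSS ≈ 0).

## Problem sizes and tolerances

Default analysis scale — 200 genes × ~11 kb on one synthetic chromosome,
two conditions, depth 100 — was chosen so the full pipeline runs in
seconds on a laptop while the pause window still collects ~10⁴ counts per
gene (per-gene log2-FC counting noise ~0.02). ODE tolerances 1e-9/1e-12;
waveform root solves to 1e-10; decay fit `xtol=ftol=1e-14` so noiseless
parameters are recovered to ≤1e-6.

## Known limitations

- The model is deterministic; no chemical-master-equation (stochastic
  single-cell) variant.
- No fitting of absolute rate constants to real PRO-seq libraries, and no
  differential-expression statistics; fold changes are descriptive.
- The initiation/premature-release ambiguity is inherent to steady-state
  densities and is reported, never resolved.
- The reference parameter set is illustrative (chosen so `P_i = 200` with
  a pause peak of 1.0); it is not a fitted description of any cell line.
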