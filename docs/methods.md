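# Methods

## Model

A locus has *n* CpG sites; a molecule's methylation pattern is a binary
vector, indexed k ∈ {1, …, 2ⁿ} with k − 1 the pattern read as a binary
number (leftmost site = most significant bit, so index order equals
lexicographic order of the pattern strings). The sample defines a
distribution θ over patterns; sequencing reports a corrupted pattern per
read. Corruption is independent across sites and reads:

1. **Non-conversion** with probability ε: an unmethylated site registers
   methylated. Methylated sites are unaffected — conversion error is
   strictly one-directional, which is what skews corrections towards
   less-methylated patterns.
2. **Sequencing error** with per-site probability η_s, symmetric in both
   directions.

The per-site transition matrix is the product of the conversion matrix and
the symmetric error matrix; the pattern-level matrix is their Kronecker
product M. Reads are independent, so observed counts y over the 2ⁿ
patterns are multinomial(N_read, φ) with φ = θM, and the log-likelihood is
L(θ|y) = Σ_k y_k log(θM)_k, maximised subject to θ in the simplex.

ε and η are **inputs**, assumed estimated externally (non-CpG cytosines,
unmethylated spike-ins). Out of scope by design: site-dependent ε,
asymmetric read error, reads with missing sites, differential epiallele
amplification, and extraction of pattern counts from alignments.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| ε | non-conversion probability | required | [0, 1), warn > 0.1 |
| η_s | per-site read error | required | [0, 0.5); scalar broadcasts to all sites |
| mode | search domain | fast | slow = all 2ⁿ patterns, guarded at n > 8 |
| tol | EM stop: log-likelihood gain per sweep (nats) | 1e-10 | absolute |
| max_iter | EM sweep cap | 1e5 | convergence flag recorded |
| zero_candidate_tol | boundary-snap candidate magnitude | 1e-5 | see below |

## Optimisation

The MLE is unique (the likelihood is concave on the simplex and strictly
so on the relevant face), so the optimiser is interchangeable; we use
multiplicative EM updates θ_j ← θ_j · Σ_k (y_k M_jk/φ_k)/N. These are a
minorise–maximise scheme (monotone in L), preserve the simplex exactly,
and drive components whose optimum lies on the boundary to zero
geometrically. The start is the additively smoothed observed proportion
(y + ½)/(N + |support|/2), strictly interior; uniqueness makes the result
start-independent, which the tests verify with random Dirichlet restarts
(componentwise agreement 1e-5 — the practical parameter accuracy that a
1e-10 likelihood tolerance buys at these read depths).

Fast mode restricts the support to observed patterns and evaluates only
the |support| × |observed| block of M entrywise (O(n·|J|·|K|)); the full
2ⁿ × 2ⁿ matrix is only materialised for n ≤ 12. Probabilities are computed
in linear space: entries of M are products of at most n factors of
magnitude ~1, nowhere near underflow for realistic n.

**Boundary refinement.** A finite-tolerance optimiser stops slightly
inside the simplex, so components that belong on the boundary end at tiny
positive values. Every component below `zero_candidate_tol` (1e-5) is a
candidate: the log-likelihood is evaluated with each candidate zeroed
individually, and with all candidates zeroed jointly, mass renormalised.
If the best boundary point is at least as likely as the current point
(within 1e-9 nats — ties prefer the more parsimonious boundary point), it
is adopted and the estimate is **re-optimised over the reduced support**;
the cycle repeats until the support is stable. Zero-calling is therefore
driven by the likelihood comparison, not by magnitude alone: a component
can converge to a genuine optimum of 7×10⁻⁵ and must then be kept, because
zeroing it measurably lowers the likelihood. Observed patterns whose final
estimate is identically zero are reported as spurious.

The magnitude threshold only selects *candidates*; it does not decide.
Raising it widens the set of boundary points examined at extra cost,
lowering it risks leaving a stalled component unexamined — 1e-5 sits an
order of magnitude below one read's worth of frequency at the depths this
tool targets (N ~ 10³–10⁴), where EM has demonstrably converged past it.

**Finite-accuracy discrepancies.** On the two bundled benchmark tables the
exact MLE disagrees with what a loosely converged optimiser reports on
exactly one borderline pattern each. On the n=6 table, pattern `110000`
(one read) has
θ̂ = 7.4×10⁻⁵ in *both* modes — the slow- and fast-mode optima coincide,
because the exact full-simplex MLE already assigns zero to every
unobserved pattern — and zeroing it costs 0.0116 nats, so both modes call
13 of the 18 truly spurious patterns; a looser optimiser that stops ≳0.01
nats short of the maximum snaps it to zero in the larger slow-mode search
and reports 14. Likewise on the n=8 honey-bee table, pattern `01110100`
(one read) has θ̂ = 2.7×10⁻⁵ (zeroing costs 1.1×10⁻³ nats), so 17 — not
18 — of 36 patterns are called spurious, 8 of the 11 single-read ones.
The package reports the likelihood audit for such cases: the retained
support always has log-likelihood at least that of the zeroed alternative,
re-optimised. These one-read calls are genuinely marginal; downstream
users should treat estimates of order 1/N_read or below as "present but
unquantified".

The naive proportions y/N and the inversion estimate (y/N)M⁻¹ are exposed
for comparison only; the former ignores the error model, the latter leaves
the simplex whenever zero counts are present.

## Simulator

`simulate_counts` draws N_read latent patterns multinomially from θ, then
corrupts each read site by site in the model's order — conversion first,
then read error — so the observed counts are exactly multinomial(N, θM);
the tests confirm the two routes are distributionally indistinguishable.
The latent true pattern of every read is retained, giving exact
spurious/real ground truth. A single seeded generator drives each
simulation; runs are bit-for-bit reproducible given the seed.
`truncate_distribution` builds sparse "true" distributions from initial
estimates on real data by flooring small components (the floored
distribution is renormalised — a distribution must sum to one).

What the simulator emulates is precisely the inference model: multinomial
sampling, per-site independent corruption, no more. Real data additionally
contain PCR amplification bias, pattern-correlated error, chimeric reads
and reads with missing sites — none are simulated, so passing recovery
tests demonstrates correctness of the estimator under its own assumptions,
not robustness to model misspecification (the sensitivity of estimates to
mis-specified ε and η can be explored by analysing simulated data with
perturbed rates).

The bundled benchmarks: the n=6 table (N_read = 2000, ε = 0.005,
η = (0.008, 0.006, 0.006, 0.006, 0.006, 0.008) modelling end-of-read
degradation) has six true epialleles and 18 spurious observed patterns;
the n=8 honey-bee amplicon (gene GB17113, 454 reads, N_read = 1793,
analysed at ε = 0.01, η = 0.02) has 36 observed patterns, 11 of them
single-read.

## Spurious-pattern evaluation

With truth known, declaring pattern i spurious when a statistic is ≤ K
(ties spurious) gives TP (called and truly spurious), FP (called, truly
present), TN, FN over the observed patterns, and TPR = TP/(TP+FN),
FPR = FP/(FP+TN), reported as NA when a class is empty. The default
threshold grid is {0, 1} ∪ {distinct statistic values} — the exact step
positions. At K = 0 the naive statistic y/N can never flag anything
(observed proportions are positive by construction), which is the basic
case for the corrected estimate. This classifier needs the truth, so it is
an evaluation device for simulations, not an inference procedure — the
threshold does not translate into a p-value because patterns are not
independent.

## Problem sizes used in the shipped tests

Exhaustive pattern-coding checks run to n = 10; dense-matrix properties to
n = 8; distributional simulator checks use up to 10⁶ reads at n ≤ 3;
parameter-recovery uses 10 replicates of 10⁵ reads at n = 6; the optimiser
is audited against 10⁵-point Dirichlet random searches at n ≤ 3. The whole
suite runs in a few seconds on one core.

## Known limitations

* Slow mode is exponential in n (guarded at n > 8, overridable); fast mode
  degrades when the observed-pattern count is large (soft warning at 200).
* No uncertainty quantification on θ̂ (no CIs or posteriors); spurious
  calls are point-estimate support decisions, sensitive near 1/N_read.
* ε and η are trusted as given; errors in them propagate directly into θ̂.
* Homogeneous conversion rate across sites and molecules is assumed.
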