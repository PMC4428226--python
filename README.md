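# methpat

Maximum-likelihood estimation of CpG **methylation-pattern (epiallele)
frequencies** from bisulphite amplicon sequencing read counts.

## The problem

Each bisulphite read covering a locus with *n* CpG sites carries a binary
methylation pattern (1 = methylated, 0 = unmethylated) — a snapshot of one
DNA molecule from one cell. Counting reads per pattern gives far more
information about the epigenetic heterogeneity of a sample than per-site
methylation levels, but the raw counts are contaminated by two error
processes:

* **incomplete bisulphite conversion** — an unmethylated cytosine fails to
  convert with probability ε (~10⁻²) and registers as methylated;
* **sequencing error** — the observed state of site *s* flips in either
  direction with probability η_s (~10⁻²).

Both create **spurious patterns**: patterns observed in the reads
(y_k > 0) that are absent from the sample (θ_k = 0). `methpat` estimates
the true pattern distribution θ and calls each observed pattern as real or
spurious. It is aimed at targeted (amplicon, RRBS, capture) bisulphite
data where per-locus coverage is deep; extraction of pattern counts from
raw reads is upstream of this package.

## The model

True patterns are indexed k = 1, …, 2ⁿ (k − 1 is the pattern read as a
binary number). Errors act independently per site, so the probability that
a molecule with pattern k is read as pattern ℓ is the Kronecker-product
matrix M = E₁ ⊗ … ⊗ E_n built from per-site 2×2 transition matrices

    E_s = [ 1−ε−η_s+2εη_s   ε+η_s−2εη_s ]
          [ η_s             1−η_s       ]

(conversion error times symmetric read error; methylated states are immune
to conversion). Observed counts y are multinomial with cell probabilities
φ = θM, and θ̂ maximises the log-likelihood

    L(θ | y) = Σ_k y_k log( Σ_j θ_j M_jk )

over the (2ⁿ−1)-simplex. Inverting M on the naive estimate y/N fails —
M shrinks the simplex, so the inverted vector has negative entries whenever
zero counts are present — hence the constrained optimisation. The MLE is
unique; `methpat` finds it with simplex-preserving multiplicative (EM)
updates followed by a boundary-refinement step that compares the likelihood
at nearby boundary points and snaps near-zero components to exact zero when
the likelihood does not decrease. Observed patterns with θ̂_k ≡ 0 are
reported as spurious.

Two modes: **fast** (default) fixes θ_k = 0 wherever y_k = 0 and searches
only the observed support — accurate in practice and scalable to large *n*;
**slow** searches all 2ⁿ patterns and is practical for n ≤ 8.

## Worked example

Estimate pattern frequencies for a 6-CpG amplicon with 2000 reads
(`table1_counts.tsv` is the bundled benchmark table, written with
`methpat.write_counts(methpat.table1_fixture()[1], "table1_counts.tsv")`):

```sh
methpat estimate --counts table1_counts.tsv \
    --epsilon 0.005 --eta 0.008,0.006,0.006,0.006,0.006,0.008 \
    --mode fast --out estimates.tsv
```

logs

```
methpat INFO estimate: n=6 N_read=2000 mode=fast epsilon=0.005
  eta=[0.008,0.006,0.006,0.006,0.006,0.008] zero_tol=1e-05 iterations=252
  converged=True log_likelihood=-3139.360649 boundary_snaps=13 spurious=13
```

and `estimates.tsv` begins

```
pattern	y	y_over_N	theta_hat	spurious
000000	907	0.4535	0.481083	false
000001	15	0.0075	0.00136311	false
000010	8	0.004	0	true
000100	7	0.0035	0	true
001000	99	0.0495	0.0467365	false
```

Reading: 907 of 2000 reads were fully unmethylated (45.35%), but after
correcting for the error rates the fully unmethylated epiallele makes up
48.11% of the sample — error pushed some of its reads into neighbouring
patterns. Pattern `000010` drew 8 reads, yet its estimated frequency is
exactly zero (`spurious true`): those reads are fully explained as
single-site conversion failures of `000000`. Thirteen of the 24 observed
patterns are called spurious.

The companion commands `methpat simulate` (draw reads from a known θ under
the same error model, retaining each read's latent true pattern) and
`methpat evaluate` (TPR/FPR threshold curves for spurious-pattern detection
against a known truth, for θ̂ and for y/N) support simulation studies; see
`methpat <command> --help`. Everything is also callable as a library
(`estimate_fast`, `estimate_slow`, `simulate_counts`, `tpr_fpr_curve`, …).

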