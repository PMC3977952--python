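# countseg

Exact multiple change-point detection for genomic count series — RNA-seq or
DNA-seq coverage, one non-negative integer per position — by pruned dynamic
programming under a negative binomial model, with plateau compression,
data-driven dispersion estimation and penalized selection of the number of
segments.

## Who this is for

Analysts who want to partition a raw per-base read-count profile into
homogeneous regions — transcribed vs. silent intervals in RNA-seq, copy-number
levels in DNA-seq — without a comparison profile and without normalizing away
the count nature of the data.

## The model

The counts `y_1..y_n` are independent, piecewise identically distributed: a
segmentation `m` into `K` segments assigns each segment `r` a parameter
`θ_r`, with

    Y_t ~ NB(φ, θ_r)   for t in r,

the negative binomial in its success-probability parametrization:
`E(Y) = φ(1−θ)/θ`, `Var(Y) = φ(1−θ)/θ²`, so small `θ` means high signal and
the overdispersion `φ > 0` is shared by all segments.  Poisson and Gaussian
losses are available through the same interface.  With the per-point loss
`γ(y, θ) = −φ log θ − y log(1−θ)` (constants dropped), the optimal
segmentation in `K` segments minimizes `Σ_r min_θ Σ_{t∈r} γ(y_t, θ)`, via
the classical recursion

    C(k, t) = min_τ { C(k−1, τ) + min_θ c((τ, t], θ) }.

The pruned dynamic programming algorithm computes `C(K, n)` **exactly** for
all `K ≤ Kmax` in near-linear empirical time: each candidate last
change-point keeps the interval of `θ` values on which it is not yet
dominated, and is discarded forever once that interval empties.  Three
supporting pieces make the method practical:

- **Plateau compression** — maximal runs of equal counts collapse to single
  weighted points without changing any optimal cost (a change-point inside a
  plateau is never necessary), which is a large constant-factor saving on
  zero-heavy coverage;
- **Dispersion estimation** — `φ` is estimated by the median of the moment
  estimator `mean²/(variance − mean)` over sliding windows (width 15,
  doubled until the median is positive);
- **Model selection** — `K̂` minimizes `C(K, n) + β·K·(1 + 4√(1.1 + log(n/K)))²`,
  with `β` calibrated from the data by the slope heuristic (AIC/BIC also
  provided).

## Worked example

```python
from countseg import CountSegmentation, simulate_profile, rand_index

prof = simulate_profile(n=1000, K=10, phi=2.3, seed=7)   # known truth
res = CountSegmentation(prof.series).fit(kmax=31)        # phi estimated
print(res.summary())
print("Rand index vs truth:", round(rand_index(prof.true_labels(), res.labels()), 4))
```

prints

```
Count series segmentation (pruned dynamic programming)
==========================================================
family:              nbinom
n (positions):       1000
effective points:    731  (compression x1.4)
phi (dispersion):    1.42948  [estimated]
Kmax:                31
criterion:           oracle  (beta = 0.05118)
selected K:          10
cost C_(K,n):        2461.55

 segment  start  end  n_r      mean  theta_hat
       1      1   58   58  0.603448   0.703164
       2     59  226  168  7.339286   0.163020
       ...
      10    936 1000   65  8.523077   0.143630

Rand index vs truth: 0.9977
```

The fit recovered the true number of segments (10), alternating low-mean
(~0.6 reads/base) and high-mean (~7–10 reads/base) regions; the Rand index of
0.998 says that virtually every pair of positions is classified (same/different
segment) as in the truth.  `res.breakpoints()`, `res.segment_table()`,
`res.select("bic")` and `res.plot()` give programmatic access.

The same pipeline from the shell:

```bash
countseg simulate --n 1000 --k 10 --phi 2.3 --seed 7 --out sim
countseg segment sim.counts.txt --kmax 31 --out fit        # writes .bed/.tsv/.json
countseg evaluate sim.truth.json fit.report.json --metric rand
```

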