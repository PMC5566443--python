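# callscale

Heavy-tailed analysis of dyadic animal calling dynamics.

Mated zebra finches exchange thousands of short "stack" contact calls per
day with no fixed context.  `callscale` is for researchers who have
time-stamped vocal-event tables for pairs of individuals and want to ask
what structure that torrent of calls has: it separates each bird's calls
into **self-contained** events (immediately preceded by the bird's own
call) and **reactive** events (immediately preceded by the partner's call),
and characterizes the inter-event intervals τ of each of the four modes
(f-f, m-m, m-f, f-m).

The central statistical object is the power-law survival function

    P(T ≥ τ) = (τ / τ_min)^(1−α),    τ ≥ τ_min > 0,

fitted by maximum likelihood with the lower bound τ_min selected by
minimizing the Kolmogorov–Smirnov distance over all candidate bounds, and
assessed by a seeded semiparametric bootstrap goodness-of-fit p-value.
Dyadic calling lives in the bursty regime 2 < α < 3 — finite mean, infinite
variance — and the fitted exponent acts as a per-bird behavioral signature.
Around that core the package provides:

* exponential and lognormal competitor fits (closed-form MLEs + one-sample
  KS tests) and a three-way model comparison;
* call-rate series (γ = ΔN/Δt in 30 s bins), rate changes Δγ, OLS R² of
  cumulative counts and rates, and the log-log periodogram slope of Δγ;
* a circadian-bias control (rank correlation of interval length with clock
  time, permutation p-value) to rule out day-cycle artifacts;
* paired Wilcoxon signed-rank contrasts of exponents across experimental
  conditions (separation, isolation, water removal), with the one-sided
  test gated on two-sided significance;
* a renewal-plus-response simulator generating dyadic streams with known
  exponents, optional response coupling, day/night masks and
  condition-dependent exponent shifts, so the whole pipeline is testable
  without any recordings.

## Worked example

Simulate one 10 h dyad recording, classify it, and fit the female
self-contained intervals:

```python
from callscale import (SimConfig, simulate_dyad, classify_calls,
                       intervals_by_mode, interval_summary, compare_models)

rec = simulate_dyad(SimConfig(duration=36000.0), seed=11)
classified = classify_calls(rec)
ivs = intervals_by_mode(classified, "f-f", mask=rec.mask)
print(interval_summary(ivs))
cmp_ = compare_models(ivs, n_boot=200, seed=1)
```

which prints (numbers from the code as shown):

```
simulated 13110 calls from pair 'sim-pair'
f-f: n=2478  min=0.010  max=633.9  mean=3.529  sd=16.856
power law: alpha=2.321  tau_min=1.274  D=0.0088  n_tail=1639  gof p=0.985
exponential: mu=3.529  KS p=2.17e-107
lognormal:   mu_log=0.591  sigma_log=0.937  KS p=2.08e-64
preferred model: power-law
```

Read: the female produced 2,478 self-contained intervals whose standard
deviation (16.9 s) dwarfs the mean (3.5 s) — the signature of a heavy tail.
The fitted tail above τ_min ≈ 1.3 s follows a power law with α ≈ 2.32
(finite mean, divergent variance) and the bootstrap cannot distinguish the
data from that model (p = 0.985), while the one-sample KS tests crush the
exponential and lognormal alternatives.

The same flow is scriptable from a shell:

```sh
callscale simulate --seed 11 --out events.csv
callscale classify --in events.csv --out intervals.csv
callscale fit --in intervals.csv --mode f-f --nboot 200 --seed 1 --out fits.json
callscale rates --in events.csv --bin 30 --out rates.csv
callscale compare --fits exponents.csv --contrast baseline:wr-male \
          --direction increase --out report.csv
```

and `run_pair` / `run_study` (CLI verb `run`) orchestrate classification,
all four mode fits, both birds' rate spectra, the circadian check and the
condition contrasts into JSON + CSV reports.

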