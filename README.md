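# trfkin

Turnover and Argonaute-association analysis of tRNA-derived fragments
(tRFs) from small-RNA sequencing.

## The problem

Precursor tRNAs are transcribed by Pol III as `leader + mature body
(± intron) + trailer`, and endonucleolytic maturation releases positionally
defined fragments: tRF-leaders (RNase P cut), tRF-1s (the trailer, released
by RNase Z and ending at the poly-U terminator), intron-tRFs (TSEN cut),
plus tRF-5s / tRF-3s / internal fragments from the mature body.  tRF-1s are
as abundant as miRNAs and of similar size, yet are largely excluded from
the RNA-induced silencing complex.  Measuring their turnover explains why:
they are degraded extremely fast (median half-life well under an hour),
while most miRNAs are stable for the duration of a transcription-shutoff
experiment.

`trfkin` provides the complete computational side of such a study as a
tested, reusable library plus CLI:

* **`trfkin.classify`** — map collapsed small-RNA sequences end-to-end onto
  pre-tRNA gene models (≤ 1 mismatch, non-templated 3′ CCA handled) and
  assign each to one positional class.
* **`trfkin.halflife`** — decay-profile-normalized half-life estimation
  from actinomycin-D time courses: RPM or spike-in scaling, T0
  normalization, stable-set detection, per-timepoint decay factors,
  nonlinear least-squares fits of `A(t) = A0·e^(−kt)` with
  `half-life = ln 2 / k` capped at the experiment duration (12 h).
* **`trfkin.enrichment`** — RIP vs input fold enrichment and condition
  shifts (e.g. control vs XRN2 knockdown).
* **`trfkin.metagene`** — strand-aware coverage profiles anchored at tRNA
  gene boundaries (trailer metagenes).
* **`trfkin.simulate`** — a synthetic small-RNA-seq generator with fully
  known ground truth (toy genome, per-class decay-rate distributions,
  negative-binomial noise, constant-abundance spike-ins, RIP pairs), used
  throughout the test suite for recovery checks.

## Worked example

```python
import trfkin as tk

data = tk.simulate_dataset(tk.SimParams(seed=1))   # genome + truth + counts
result = tk.run_halflife(data.timecourse)          # full half-life pipeline
print(result.summary.round(3))
```

```
              n  median_half_life_h  median_expr_t0  median_log2fc_0h_1h
class
intron-tRF   15               3.764         228.039                0.014
miRNA       120              12.000         848.414                0.196
misc-tRF     20               5.214         249.845                0.044
tRF-1        40               0.338        3277.357               -2.697
tRF-3        30               8.331         225.211                0.214
tRF-5        30               7.127         532.478                0.143
tRF-leader   5                2.997         186.366               -0.312
```

Reading the table: tRF-1s are the most abundant class at steady state
(median 3277 normalized counts) yet turn over fastest — a median fitted
half-life of 0.34 h against a configured 0.3 h, and a 1-hour median log2
fold change of −2.7 while the stable classes sit near 0.  Every miRNA
half-life reaches the 12 h cap (`capped` flag in `result.fits`).  The
per-timepoint decay factors (`result.profile.decay_factors`) rise from 1.0
at t = 0 to ≈ 1.5 at 12 h: the compositional inflation of stable species
that the normalization removes.

The same stages are available as a CLI:

```bash
trfkin simulate  --seed 1 --out-dir run/
trfkin classify  --genome run/genome.fa --models run/models.bed \
                 --mirnas run/mirnas.fa --reads run/reads.fa --out-dir run/cls
trfkin halflife  --counts run/counts.tsv --samples run/samples.tsv \
                 --classes run/truth.tsv --out-dir run/hl
trfkin pipeline  --seed 1 --out-dir run/all   # simulate -> classify -> halflife
```

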