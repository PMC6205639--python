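# quadcount

Unbiased population-size estimation for planar point patterns by systematic
quadrat-grid sampling.

Counting every particle in an image — spectators in a stadium, birds in a
flock, cells in a micrograph — is slow and hard to verify, while density
guesses and automated detectors are generally biased. `quadcount`
implements the stereological alternative: superimpose a uniform-random,
optionally tilted grid of square quadrats (side `t`, period `T`) on the
image, count only the `Q` particles captured by the quadrats under the
unbiased counting-frame rule, and estimate

    N̂ = (T/t)² · Q = Q / f,        f = t²/T².

Because every particle is captured with probability exactly `f`, the
estimator is unbiased for **any** population size and **any** spatial
arrangement; counting 50–200 particles is typically enough for a 5–15 %
coefficient of error. The package provides:

* the intuitive `(f, n₀)` grid parametrization (sampling fraction and
  initial number of quadrats), exactly interconvertible with `(t, T)`;
* the counting engine (half-open forbidden-line rule for point particles);
* a protocol advisor that maps the observed sample richness `(Q, n)` to an
  expected coefficient-of-error band (≈5 % / ≲10 % / ≲15 %) and tells you
  which knob to turn (`f` if `Q` is short, `n₀` if `n` is);
* empirical error measurement by `K² = 1024` systematic Monte Carlo
  replications of the grid placement, with an independent brute-force
  oracle;
* synthetic fixed-N pattern generators (uniform, gradient, clustered,
  lattice) so everything is testable without external data;
* a small CLI: `quadcount simulate | estimate | resample | sweep`.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

Generate a synthetic "crowd" of 1120 points with a perspective-like
density gradient, then estimate its size from one random grid placement
with the default starting parameters `f = 0.04, n₀ = 100`:

```sh
$ quadcount simulate --kind gradient --n 1120 --seed 11 --out crowd.csv
wrote 1120 points to crowd.csv

$ quadcount estimate --pattern crowd.csv --f 0.04 --n0 100 --seed 3
N_hat = 1125.0
Q = 45 particles in n = 36 nonempty quadrats
grid: t = 11.09 px, T = 55.43 px, theta = 30 deg (f = 0.0400, n0 = 100.0)
expected CE band: insufficient-sample
advice for CE <~10%: increase-f
```

The estimate (1125 for a true 1120) happens to be excellent, but with only
`Q = 45` particles counted the protocol cannot promise a ≤10 % error and
recommends a larger sampling fraction. Following the advice
(`f ≈ 100/1120 ≈ 0.09`, so the expected sample is ~100 particles):

```sh
$ quadcount estimate --pattern crowd.csv --f 0.0893 --n0 100 --seed 4
N_hat = 1175.8
Q = 105 particles in n = 62 nonempty quadrats
grid: t = 16.56 px, T = 55.43 px, theta = 30 deg (f = 0.0893, n0 = 100.0)
expected CE band: <~10%
advice for CE <~10%: none
```

`N̂ = 1175.8` is within 5 % of the truth. Because the pattern's true size
is known, the promised band can be verified empirically — replicate the
placement over a 32 × 32 systematic subgrid of offsets:

```sh
$ quadcount resample --pattern crowd.csv --f 0.0893 --n0 100 --K 32 --seed 3
{
  ...
  "mean_Q": 99.83,
  "mean_n": 63.01,
  "E_e": 1117.9,          # replicate mean: unbiased (true N = 1120)
  "CE_e_percent": 9.30    # inside the <~10% band
}
```

The same operations are available as library functions
(`quadcount.generate`, `params_from_fraction`, `place_grid`,
`sample_pattern`, `estimate_size`, `ce_band`, `advise`, `resample`,
`sweep`), and `quadcount.viz.plot_overlay` renders a pattern with the
placed grid and the counted points highlighted.

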