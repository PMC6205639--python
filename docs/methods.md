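# Methods

## The estimation problem

Given an image containing a finite population of `N` distinguishable
particles (people in a crowd, birds in a flock, cells in a field of view),
annotated or annotatable as a planar point pattern
`Y = {y_1, …, y_N}` inside a bounding box of `B_x × B_y` pixels, estimate
`N` from a small systematic sample instead of exhaustive counting.

## Estimator

A periodic grid of square quadrats (side `t`, period `T`, `0 < t ≤ T`) is
superimposed uniformly at random: the lower-left corner of one quadrat is
shifted to a uniform point `z` in the fundamental tile `J₀ = [0,T)²`,
dragging the whole grid. The grid may be tilted a fixed angle `θ` relative
to the image x axis. With `Q` the total number of particles captured by the
quadrats,

    N̂ = (T/t)² · Q = Q / f,      f = t²/T².

This is a Horvitz–Thompson estimator: the quadrats cover a fraction `f` of
the plane, and the counting rule guarantees every particle is captured with
probability exactly `f` under the uniform-random offset, so `E(N̂) = N`
with no assumption whatsoever about the spatial arrangement or the size of
the population. The only error is sampling variance.

### Counting rule for point particles

For extended particles, unbiasedness near quadrat edges requires the
unbiased counting frame ("forbidden line") rule. This package consumes
zero-extent annotated positions, for which the rule reduces to a half-open
boundary convention: a point with tile-local coordinates `(l_x, l_y)` is
counted iff `l_x ∈ [0, t)` and `l_y ∈ [0, t)`. Each point then belongs to
exactly one quadrat of the `t = T` tiling and has inclusion probability
exactly `f` otherwise (property-tested by exhaustive offset integration).
Which edges are closed is immaterial for points; we fix
lower-left-closed / upper-right-open. Events on the open edges have
probability zero under a continuous offset.

### Grid frame and tilt

The grid frame is the image frame rotated by `θ` about the bounding-box
origin; points are mapped by the inverse rotation and an axis-aligned grid
is used, which is mathematically identical to rotating the grid. The
rotation center is a pure convention — any fixed center gives the same
statistics because the offset is uniform in `J₀`. Coordinates are
continuous pixels, y increasing downward, origin at the bounding-box
top-left. The default `θ = 30°` guards against accidental alignment of
quadrat rows with particle rows (regular patterns sampled by an aligned
grid have strongly inflated variance — reproducible here with the lattice
generator at `θ = 0`); it is configurable.

## The (f, n₀) parametrization

Choosing `t, T` in raw pixels is unintuitive. The equivalent pair

    f  = t²/T²            (sampling fraction = inclusion probability)
    n₀ = B_x·B_y / T²     (initial number of quadrats over the box)

separates the two levers that matter: `f` controls the expected sample size
`E(Q) = f·N`, and `n₀` controls over how many quadrats that sample is
spread. Conversions are exact: `T = √(B_x·B_y/n₀)`, `t = T·√f`
(round-trip tested to 1e-12).

## Protocol: reading the sample, adjusting the grid

After one placement, the observed `Q` and the number `n` of nonempty
quadrats predict the empirical coefficient of error:

| sample richness     | expected CE |
|---------------------|-------------|
| Q ≥ 200 and n ≥ 50  | ≈ 5 %       |
| Q ≥ 100 and n ≥ 30  | ≲ 10 %      |
| Q ≥ 50 and n ≥ 20   | ≲ 15 %      |
| otherwise           | insufficient |

The advisory thresholds are soft in origin ("≳", "≈"); they are
operationalized as hard cutoffs with the table configurable. If `Q` is
short of the target band, increase `f`; if `n` is short, increase `n₀`
(`advise` returns none / increase-f / increase-n₀ / both). A warning is
raised when the mean count per nonempty quadrat exceeds 5, the practical
limit for reliable manual counting — not an error. Sensible starting
values: `f = 0.04, n₀ = 100` when nothing is known; by order of magnitude
of `N`: `f = 0.1` for `N ≲ 10³` (below ~200 particles sampling barely
helps, since Q approaches N), `0.04` for `10³–10⁴`, `0.01` for `N ≳ 10⁴`.
No closed-form CE predictor from a single placement is provided; the band
table plays that role.

## Monte Carlo error measurement

With a pattern of known `N`, the sampling variance is measured by
replicating the placement `K²` times (default `K = 32`, 1024 replicates):

    N̂_k  = (T/t)²·Q_k,
    E_e   = K⁻² Σ N̂_k,
    Var_e = K⁻² Σ (N̂_k − E_e)²,
    CE²_e = Var_e / N².

Choices worth stating:

* **Systematic subgrid offsets.** The K² offsets are `u + (i,j)·T/K` with a
  single uniform `u ∈ [0, T/K)²` — a randomly shifted regular subgrid of
  `J₀`. This stratification estimates the offset integral far more
  efficiently than independent draws (tested); independent replicates are
  available behind a flag for comparison.
* **Population normalizer.** `Var_e` divides by `K²`, not `K² − 1`; the
  replicates are a designed quadrature of offset space, not an i.i.d.
  sample.
* **Normalization by true N.** `CE²_e = Var_e/N²` requires the true size;
  `resample` refuses patterns with `N = 0` rather than silently
  substituting `E_e`.
* **Counting path.** Every replicate goes through the same counting engine
  as single estimates; there is no separate fast path that could diverge
  from the tested rule.
* **Independent oracle.** `exact_mean_oracle` integrates `N̂(z)` over an
  `M × M` midpoint lattice of `J₀` (default `M = 300`), exploiting the
  fact that the capture indicator factorizes over the two grid-frame axes.
  Its relative discretization error is bounded by `2/(M√f) + 1/(M√f)²`
  for any pattern; tests assert agreement with `N` at that bound and
  cross-validate it against `resample`.
* **Sweeps.** `sweep` runs a grid of `(f, n₀)` settings over a set of
  patterns and emits a tidy table (one row per cell, failures flagged per
  row, not fatal). The reported `mean_Q` and `mean_n` are averages over
  the K² replicates — an interpretation choice, since a nonempty-quadrat
  count could also be read off a single placement.

## Synthetic patterns

All generators condition on exactly `N` points (the CE normalizes by a
known `N`, and annotated datasets carry fixed counts), are seed-
deterministic, keep points inside the box, and default to a 640 × 480 px
box with `N` spanning 96–4633 in the tests:

* **uniform** — binomial process; the neutral baseline.
* **gradient** — x uniform, y from the linear density
  `ρ(v) ∝ 1 + slope·(v − ½)`, `v ∈ [0,1]`, `|slope| ≤ 2` (inverse-CDF
  sampling); emulates the perspective foreshortening of crowd photographs.
* **clustered** — Thomas-like: uniform parents, multinomial offspring
  assignment, isotropic Gaussian displacement of scale `sigma`;
  out-of-box offspring are redrawn (not clipped), preserving exact `N` at
  the cost of slightly truncated cluster tails near edges.
* **lattice** — jittered rectangular lattice; at zero jitter it is
  seed-independent and maximally alignment-hazardous.

What these do **not** emulate: the hard-core inhibition of real crowds
(people cannot overlap), occlusion-driven annotation noise, and the
specific clustering of any real dataset. This matters for interpreting the
band table: for a binomial pattern the ensemble-mean replicate variance is
exactly `Var_z(Q) = N·f·(1−f)` (projected onto the `T`-torus, the points
are i.i.d. uniform and pair covariances average to zero), so
`CE ≈ √((1−f)/Q)` — about 9.5 % at `Q = 100` and 6.9 % at `Q = 200`.
Inhibited real-world patterns sit lower; the ≈5 % figure at `Q ≈ 200`
reflects that extra regularity, and a binomial pattern lands nearer 7 %.
Passing tests therefore demonstrate unbiasedness and the ≲10 %/≲15 % bands
on neutral synthetic structure, not the exact error level of any
particular real dataset.

## Numerical and degenerate-input conventions

* `f = 1` (`t = T`) partitions the plane: every placement returns `Q = N`
  exactly and `CE_e = 0`.
* Empty patterns sample to `Q = 0, n = 0` (valid); estimation from `Q = 0`
  returns `N̂ = 0`; resampling an empty pattern is refused (CE undefined).
* Quadrat enumeration returns a conservative superset of the quadrats that
  could intersect the box (empty quadrats contribute nothing), avoiding
  exact rotated-rectangle intersection tests.
* Offsets are normalized modulo `T` on construction, making grid
  placements translation-stationary by construction.
* Tight bounding boxes inferred from bare CSVs are padded by a relative
  epsilon so extreme points stay inside under floating-point rounding.

## Problem sizes in the test suite

Unit and property tests run on patterns up to `N = 4633` with
`K² = 1024` replicates and offset sweeps up to 500²; the full-grid
unbiasedness check covers 4 generators × 4 sizes × 6 `(f, n₀)` settings.
The complete suite runs in well under a minute on one CPU.
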