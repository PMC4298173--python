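# Methods

## The quantity: match length distributions

A maximal exact match (MEM) between two DNA sequences (or two loci of one
sequence) is an identical substring pair that cannot be extended on either
side — extension is stopped by a mismatch, a sequence boundary, or an
ambiguous base `N` (which matches nothing, itself included). The match
length distribution (MLD) `m(r)` counts MEMs of length `r` in a
self-alignment (paralogous pairs) or a comparative alignment of two
genomes (dominated by orthologous pairs).

For two iid random sequences of length `L` with per-site chance-match
probability `p`, the expectation is geometric,

    m_iid(r) = L^2 * (1/2) * (1-p)^2 * p^r,

where the 1/2 counts unordered segment pairs. A comparative alignment of
two *distinct* sequences realises one count per ordered A–B position pair
and therefore twice this value; `iid_mld` exposes both conventions
(`half`, the default, and `full`), and the tests compare measured
histograms against whichever convention the counting at hand realises.
At `L = 1 Gbp`, `p = 1/4` essentially no chance match exceeds 30 bp, so
lengths beyond ~25–30 bp ("the tail") carry the duplication signal.

## The model: stick breaking integrated over a pair density

A duplication creates two identical segments of length `K` that then
diverge. At dimensionless divergence `tau` (expected substitutions per
site along the connecting path) the expected MLD of one pair is the
stick-breaking kernel

    m(r, tau) = [2 tau + tau^2 (K - r)] exp(-tau r),    1 << r < K.

A genome's MLD is this kernel integrated against the pair density
`N(tau)` — the number of segment pairs at divergence `tau`:

    m(r) = ∫ m(r, tau) N(tau) dtau.

Because the kernel concentrates at `tau ~ 1/r`, only the small-`tau`
behaviour of `N` matters for the tail: if `N(tau) ~ tau^beta`, then
`m(r) ~ r^-(3+beta)`. The package evaluates four densities:

* **Yule family** — every segment duplicates at rate `lam*K`:
  `N(tau) = (lam K / 2 mu) e^(lam K T) e^(lam K tau / 2 mu)` on
  `[0, 2 mu T]`. `N(0) > 0`, so the tail is
  `m(r) = lam K^2 e^(lam K T) / (mu r^3)`.
* **Random duplication at stationarity** — `N` constant, tail
  `m(r) = A L / r^3` with `A = lam K / mu`; the longest expected match is
  `rmax = (A L)^(1/3)` capped at `K`.
* **Retroduplication** — one source gene (mutation rate `a*mu`, `a < 1`)
  spawns copies (rate `mu`) that never duplicate. With duplication times
  uniform on `[0, T]`, the pair distance is
  `tau = mu(2T - T1 - T2) + a mu |T1 - T2|`. Writing `s = tau/(mu T)`,
  its density is the triangle `f(s) = s/(1+a)` for `s <= 1+a` and
  `(2-s)/(1-a)` for `1+a <= s <= 2` (derived here from the geometry of the
  unit square; the whole density is `(lam K T)^2/2 * f(s)/(mu T)`). Thus
  `N(0) = 0`, `N'(0) = lam^2 K^2 / (2(1+a) mu^2)`, and the tail is
  `m(r) = 3 K^3 lam^2 / ((1+a) mu^2 r^4)`.
* **Comparative alignment** — the distance of an orthologous pair is
  `tau_A + tau_B`, so `N` is a convolution that always vanishes at 0;
  generically `N'(0) > 0` and
  `m(r) = N'(0) (6K - 2r) / r^4 ~ r^-4`. If the first derivative also
  vanishes (e.g. `N ~ tau^2`), the tail steepens to `r^-5`.

## MEM enumeration

Sequences are encoded over a suffix array (numpy prefix doubling,
O(n log^2 n)) with Kasai's LCP array. Every `N` and every record
separator receives a unique integer symbol, so it is equal to nothing and
no match can span it; multi-record FASTA input is concatenated with an
`N` joint (the "pseudogenome" construction). MEMs are read off LCP
blocks: suffix pairs with common prefix >= `minlen` are right-maximal by
construction and kept when their preceding symbols differ
(left-maximality). Self-alignments report each unordered locus pair once
(`pos_a < pos_b`) and exclude the identity diagonal; matching is
forward-strand by default with an optional reverse-complement pass that
reports forward B-coordinates and a `-` strand marker. Coordinates are
0-based, half-open. The enumerator is validated against a quadratic
brute-force oracle on hundreds of random instances, including `N`-bearing
ones and highly repetitive duplication families.

The uniqueness filter mirrors the published match-filtering rule: all
match strings are compared all-vs-all, and any match sharing a continuous
exact segment longer than `share_threshold` (default 20, i.e. >= 21 bp)
with another match is discarded.

## Log binning and tail fitting

MLDs are binned geometrically (default ratio 1.25) with bin edges snapped
up to integers, so each bin covers a whole number of lengths and
`density = count / width` conserves the total exactly. The tail exponent
is estimated by weighted least squares of `log(density)` on
`log(geometric-mean length)` with match-count weights (Var[log n] ~ 1/n
for Poisson counts), mirroring the field's graphical practice rather than
a maximum-likelihood power-law fit. The upper fit bound defaults to the
last bin with >= 5 matches to suppress tip noise; `tail_start` places the
lower bound where the iid expectation drops below 1/2 (about 30 bp for
Gbp genomes at p = 1/4). Fewer than four occupied bins raise an
`InsufficientDataError` instead of returning a spurious exponent.

## The simulator

`evolve` implements exact kinetic Monte Carlo for independent Poisson
processes: point mutations (rate `mu` per bp; an effective rate — short
indels break exact matches just like substitutions) and segmental
duplications (rate `lam` per bp). Between duplication events the
mutation process factorises over sites, so mutations are applied in exact
vectorised batches: hits per site are Poisson, and a site hit `k` times
ends unchanged with probability `1/4 + (3/4)(-1/3)^k` (the k-step
uniform-replacement chain), otherwise uniformly another base. This is
distribution-identical to event-by-event Gillespie simulation and is
verified against the per-site closed form
`P(unchanged) = 1/4 + 3/4 e^(-4 mu t/3)` and Poisson event counts.

Duplication modes: `random-dup` copies a uniform `K`-mer over another
uniform `K`-mer position (length conserved, source read before paste);
`yule` grows a family in which each of `n` segments duplicates at
`lam*K`, appending at `n*K`; `retro` always copies the source gene
`[0, K)` while reducing its own mutation rate to `a*mu`. Burn-in to
stationarity defaults to 5 expected substitutions per site — matches of
length `r` decay at rate ~`2 mu r`, so the analysed tail (r >= 20)
relaxes long before that; a plateau test confirms the tail is stable
between burn-in 4 and 5.

The speciation protocol evolves an ancestor to stationarity (with its own
heterogeneous rate field), duplicates it, draws fresh region-wise rates
`mu * Exponential(mean 1)` (region length `M`) for each descendant, and
evolves both for `t1`. **Post-split duplications default to off**
(`SimConfig.post_split_lam = 0`): at the stationary rate the per-site
paste turnover is `lam*K = 1` per unit time, so ongoing duplication would
overwrite conserved orthologous windows with probability
`1 - e^(-~2 lam K t1)` per lineage — at `t1 >= 2` essentially every
conserved element is destroyed and the comparative tail vanishes entirely
(we measured 26 matches >= 20 bp across 60 replicate pairs, none beyond
31 bp). The conserved-element regime the divergence model describes
therefore requires the post-split dynamics to be mutation-dominated;
ancestral duplications are retained, and the rate remains a parameter for
experimentation.

## Synthetic data: what it does and does not emulate

The generator realises the model's own assumptions: neutral evolution,
uniform base composition, fixed duplication length `K`, piecewise-
constant mutation rates, no selection acting on sequence content, no
repetitive-element dynamics, no inversions or rearrangements, and
(default) no reverse-complement duplications. Passing tests therefore
demonstrate internal consistency of the theory, the enumerator and the
simulator — not that real genomes obey the model; in real data, repeat
masking quality, GC heterogeneity, assembly artefacts and selection all
perturb the measured MLD.

## Study sizes and numerical choices

Desk-scale ensembles replace the original large simulations (10^4
sequences of 10^6 bp):

* random-duplication regime: 200 genomes of 1e5 bp (`mu=1, lam=1e-3,
  K=1000`), pooled; tail fit from r = 30, bin ratio 1.25. The pooled tail
  holds ~10^4 matches.
* retro regime: 150 families with `lam*K = 50`, `T = 2`, `a = 0.1`,
  `K = 1000`, yielding >= 10^4 tail matches. The family duplication rate
  is deliberately higher than the genome-wide default: the expected tail
  count per family scales as `lam^2 K^3 / r^3`, so at `lam K = 1` a
  family contributes only ~0.1 tail matches and no desk-scale ensemble
  could measure the exponent; the exponent itself is rate-independent.
* divergence regime: 800 pairs of 1e5 bp at `t1 = 2`, `M = 1000`.
  Conserved slow regions make tail matches arrive in correlated bursts,
  inflating the exponent's true spread well beyond its nominal WLS
  standard error; the replicate count is set so the spread is ~0.15.
  (The pytest suite uses 80/100/400 replicates for the same three
  regimes to stay inside its own runtime budget.)

Quadrature for `m(r) = ∫ kernel * N` uses adaptive `scipy` integration on
`[0, min(support, 30/r)]` (the kernel is < 1e-13 beyond), relative
tolerance 1e-6. Convolutions are rectangle-rule on a shared 4096-point
grid with the origin pinned to zero (exact there). Monte Carlo oracle
tests use familywise z-bounds (all |z| < ~4–5, at most the expected
number of 3-sigma excursions) rather than naive per-bin 3-sigma cuts,
which would false-alarm with ~200 bins; stick-fragment and family-match
counts are mildly overdispersed relative to Poisson because fragments of
one stick (or matches of one burst) are correlated.

## Known limitations

* The stick-breaking kernel is the continuum expression; per-site
  dynamics with back mutations give `q = 1/4 + 3/4 e^(-4 tau/3)` rather
  than `e^(-tau)`, a few-percent level effect at the divergences probed
  (the exact discrete expectation shifts fitted exponents by < 0.05 at
  the scales used).
* Heterogeneous rates apply to point mutations only; the duplication rate
  is uniform.
* `filter_unique` is quadratic in the number of candidate match pairs
  within an LCP block; fine for match sets, not meant for whole genomes.
* Tree building for pseudogene families is reduced to the
  average-distance ranking that fixes the attachment order; branch-length
  re-fitting under a constrained topology is out of scope.
* The exponent estimator is the weighted log-log regression used in
  graphical practice; no MLE mode is provided.
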