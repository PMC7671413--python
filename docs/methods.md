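# Methods

## The model: count compositions on the lattice

A composition carries only relative information: **x** and a**x** (a > 0) are
equivalent, and any meaningful function of a composition must be
scale-invariant. Count data violate the premise. A vector of counts lies on
the natural-number lattice ℕᴰ, and scaling it down generally leaves the
lattice: (86, 75, 309)/10 = (8.6, 7.5, 30.9) must be re-rounded to
(9, 8, 31), a *different* composition. The package's running theme is the gap
between a continuous compositional relationship and its nearest lattice
representation — quantization error — and the fact that this gap grows as
counts shrink.

## Exact uniqueness counting

Closure and clr are many-to-one on the lattice: all points on one ray from the
origin share an image. Two integer points are on the same ray iff their
gcd-reduced coordinate tuples are equal, so uniqueness is decided by exact
integer arithmetic (`canonical_ray`), never by floating-point comparison of
closed values — the closures of (3, 6, 9) and (1, 2, 3) can differ in the last
ulp. A lattice point is *visible from the origin* iff its coordinates are
coprime; the density of visible points is 1/ζ(D). ζ is computed by direct
series summation with an Euler–Maclaurin tail
(Σ_{n≤N} n⁻ˢ + N¹⁻ˢ/(s−1) − N⁻ˢ/2 + sN⁻ˢ⁻¹/12), N doubled until the next
correction term is below the requested tolerance (default 1e−9); this avoids
any extra dependency and matches tabulated ζ(3) = 1.2020569…

Where distinct clr images are counted *as clr vectors* (rather than via rays),
vectors are rounded to 9 decimals first; on the grids used here distinct rays
are separated by ≥ 5e−3 in clr space, so the rounding is exact.

## Log bases and the proportionality statistics

All logarithms default to base 10 (configurable). vlr ratios φₛ and ρₚ are
base-invariant; raw vlr values scale with the base and are reported in the
configured one. Variances are sample variances (N−1); the convention cancels
in φₛ and ρₚ.

φₛ and ρₚ are computed from the clr of the **full** table, as defined — they
are therefore *not* subcompositionally coherent, unlike vlr. For D = 2 they
are undefined (clr rows are (c, −c)) and the package raises; a degenerate
denominator var(cⱼ + cₖ) = 0 at D ≥ 3 instead yields NaN, so sweep curves
record gaps rather than crash. ρₚ's range is the mathematically forced
(−1, 1]: ρₚ < 0 occurs whenever φₛ > 1.

## The angle sweep

Slopes k ∈ (0, ∞) are parameterized by angle θ with k = tan θ, sampled at 900
equiangular steps from (0 + δ)° to (90 − δ)° with δ = 0.05° (keeps tan finite;
the curves are insensitive to δ below ~0.1°). The lattice approximation is
built along the dominant axis — x for k ≤ 1, y for k > 1 — with the other
coordinate rounded half-away-from-zero and clamped at 1 so logarithms stay
defined; this makes the construction mirror-symmetric about 45°. Radius bands
are half-open annuli (r_min, r_max] on the (x, y) radius only (z = 1 is an
auxiliary part appended to make φₛ/ρₚ well-defined). Neither the rounding rule
nor the band boundary convention is canonical; both are fixed here for
determinism and exercised by sensitivity-style tests rather than asserted as
the only possible construction. Bands with fewer than two points keep their
angle row with NaN statistics.

The continuous oracle (`quantized=False`) uses exact y = kx with no rounding
or clamping; its vlr is zero to double precision (≤ 1e−28 in tests) at every
angle, demonstrating that everything the lattice curves show is quantization.

## Quantization series

`scale_round` divides by the factor and rounds half-away-from-zero
(7.5 → 8, matching the (86, 75, 309) → (9, 8, 31) example; the rule is fixed
for determinism where banker's rounding would differ, e.g. at 8.5). Each
level of a series rounds the *original* counts, not the previous level.
Rounding is not associative across factors; the staged-vs-direct discrepancy
is at most 1 per cell and is tested as such.

## Zero replacement

The strategies follow the standard multiplicative / Bayesian-multiplicative
lineage but are this package's own parameterization (the lineage's published
variants differ in details across implementations):

- **multiplicative** — each zero becomes `fraction · dl` (defaults 0.65 and
  one count, the smallest observable value);
- **czm** — multiplicative with the detection limit pinned to one count
  regardless of the user's dl (which therefore coincides with the default
  multiplicative rule at dl = 1);
- **Bayesian-multiplicative** (`bayes_bl`, `bayes_sq`, `bayes_gbm`) — a
  Dirichlet prior with location **t** and strength s gives the zero cell the
  posterior-expected count tⱼ·sᵢ·Tᵢ/(Tᵢ + sᵢ). The location tⱼ is estimated
  from the data for *all three* variants: the normalized across-sample
  geometric-mean proportions (positive entries only; parts never observed
  fall back to uniform). A uniform location tⱼ = 1/D would make the
  replacements exact small rationals that frequently coincide with the
  tenths lattice — precisely the structure the experiment is designed to
  interrogate — so the data-driven location is used throughout. The variants
  differ in prior strength: BL s = D, SQ s = √Tᵢ, GBM s = 1 (one pseudo-count
  in total).

Imputed values represent observations below the detection limit, so any
candidate at or above dl is pulled back to `fraction · dl` (this binds only
for SQ at large row totals). After imputation the non-zero parts of each row
are scaled by the common factor (Tᵢ − Σ replacements)/Tᵢ: row totals are
preserved to 1e−9 and ratios among non-zero parts are untouched. A documented
caveat: parts zero in the same rows receive identical replacements under the
multiplicative family, adding spurious correlation between rare parts.

`lattice_friendly_replace` rounds the multiplicative imputation to the
nearest tenth, clamped to [0.1, 0.9], so every replacement lies on the
lattice of next lower magnitude 0.1ℕ — the property none of the conventional
strategies has, as `on_sublattice_fraction` (membership tolerance 1e−9)
verifies on the 1100-triple demonstration grid.

## Profiling, categories and filters

Log-like bins: {0}, then width-10 bins to 100, width-100 bins to 1000, and so
on, widths growing tenfold at each decade boundary. Bin percentages are per
sample (summing to 100) with five-number summaries across samples.

The six abundance/rarity categories use per-sample relative abundance in
percent against low = 0.01 % and high = 1 %, evaluated in a fixed precedence
order (AAT, CRAT, CAT, ART, MT, CRT) so the overlapping verbal definitions
resolve deterministically; in particular CRAT (below low somewhere *and* at
or above high somewhere) is claimed before CAT/CRT. The classification is a
partition — every feature gets exactly one label — and is cross-checked
against an independent brute-force truth table in the tests.

Relative-abundance filters take *proportions* (e.g. 0.0001) while category
thresholds are *percentages*; the interface converts and the distinction is
deliberate, matching how each is conventionally quoted. The
relative-abundance filter retains a feature that meets the threshold in at
least one sample by default (configurable to all/mean): the "any" semantics
keeps zero cells present after filtering, which is the behavior of interest
when studying zeros; an "all" rule would mostly eliminate them. Count filters
default to max-per-sample-count ≥ t (configurable to total), under which
nearly all features survive t = 2 on transcriptome-like data.

## Synthetic data

The generators emulate the two distributional regimes of sequencing studies,
not any specific dataset:

- `rnaseq_like` — log-normal feature profile (log-sd 1.5), multinomial
  sampling at fixed depth (defaults 16 samples × 3000 features at 100 000
  reads — study sizes scaled to desk scale). Multinomial conditioning (rather
  than per-cell Poisson) keeps per-sample totals fixed, matching the
  reads-per-sample framing. Zero fraction < 10 % at defaults.
- `metagenome_like` — Zipf-like rank-abundance base (exponent 1.8) with
  per-sample presence turnover 0.7 (each feature absent from a given sample
  with that probability, emulating community turnover across environments),
  defaults 30 samples × 10 000 features at 65 000 reads. Zero fraction ≥ 75 %,
  typically ~90 %.
- `two_species` — independent Poisson counts (means 500 and 250 by default);
  Poisson is an emulation choice for sampling scatter, not a fitted model.
- `proportional_pair` — x log-uniform over 10..1000, y = k·x·ε with
  log₁₀ ε ~ N(0, σ²): the true base-10 vlr is exactly σ², giving a known
  target for parameter recovery (±10 % at N = 10 000).

What these generators do **not** emulate: taxonomic structure, sequencing
error, batch effects, compositional feedback between features, or overdispersion
fitted to any real study. Tests passing on them show the machinery is correct
under the stated distributional shapes, not that any biological conclusion
transfers to a particular dataset.

## Problem sizes and determinism

All experiments run on desk-scale inputs: the 1000- and 1100-point grids, the
900-angle sweep with bands out to radius 100, 10 000-observation recovery
checks, and generator defaults as above — sizes chosen so the full analysis
sequence completes in seconds while leaving the qualitative structure intact.
Every stochastic component takes an explicit integer seed and is
bit-reproducible; all counts remain exact integers until a log or closure is
requested.
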