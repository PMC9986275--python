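# Methods

This note records the statistical models, default parameters, numerical
methods and known limitations of `sweepscan`. Every quantitative claim here
is either a definition or a property exercised by the test suite or
`scripts/acceptance.py`.

## Synthetic cohorts

`synthetic_data.simulate_cohort` draws a two-population cohort from a
Balding–Nichols model: ancestral frequencies `p0 ~ Uniform(0.05, 0.95)` per
site, and population frequencies

```
p_pop ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F)
```

with mean `p0` and variance `F p0 (1-p0)`; `F` is the per-population drift
parameter (default 0.1 for both populations). Genotypes are
`Binomial(2, p_pop)` dosages per individual, independently per site — there
is no linkage in the neutral background.

Sweeps are implanted at the *frequency* level: for a site at distance `d`
from the sweep center, the escape probability is `c = 1 - exp(-kappa d)`;
with probability `c` the site keeps its drifted frequency `p`, otherwise the
alt allele either rode the swept haplotype (probability `p`, new frequency
`1 - c + c p`) or did not (`c p`). This is exactly the mixture the scan's
sweep model assumes, so recovery tests are testing inference, not a shared
implementation (the simulator transforms frequencies with its own RNG; the
scan evaluates likelihoods).

Sequencing depths are negative binomial (mean 30, dispersion 5). Filter
annotations (QD, FS, MQ, SOR, MQRankSum, ReadPosRankSum) are drawn uniformly
from disjoint pass/fail bands per key, with configurable per-key fail
fractions; each band keeps a margin of at least 0.1 from its threshold and
magnitudes below 1000, and values are quantized to 3 decimals through
float32 so the textual VCF representation (htslib prints INFO floats with 6
significant digits) round-trips bit-exactly. A configurable fraction of
sites gets a second declared alt allele carried by one genotype, exercising
the biallelic filter. Ground truth (per-site frequencies, sweep flags,
per-key fail labels, per-gene sweep overlap) is returned and optionally
written to TSV.

## Filter cascade

Stage order: hard filters → depth mask → biallelic → missingness → MAF.
Thresholds follow common GATK hard-filter practice: remove a site when
QD < 10, FS > 60, MQ < 40, SOR > 3, MQRankSum < −12.5 or
ReadPosRankSum < −8. All comparisons are strict; a missing annotation never
removes a site.

**Depth masking.** A called genotype is set to missing when its depth lies
outside `[mean/3, 2*mean]` (boundaries kept). The reference mean is, by
default, the per-*site* mean depth across samples (`depth_reference:
"site"`); a per-*sample* mean over that sample's called genotypes is
available as `"sample"`. The site reference is the default because it is
invariant under both genotype masking (depths of masked genotypes are still
recorded) and site subsetting, which makes the whole cascade exactly
idempotent; a per-sample mean changes when earlier stages drop sites, so a
second pass could mask additional genotypes.

**Missingness and MAF.** A site survives when its missing fraction is
strictly below 0.10 and its minor-allele frequency over called alleles is at
least 0.02 (strict mode available). The missing fraction is computed as
`(n - called)/n`, not `1 - called/n`, so boundary cases like 1 missing of 10
compare exactly. Sites with exactly one *observed* alt allele among called
genotypes are kept and recoded to that alt; sites with zero or two or more
observed alts are removed at the biallelic stage.

## Diversity and differentiation

**π.** Per-site diversity is the pairwise-difference fraction
`(n² - c0² - c1²) / (n (n-1))` over called alleles, summed per
non-overlapping window and divided by the window's span in bp (the last
partial window by its actual length). All windows are reported; sites with
fewer than two called alleles are skipped. The acceptance suite checks exact
(not approximate) equality against a per-pair enumeration oracle.

**F<sub>ST</sub>.** Per-site Weir–Cockerham (1984) variance components
(a, b, c) for two populations, with `theta = a/(a+b+c)`, NaN when the
denominator is zero (cross-population monomorphic sites) — never reported as
zero. Sites where either population has no called genotype are skipped and
counted. The genome-wide estimator is the weighted multi-locus ratio
`sum(a)/sum(a+b+c)`; the plain mean of per-site ratios is available but
biased downward by Jensen's inequality and is not the default. Per-gene
scores take the maximum (default) or mean per-site theta over the gene span
(1-bp overlap counts); top-fraction calling takes `ceil(q N)` genes with
deterministic tie-breaking (score desc, contig order, position, gene id).
The z-transform (atanh after clipping to [0, 1−1e−12], or a z-score) is
strictly monotone, so rank-based calls do not depend on the choice.

## XP-CLR-style scan

For each direction (object or reference population focal), each sliding
window (200 kb, step 20 kb; `(L − W)//S + 1` windows per contig) collects up
to `max_snps` = 600 SNPs. Per site, the focal population contributes alt
count `k` of `n` called alleles; the reference frequency `p_ref` is the
observed frequency, shrunk only at fixation/loss to `(count+0.5)/(n+1)` so
the drift variance stays positive.

**Neutral model.** `k | p ~ Binomial(n, p)` with
`p ~ Normal(p_ref, omega p_ref (1 - p_ref))` truncated to [0, 1], the
truncated mass collapsing to atoms at 0 and 1 (computed with `scipy`'s
`ndtr`). `omega` is estimated once per direction by method of moments over
sites with reference frequency in (0.05, 0.95), requiring at least 500 such
sites (otherwise an error advises a fixed `omega`); a floor of 1e−6 keeps it
positive.

**Sweep model.** With escape probability `c = 1 - exp(-kappa d)` (`d` =
distance to the window's focal point), the site is neutral with probability
`c`; otherwise `p` maps to `1 - c + c p` with probability `p_ref` or `c p`
with probability `1 - p_ref` — the same mixture the simulator implants. The
window statistic is `clr = max(0, 2 (max_kappa L1(kappa) - L0))` with
`kappa` maximised over a 12-point log-spaced grid on [1e−7, 1e−3]; sites are
down-weighted by `1/#{sites with r² ≥ 0.95}` within the window to blunt
redundant, correlated SNPs. Top blocks are the `ceil(f N_positive)`
highest-clr blocks per direction among blocks with clr > 0 (default f =
0.01), deterministically tie-broken.

**Calibration note.** The composite likelihood is a ranking statistic, not a
calibrated test. With a very small *focal* population (e.g. 3 diploids, 6
alleles) the per-window maximisation over kappa inflates clr even under
neutrality, so that direction is anti-conservative; the neutral-calibration
acceptance test therefore pins the median clr of the large-object direction
(exactly 0 at desk scale) and checks both directions only through the
by-construction top-block counts. Sweep-recovery power is tested in the
large-object direction, where the reference frequency is noisy but the noise
is absorbed by `omega`.

## Numerics of the site likelihoods

The scalar API (`neutral_site_loglik`, `sweep_site_loglik`) integrates the
log-concave integrand `Binomial(k|n,·) × TruncNormal density` by
mode-centred Gauss–Legendre quadrature in the log domain: the mode is found
by bisection on the derivative of the log-integrand, the bracket extends to
where the log-integrand falls 60 nats below its peak, and the peak value is
factored out before exponentiation. This stays accurate when the observation
sits deep in the drift law's tail. Boundary atoms are added in log space via
`logsumexp`; likelihoods are floored at 1e−300 before logs. When
`omega → 0` (sigma below a tiny threshold) both models reduce exactly to the
binomial log-pmf, and `c = 1` returns the neutral value identically — both
are asserted exactly in the tests, as is normalisation over `k` to 1e−8.

The scan's vectorised path (`_DriftGrids`) evaluates the same integrals on a
fixed ±8σ Gauss–Legendre grid per site. This matches the exact scalar path
to ~1e−8 wherever the log-likelihood exceeds −15 (verified in the test
suite) and degrades smoothly in deeper tails, where terms are negligible for
window sums; the dense log-domain trapezoid oracle in the tests bounds both.

## Structure and phylogeny

PCA mean-imputes missing dosages per site, centres, and scales by
`sqrt(phat (1 - phat))` with the shrunk frequency
`phat = (1 + sum d)/(2 + 2 n_called)` (never zero or one), then uses the
SVD. Allele-sharing distance is the mean of `|d_i - d_j|/2` over sites
called in both samples; pairs sharing no called site get NaN, which
neighbor joining refuses. NJ follows Saitou–Nei with deterministic
tie-breaking; negative branch lengths are clamped to zero with the deficit
transferred to the sibling so the pair's path length is preserved (exact on
additive matrices, asserted on a 4-taxon case). The SNP supermatrix codes
heterozygotes as IUPAC ambiguity bases and missing as `N`, written as
relaxed PHYLIP row-by-row. `collapse_low_support` contracts internal edges
whose node label is below the threshold; `count_polytomies` counts internal
nodes of degree > 3, so the basal trifurcation of an unrooted newick is not
a polytomy.

## Intersection and enrichment

Sweep genes are the intersection of genes with F<sub>ST</sub> score
*strictly above* the threshold (default 0.9 on the z/score column supplied)
and genes overlapping the top-N XP-CLR genes (default 500; per-gene score is
the best overlapping block's clr, union over directions by default). The
result carries a provenance string echoing both parameters. Enrichment is
the exact hypergeometric upper tail (`scipy.stats.hypergeom.sf(k-1, N, K,
n)`), terms restricted to the background, sorted by (p, term id), with
Benjamini–Hochberg q-values; the tests compare against exhaustive
enumeration of the pmf tail at 1e−12 and a brute-force BH oracle.

## Pipeline

`run_pipeline` executes simulate/load → filter → density → π →
F<sub>ST</sub> → XP-CLR → intersection → enrichment → PCA → PHYLIP → NJ,
writing every artifact plus `manifest.json` with parameters, counts and
sha256 hashes per stage. All randomness flows from the config seed through
`numpy.random.default_rng`; two runs from the same config produce
byte-identical artifacts (asserted end-to-end).

## Limitations

- Sweeps are simulated and modelled at the allele-frequency level; there are
  no haplotypes, recombination maps or genealogies, so `kappa` is an
  effective escape-rate scale per bp, not `r/s` on a genetic map.
- The scan is "XP-CLR-style", written for this package — it is not the
  original XP-CLR implementation and makes no claim of numerical agreement
  with it.
- clr values are composite-likelihood ratios useful for ranking; they have
  no chi-squared calibration, and tiny focal populations inflate them (see
  the calibration note above).
- `omega` is a single genome-wide method-of-moments estimate per direction;
  locus-specific drift heterogeneity is not modelled.
- Default problem sizes (desk-scale windows, 12-point kappa grid, 600 SNPs
  per window) are this package's choices for single-CPU runs and can be
  changed via `XpclrParams`.
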