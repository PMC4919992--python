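# Methods

## The inference problem

A DNA-SIP experiment asks which community members incorporated carbon from
an isotope-labelled substrate. Incorporated ¹³C makes a genome's DNA
denser; after isopycnic CsCl centrifugation and bottom-to-top
fractionation, a labelled taxon's amplicon signal moves toward the heavy
fractions of the ¹³C gradient relative to a parallel ¹²C control gradient.
The catch is that buoyant density also depends strongly on GC content, so
absolute position in the gradient says nothing — only the paired
¹³C-vs-¹²C comparison does. `sipshift` makes that comparison quantitative
and reproducible.

## Physical model of the gradient (simulator)

Band centre of taxon *t*:

    BD_t = a + b·GC_t + Δmax · (x_t − x_nat) / (1 − x_nat)

* `a` = 1.660 g/ml, `b` = 0.098 g/ml per unit GC — the classical linear
  dependence of CsCl buoyant density on GC content.
* `Δmax` = 0.036 g/ml — the density gain of fully ¹³C-substituted DNA.
* `x_t` = ¹³C atom fraction of the taxon's DNA; `x_nat` = R/(1+R) ≈
  0.011057 with the V-PDB reference ratio R = 0.0111802.

All three are configuration, not hard-coded truths; the linear form is an
adequate approximation over the 1.66–1.78 g/ml window a soil community
occupies.

Within a gradient, a fraction `1 − smear` of each taxon's mass spreads as
a Gaussian band (σ = `band_sigma`, default 0.006 g/ml, giving realistic
3–5-fraction bands) and the remaining `smear` (default 3%) spreads
uniformly over the fraction window. The smear term models the carry-over
of DNA across fractions that CsCl gradients invariably show (wall films,
diffusion, pipetting). It is not cosmetic: without it, the heavy fractions
of an unlabelled gradient contain only the far Gaussian tail of the single
highest-GC taxon, and per-fraction normalization then assigns that taxon
~100% relative abundance there — so its difference profile turns *negative*
when it is labelled, the opposite of what real fingerprints show. Band
mass falling outside the window is reported as pellet/top tails, never
silently renormalized, so per-taxon mass is conserved to machine precision
(a tested invariant).

The fraction window defaults to 1.665–1.775 g/ml in 12 equal widths,
centred near the 1.72 g/ml mean density of a standard SIP gradient;
fraction 1 is the bottom (heaviest) fraction and fraction densities
strictly decrease with index — the container enforces this.

### Observation model

* **qPCR totals**: per-fraction 16S copies = fraction DNA mass × a global
  copy scale × mean-preserving lognormal noise with CV `qpcr_cv`
  (default 0.10, a typical qPCR technical CV).
* **Sequencing/fingerprint reads**: per fraction, counts are
  Dirichlet-multinomial over the fraction's mass composition at
  `seq_depth` reads (default 3240, a common per-sample subsampling depth)
  with concentration `overdispersion` (default 200). The concentration is
  the effective number of independent draws when depth is large: 200
  reproduces the replicate-to-replicate profile correlation of real
  amplicon/TRFLP data while leaving rare-taxon counts substantially
  noisier than multinomial. `overdispersion=None` gives plain multinomial
  sampling.
* Every run's randomness derives from one `SeedSequence`; a full
  soils × treatments × replicates experiment spawns child seeds in a fixed
  order, so outputs are byte-identical across re-runs of the same seed.

### What the generator does *not* emulate

Chimeras and sequencing error, read-length effects, primer bias, PCR
saturation of near-empty fractions, gradient-to-gradient density
miscalibration, partial labelling heterogeneity within a taxon, and
cross-feeding dynamics. Passing tests therefore demonstrate that the
*inference* behaves correctly under a faithful structural model of the
experiment, not that any particular real dataset will be as clean.

## Preprocessing rules

* **Normalization**: each fraction profile is divided by its total signal
  (the convention for TRFLP peak tables and the natural scale for
  compositional amplicon data).
* **TRF filtering**: fragments shorter than 50 bp are removed (primer/
  noise region of a fingerprint), and TRFs contributing less than 1% of a
  profile's total are zeroed per profile, then surviving columns are
  renormalized. The 1% rule is judged against the pre-filter profile total
  by default; a `relabund_basis="postfilter"` flag judges it after the
  length filter, for labs that normalize first.
* **Rarefaction**: count tables are subsampled without replacement
  (multivariate hypergeometric) to a common depth, default 3240; columns
  shallower than the depth are an error, not silently dropped.

## The screen

1. **Total-community reconstruction**: taxon totals are the per-fraction
   relative abundances weighted by each fraction's share of the 16S copy
   pool (or uniformly). This is the "what was in the soil" view used for
   the `min_abund` floor (default 0.001).
2. **Whole-community check** (`total_shift_check`): the copy-weighted mean
   BD of the entire 16S pool, averaged over replicates per arm; a ¹³C−¹²C
   difference above `tolerance` (default 0.003 g/ml) flags the timepoint
   as showing bulk labelling. With only ~10–20% of a community labelled,
   genuine pool shifts are a few thousandths of a g/ml, hence the small
   tolerance; replicate-averaged qPCR noise contributes ≈1 mg/ml-scale
   (~0.001) noise, giving clean separation in practice.
3. **Per-taxon centre of mass**: within an arm, the taxon's mass
   (relative abundance × fraction copy share) is pooled over replicate
   gradients and the density-weighted mean taken once — a ratio of sums.
   Pooling matters: averaging per-replicate ratios is heavy-tailed for
   taxa that carry little signal in a single gradient and inflates the
   false-positive rate among rare taxa.
4. **Call rule**: labelled ⇔ `com_shift ≥ com_threshold` (default
   0.010 g/ml ≈ one 12-fraction width) AND the difference profile is
   positive in ≥ `heavy_k` (default 2) heavy-side fractions, where "heavy
   side" means denser than the ¹²C arm's copy-weighted median density.
   The two-fraction requirement encodes the observation that genuine
   shifts develop gradually across adjacent fractions; the threshold
   encodes that a shift smaller than one fraction width is not resolvable
   by eye or by this design.
5. **Permutation test (optional, off by default)**: treatment labels are
   shuffled across the pooled replicate gradients and `com_shift`
   recomputed; calls then additionally require p ≤ α. It is off by default
   because the classical screen is thresholded, not tested — with 3+3
   replicates the p floor is 1/20 anyway. It needs ≥2 replicates per arm
   and is skipped with a warning otherwise.

Fractions are aligned across gradients by index (the positional
convention of comparing "heavier fractions"); taxa observed in only one
arm cannot be screened and are reported separately (`one_arm_taxa`) rather
than auto-called.

## Isotope arithmetic

Biomass δ¹³C from chloroform fumigation-extraction is the two-pool
unmixing

    δ¹³C_mic = (δ_fum·C_fum − δ_nfum·C_nfum) / (C_fum − C_nfum)

computed per replicate and reported as mean ± sd. No extraction-efficiency
correction factor (k_EC) is applied to C_mic: the formula operates on the
raw concentration difference, and since the same C_mic appears in
numerator weighting and denominator, a multiplicative efficiency factor
would cancel out of the δ value anyway. qPCR amplification efficiency is
`10^(−1/slope) − 1` for a Ct-vs-log10(copies) standard curve; δ ↔ atom
fraction conversions use `R = R_VPDB(δ/1000 + 1)`, `x = R/(1+R)` and close
round trips to 1e-12.

## Numerical and design choices

* Fraction windows are integrated with the Gaussian CDF (no quadrature
  error); conservation holds to 1e-9 by construction and is tested at
  1e-9 over 1000 random communities.
* The measured `com_shift` of a fully labelled taxon converges to
  `(1 − smear)·Δmax` ≈ 0.0349 g/ml as fractionation is refined, because
  the smear component does not move; at 12 fractions the discretization
  error stays within one fraction width.
* Degenerate inputs fail loudly: empty communities, all-zero fraction
  profiles, non-monotone density columns, columns shallower than the
  rarefaction depth, filters that remove everything, and non-negative
  slope standard curves are all errors with named offenders.
* Ties in the heavy-side median fall to the lighter side
  (`density > median`), so a perfectly symmetric copy distribution yields
  at most half the fractions as "heavy".
* The demo design (3 soils × 2 treatments × 3 replicates × 12 fractions,
  50 shared taxa, guilds of 5 at 2–4% abundance each, weak 10 atom% vs
  strong 99 atom% timepoints) is the package's reference study: large
  enough for every mechanism to operate, small enough that the full
  operating-characteristic sweeps (200 null experiments, 200 recovery
  experiments, 50 demo re-seeds) run in a few minutes on one CPU.

## Known limitations

* Calls are binary; the package deliberately does not invert density
  shifts into per-taxon atom-fraction-excess estimates (qSIP-style), which
  requires per-fraction density calibration beyond this design.
* Index-based fraction alignment assumes comparable fraction windows
  across gradients; strong density miscalibration between runs would need
  the density-interpolation alignment that the current implementation does
  not provide.
* Cross-feeding (secondary labelling through metabolites or biomass
  turnover) is indistinguishable from primary assimilation by any
  single-timepoint screen, including this one.
* The smear fraction is a lumped nuisance parameter; real carry-over is
  probably heavier-tailed toward the load position than uniform.
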