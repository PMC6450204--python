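# Methods

This note records the models, numerical choices and known limitations of
`meles`, in the order the pipeline runs them.

## Study system emulated by the generator

`meles.simgen` produces a stand-in for a high-density, group-living badger
population under long-term trapping. Groups are points (main setts) on a
5×5 grid with 355 m spacing (the reported nearest-neighbour sett distance;
user coordinates may replace the grid). Demography is an annual cycle:
age-specific survival (cubs 0.65, prime adults 0.85, senescent decline),
female breeding probability 0.48 with mild density regulation toward a mean
group size of 6.4, litter sizes in {1, 2, 3} with probabilities
{0.6, 0.3, 0.1}, adult immigration at 0.2 individuals/group/year, birth sex
ratio 0.4 (male) so the adult sex ratio matches the ~0.4 the field data
show. The litter-size distribution is a convenience choice — only its mean
(≈ 1.5) is loosely constrained by assigned litters in real data.

**Sire choice.** Each cub's father is drawn by softmax over all eligible
males (alive and ≥ 1 year old in the conception year, i.e. 12 months before
birth — delayed implantation) with utility

    β·d + (u_dam + u_sire + m_g + p_h) · 1[extra-group],

where d is the sett distance from the natal group g to the candidate's
group h, u are per-individual excursion propensities (SD 0.5 by sex), and
(m_g, p_h) are per-group maternal-role/paternal-role effects drawn from a
2×2 covariance (default SD 0.5, correlation −0.6). The heterogeneity terms
act on extra-group candidacies only: a bonus applied uniformly to a male at
home and away cancels out of the softmax ratios and would generate no
paternal variance in paternity distance. β defaults to −0.007 per meter,
which at the default spacing and group size yields ≈ 37% extra-group
paternity — the rate the motivating study reports. One mechanism therefore
produces all the variance strata the downstream models estimate.

**Genotypes.** Founders and immigrants draw alleles from panel frequencies
under Hardy–Weinberg; offspring inherit one allele per parent per locus.
The default panel has 22 loci with 4–6 alleles each (Dirichlet frequencies
tuned to mean He ≈ 0.61, ≈ 4.85 alleles/locus).

**Observation.** Each individual-year is captured with per-sex probability
(defaults 0.65/0.70, within the reported quarterly ranges once annualized);
uncaptured animals have no genotype and become unsampled parents.
Immigrants are first caught as adults, so their ages are unknown downstream.

**What the generator does not emulate:** territory polygons (groups are
points), disease dynamics, age-dependent fecundity, real missing-data
patterns in historical genotyping batches, and non-equilibrium demography.
Passing tests show the *estimators* recover a truth of this structure; they
cannot validate the biological realism of any particular field system.

## Genotyping-error channel

Per locus, dropout then miscall. A true heterozygote (a, b) is observed as
(a, a) with probability e1, (b, b) with probability e1, unchanged otherwise
(so e1 < 0.5; homozygotes are unaffected). Each surviving allele is then
independently replaced with probability e2 by a draw from the panel
frequencies. This keeps the distribution over observable genotypes exactly
normalized — there is no both-alleles-dropped "missing" branch; missingness
is a separate process and a missing observation contributes likelihood 1.
All transition matrices are enumerated exactly, so the same algebra drives
simulation, the MCMC's transmission likelihoods, and the duplicate-based
maximum-likelihood estimation of (e1, e2) (grid search then bounded
quasi-Newton; a locus with no discordant duplicates reports 0 with a flag).
Note that duplicate data identify (e1, e2) only jointly: a het→homo
discordance can reflect dropout in one replicate or a false allele in the
other, so attribution depends on allele frequencies; recovery is unbiased
when the data are generated by the channel itself.

## Parentage sampler

Genotypes are fixed, so the multilocus transmission likelihood of every cub
× (dam, sire) pair — including the UNSAMPLED pseudo-candidate, whose
gametes are integrated over Hardy–Weinberg — is computed once and cached.
Each sweep then draws every cub's (dam, sire) pair *exactly* from its full
conditional (a categorical over the cached grid times the parentage prior),
which eliminates the slow mixing that alternating dam/sire updates would
suffer under full-sib structure and makes desk-scale schedules (tens of
thousands of iterations) behave like the canonical 2M/500k/100 schedule,
which retains exactly 15,000 samples.

Priors: dams uniform within the natal-group candidate list with UNSAMPLED
mass ∝ UD_g (one mass per social group; a cub with joint natal membership
uses its first-sorted group); sires ∝ exp(β·d) with UNSAMPLED mass
∝ US·exp(β·d̄) at the cub's mean candidate distance, which keeps β
identified when unsampled paternity is common. β ~ Normal(0, 0.1 per meter)
— effectively flat on the plausible range; US and UD_g are log-normal
(medians 10 and 1, log-SD 1). β, US and UD_g are updated by random-walk
Metropolis (log scale for the masses, with Jacobian), with proposal scales
adapted toward the 0.2–0.5 acceptance window during burn-in and frozen
afterwards. Lag-1 autocorrelations of β and US are logged, not gated on.

PD_c is recorded per retained iteration as the mean candidate distance over
cubs currently assigned a *sampled* sire (iterations with none contribute no
draw and are counted). This reads the joint-estimation definition literally:
pedigree and distance are sampled together, not sequentially. In
`use_distance=False` mode (the supported fallback for cohorts whose spatial
data break the distance model) β is fixed at 0 and no PD_c is produced.

Numerics: each cub's likelihood grid is rescaled to maximum 1 (the scale
cancels in every conditional) and entries below 1e-120 are zeroed — this
avoids subnormal-arithmetic slowdowns and cannot affect any posterior mass
a 15,000-draw chain could resolve. Candidates failing the
opposing-homozygote mismatch tolerance (default 1) are zeroed before
sampling.

## Cub metrics

EGP_i is derived from group identity, never from PD_i > 0: a father recorded
in the natal group and elsewhere makes the cub within-group (tie rule) with
PD_i = 0. For extra-group fathers with several memberships the minimum sett
distance is used — a conservative, documented guess, since the source
procedure is unstated. Parental body mass is the mean of birth-year
weighings; group size and sex ratio (males/(males+females) among resident
yearlings + adults) refer to the conception year. Residency is the modal
capture group of the year (ties keep all groups); the stricter
transient-exclusion criteria used on quarterly field data need multiple
captures per year, which annualized capture tables do not carry.

## Cohort regression

For each posterior draw index, ordinary least squares of PD_c across
cohorts on mean-centred population size, population sex ratio and year; the
2.5/97.5 percentiles of the resulting coefficient distributions are the 95%
credible intervals, and the centred design makes the intercept the
predicted PD_c at mean covariates. Draws are paired across cohorts by index
(chains are independent, so any pairing is valid; `shuffle_pairing`
probes this). The intervals propagate *assignment* uncertainty only: they
are calibrated when the per-cohort posteriors are themselves calibrated,
and anticonservative if cohort means vary beyond what the posteriors carry.

## Variance partition (REML)

The marginal covariance is assembled densely, V(θ) = Σ θ_k A_k, with A_k
the factor-sharing indicator matrices of Year, dam, sire, MSG, PSG, the
MSG×PSG cross term and the identity. The restricted log-likelihood is the
standard profile form (it matches lme4's REML logLik exactly on shared
models); gradients are analytic via tr(P A_k) − y'P A_k P y, making a
50-replicate recovery study at n = 600 a couple of minutes' work.
Parameters are optimized unconstrained — log-SDs, with the (MSG, PSG) pair
through its 2×2 Cholesky factor, so the implied covariance is positive
semi-definite by construction. Convergence: L-BFGS-B, ftol 1e-12, bounds
±(12, 8) on the log scale; optional dispersed restarts. Variances within
1e-6 of zero relative to the total are flagged as boundary estimates.

Choices that were genuinely open:

* **Gaussian working model for binary EGP_i and ln PD_i** — pragmatic, as
  it admits the explicit MSG–PSG covariance; a logistic mixed model is out
  of scope.
* **ln(0) offset**: PD_i = 0 for within-group cubs, so the response is
  ln(PD_i + δ) with δ = 1 m by default; δ = 10 is a supported sensitivity
  setting. Responses are then scaled to SD units.
* **ICC denominators** exclude the covariance term (variances only,
  residual included), so ICCs are nonnegative and sum to 1.
* **LRT df**: the number of constrained (co)variance parameters — 1 for a
  single variance or the covariance, 2 for a group role (variance +
  covariance) — ignoring boundary corrections; statistics are floored at 0.
  This is deliberately conservative, and the type-I error simulation
  confirms rejection at or below nominal rates.
* **Wald denominator df**: a Satterthwaite-type approximation,
  2·v̂²/Var(v̂), with Var(v̂) by the delta method from the observed
  information of the restricted likelihood; exact Kenward–Roger is out of
  scope and calibration is demonstrated by simulation instead.
* **r and slope from variance estimates**: r_MSG.PSG = COV/√(V_MSG·V_PSG)
  and slope = COV/V_MSG are computed from the estimated components, never by
  regressing BLUPs, which are shrunken.

A note on the generating values used in recovery tests: the published
ln-PD components (V_MSG = 0.39, V_PSG = 0.59, COV = −0.48) imply
r = −1.0006 — a rounding artifact, consistent with the reported r = −0.99
(± 0.03). The generator clips covariances within 1% of the PSD boundary to
the r = ±1 edge and rejects anything further out.

## Problem sizes

Defaults used by the test suite and the acceptance script: cohorts of
30–100 cubs, 6,000–50,000 MCMC iterations, REML studies of 12–50 replicates
at n = 150–600 cubs. These sizes give Monte-Carlo errors comfortably inside
every stated tolerance while keeping a full run on a single CPU short.

## Known limitations

* Unsampled-parent counts (US, UD_g) are estimated masses in a categorical
  prior, an approximation of how reference tools parameterize unsampled
  parents; their posteriors are diagnostics, not demographic estimates.
* Per-cohort chains ignore cross-cohort pedigree links (as in the source
  design); grandparental statistics are computed on the merged pedigree.
* The Gaussian EGP model can predict outside [0, 1]; only variance ratios
  and the covariance sign are interpreted.
* Capture–recapture abundance estimation is out of scope: population
  covariates come from the generator's truth or a user-supplied table.
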