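# meles

Bayesian parentage assignment, paternity distance and extra-group paternity
analysis for group-living mammal populations — modelled on long-term
trapping studies of high-density European badgers (*Meles meles*), where
social groups defend territories around communal setts and matings often
cross group boundaries ("breeding excursions").

## What it does

Neither parent of a badger cub can be observed directly, so parentage must
be reconstructed from error-prone microsatellite genotypes plus life-history
and spatial data. `meles` implements that inference chain end to end:

1. **Parentage MCMC** (`meles.parentage`). For each annual cub cohort, a
   Markov chain samples every cub's (dam, sire) pair jointly with a
   log-linear distance coefficient β on paternity and the numbers of
   unsampled parents (males per population, females per social group).
   Candidate mothers are females aged ≥ 2 resident in the cub's natal group;
   candidate fathers are males of any group alive and ≥ 1 year old twelve
   months before birth (delayed implantation). Genotyping error is handled
   with a per-locus dropout (e1) / false-allele (e2) channel, and candidates
   with more than one opposing-homozygote mismatch are excluded. Each
   retained iteration yields a draw of the cohort mean paternity distance
   PD_c = mean distance between each cub's natal sett and its (currently
   assigned) father's sett.
2. **Cub-level metrics** (`meles.pedmetrics`). Assignments exceeding a
   posterior-probability threshold (0.80, or 0.95 for a strict pedigree) are
   compiled into a validated pedigree, from which each cub gets a paternity
   distance PD_i and a binary extra-group paternity indicator EGP_i, with
   the within-group tie rule for fathers holding joint memberships.
3. **Cohort regression** (`meles.cohortreg`). PD_c is regressed on
   mean-centred population size, population sex ratio and year, refitting
   the OLS to every posterior draw so the 95% credible intervals propagate
   assignment uncertainty.
4. **Variance partition** (`meles.varpart`). ln(PD_i + δ) and EGP_i (in SD
   units, Gaussian working model) are decomposed with crossed random effects

   y = Xβ + u_Year + u_M + u_P + a_MSG + b_PSG + e,
   (a_g, b_g) ~ N(0, [[V_MSG, COV], [COV, V_PSG]]),

   where the same social group enters in maternal (MSG) and paternal (PSG)
   role. A custom dense REML engine with analytic gradients estimates the
   components; the sign of COV diagnoses source-sink gene flow (negative:
   groups that export paternity in one role import it in the other), with
   r = COV/√(V_MSG·V_PSG) and the source-sink slope COV/V_MSG. Intraclass
   correlations, likelihood-ratio tests (conservative df), conditional Wald
   F-tests (Satterthwaite-type denominator df) and per-group BLUPs round out
   the inference.
5. **Synthetic study system** (`meles.simgen`). The original data are a
   private long-term database, so the package ships a calibrated generator:
   ~25 groups at 355 m sett spacing, mean group size ≈ 6.4, adult sex ratio
   ≈ 0.4, 16–22 microsatellites with He ≈ 0.61, distance-decaying sire
   choice with individual and group heterogeneity, immigration and
   incomplete trapping. Every stage is tested against this ground truth.

## Worked example

```python
from meles.parentage import MCMCConfig, build_candidate_sets, run_mcmc, \
    summarize_assignments, pdc_posterior
from meles.pipeline import PipelineConfig, simulate_stage

cfg = PipelineConfig(seed=11)
sim = simulate_stage(cfg)            # synthetic captures, groups, genotypes
cands, _ = build_candidate_sets(
    sim["captures"], sim["truth"].groups, cohort_year=30,
    genotypes=sim["genotypes"],
)
chain = run_mcmc(cands, sim["genotypes"], sim["panel"],
                 MCMCConfig(n_iter=20_000, burn_in=5_000, thin=10, seed=1))
print(chain.n_retained)              # 1500  (= (20000 - 5000) / 10)
ped = summarize_assignments(chain, threshold=0.8)
print(ped["sire_id"].notna().mean()) # 1.0 -> every cub's father reaches 80%
p = pdc_posterior(chain)
print(round(p["mean"]), p["ci95"])   # 165 (155.2, 165.3) meters
```

`chain.n_retained` is the retained-sample count implied by the schedule (the
canonical 2,000,000 / 500,000 / 100 schedule retains exactly 15,000); the
assignment rate is the fraction of cubs whose modal father reaches 80%
posterior probability (1.0 here because this synthetic cohort is fully
sampled and genotyped at 22 low-error loci); the last line is the cohort
mean paternity distance with its 95% credible interval in meters, close to
the true realized mean of 170 m for this cohort.

The same pipeline is available from the shell:

```bash
meles pipeline --seed 11 --outdir run/
meles varpart --records run/cub_records.csv --response pd --out fit.json
```

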