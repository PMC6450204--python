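"""End-to-end orchestration: simulate -> assign -> metrics -> cohort
regression -> variance partition, with reproducibility manifests.

Every stage consumes the files (or in-memory objects) the previous stage
produced; any prefix of the chain is runnable.  All randomness derives from
one global seed, so a pipeline run is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohortreg import fit_posterior_regression
from .genepop import write_genepop
from .genetics import GenotypeTable, LocusPanel
from .parentage import (
    MCMCConfig,
    build_candidate_sets,
    pdc_posterior,
    run_mcmc,
    summarize_assignments,
)
from .pedmetrics import compile_pedigree, cub_metrics, pedigree_stats
from .simgen import (
    PopulationTruth,
    SimConfig,
    random_panel,
    simulate_genotypes,
    simulate_observation,
    simulate_population,
)
from .varpart import LmmSpec, fit_lmm, group_effects, icc, preprocess_response

logger = logging.getLogger(__name__)

MISSING_TOKEN = ""


@dataclass
class PipelineConfig:
    """Global configuration of a full synthetic-analysis run."""

    sim: SimConfig = field(default_factory=SimConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    n_cohorts: int = 5  # analyse the last n birth cohorts
    threshold: float = 0.8
    strict_threshold: float = 0.95
    delta: float = 1.0  # ln(PD + delta) offset, meters
    n_loci: int = 22
    genotyping_e1: float = 0.01
    genotyping_e2: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.threshold, self.strict_threshold):
            if not (0.5 < t <= 1.0):
                raise ValueError(f"assignment threshold {t} outside (0.5, 1]")
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")


def population_covariates(truth: PopulationTruth) -> pd.DataFrame:
    """True per-year adult population size and sex ratio from the simulation.

    Stands in for mark-recapture abundance estimates: the generator knows the
    true adult counts, so no capture-recapture model is needed here.
    """
    rows = []
    for year in range(1, truth.config.n_years + 1):
        alive = truth.alive_in(year)
        adults = alive[alive["birth_year"] <= year - 1]
        n = len(adults)
        males = int((adults["sex"] == "M").sum())
        rows.append(
            {
                "cohort_year": year,
                "population_size": n,
                "population_sex_ratio": males / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def simulate_stage(config: PipelineConfig) -> dict:
    """Generate population truth, genotypes and the capture table."""
    truth = simulate_population(config.sim)
    panel = random_panel(
        n_loci=config.n_loci,
        seed=config.seed + 1,
        e1=config.genotyping_e1,
        e2=config.genotyping_e2,
    )
    true_gt, obs_gt = simulate_genotypes(
        truth, panel, seed=config.seed + 2, missing_rate=config.missing_rate
    )
    captures = simulate_observation(truth, config.sim, seed=config.seed + 3)
    sampled = sorted(captures["id"].unique())
    genotypes = obs_gt.subset(sampled)  # never-captured animals leave no genotype
    return {
        "truth": truth,
        "panel": panel,
        "true_genotypes": true_gt,
        "genotypes": genotypes,
        "captures": captures,
        "covariates": population_covariates(truth),
    }


def assign_stage(
    captures: pd.DataFrame,
    groups: pd.DataFrame,
    genotypes: GenotypeTable,
    panel: LocusPanel,
    cohort_years: list[int],
    mcmc: MCMCConfig,
    threshold: float = 0.8,
    seed: int = 0,
) -> dict:
    """Run the parentage sampler for each cohort and threshold the posteriors."""
    chains, assignments, pdc = {}, [], {}
    for k, year in enumerate(cohort_years):
        cands, excluded = build_candidate_sets(
            captures, groups, year, genotypes=genotypes, use_distance=mcmc.use_distance
        )
        if not cands:
            logger.warning("cohort %s: no eligible cubs", year)
            continue
        cfg = dataclasses.replace(mcmc, seed=seed + 1000 + k)
        chain = run_mcmc(cands, genotypes, panel, cfg)
        chains[year] = chain
        assignments.append(summarize_assignments(chain, threshold))
        if chain.pdc is not None:
            pdc[year] = pdc_posterior(chain)
    merged = (
        pd.concat(assignments, ignore_index=True)
        if assignments
        else pd.DataFrame(columns=["cub_id", "dam_id", "dam_prob", "sire_id", "sire_prob", "cohort"])
    )
    return {"chains": chains, "assignments": merged, "pdc": pdc}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full chain on synthetic data and return the report bundle."""
    out: Path | None = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    sim = simulate_stage(config)
    truth, captures, groups = sim["truth"], sim["captures"], sim["truth"].groups
    last = config.sim.n_years
    cohort_years = list(range(last - config.n_cohorts + 1, last + 1))

    assigned = assign_stage(
        captures,
        groups,
        sim["genotypes"],
        sim["panel"],
        cohort_years,
        config.mcmc,
        threshold=config.threshold,
        seed=config.seed,
    )
    pedigree = compile_pedigree(assigned["assignments"])
    records = cub_metrics(pedigree, captures, groups)
    stats = pedigree_stats(
        pedigree, egp=records.set_index("cub_id")["egp_i"] if len(records) else None
    )

    report: dict = {
        "simulate": {
            "n_individuals": int(len(truth.individuals)),
            "n_cubs_true": int(len(truth.pedigree)),
            "true_egp_rate": truth.egp_rate(),
            "n_groups": int(len(groups)),
        },
        "assign": {
            str(y): {
                "n_cubs": len(c.cub_ids),
                "beta_mean": float(c.beta.mean()),
                "beta_accept": c.diagnostics.get("beta_accept"),
                "us_accept": c.diagnostics.get("us_accept"),
            }
            for y, c in assigned["chains"].items()
        },
        "pedigree_stats": stats,
    }

    if len(assigned["pdc"]) >= 4:
        draws = {y: p["draws"] for y, p in assigned["pdc"].items()}
        m = min(len(d) for d in draws.values())
        reg = fit_posterior_regression(
            {y: d[:m] for y, d in draws.items()},
            sim["covariates"][sim["covariates"]["cohort_year"].isin(draws)],
        )
        report["cohortreg"] = reg.summary.to_dict(orient="records")
    else:
        report["cohortreg"] = None

    report["varpart"] = {}
    for resp in ("pd", "egp"):
        try:
            model_data = preprocess_response(records, response=resp, delta=config.delta)
            spec = LmmSpec(fixed=_usable_fixed(model_data))
            fit = fit_lmm(model_data, spec, compute_se=True)
            ge = group_effects(fit)
            report["varpart"][resp] = {
                "n": fit.n,
                "components": fit.components,
                "component_se": fit.component_se,
                "icc": icc(fit),
                "r_msg_psg": fit.r_msg_psg,
                "slope": fit.source_sink_slope,
                "converged": fit.converged,
            }
            if out is not None:
                ge["blups"].to_csv(out / f"blups_{resp}.csv", index=False)
        except Exception as exc:  # noqa: BLE001 -- partial outputs are retained
            logger.warning("variance partition for %s failed: %s", resp, exc)
            report["varpart"][resp] = {"error": str(exc)}

    if out is not None:
        _write_outputs(out, config, sim, assigned, pedigree, records, stats, report)
    return report


def _usable_fixed(model_data: pd.DataFrame) -> tuple[str, ...]:
    """Fixed covariates with enough complete rows to be estimable."""
    from .simgen import FIXED_COVARIATES

    candidates = [c for c in FIXED_COVARIATES if c in model_data.columns]
    keep = [c for c in candidates if model_data[c].notna().mean() > 0.7]
    sub = model_data.dropna(subset=keep + ["response"])
    if len(sub) < 5 * (len(keep) + 2):
        keep = []
    return tuple(keep)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["group_effect_cov"] = np.asarray(d["sim"]["group_effect_cov"]).tolist()
    if d["sim"]["sett_coords"] is not None:
        d["sim"]["sett_coords"] = np.asarray(d["sim"]["sett_coords"]).tolist()
    d["sim"]["sigma_individual"] = list(d["sim"]["sigma_individual"])
    d["sim"]["litter_size_dist"] = {str(k): v for k, v in d["sim"]["litter_size_dist"].items()}
    d["mcmc"]["target_accept"] = list(d["mcmc"]["target_accept"])
    return d


def _write_outputs(out, config, sim, assigned, pedigree, records, stats, report) -> None:
    truth: PopulationTruth = sim["truth"]
    sim["captures"].to_csv(out / "captures.csv", index=False)
    truth.groups.to_csv(out / "groups.csv", index=False)
    truth.pedigree[["cub", "dam", "sire"]].to_csv(out / "truth_pedigree.csv", index=False)
    sim["covariates"].to_csv(out / "covariates.csv", index=False)
    sim["genotypes"].to_wide_csv(out / "genotypes.csv")
    write_genepop(sim["genotypes"], out / "genotypes.gen")
    sim["panel"].to_csv(out / "panel.csv")
    pedigree.to_csv(out / "pedigree.csv", index=False, na_rep=MISSING_TOKEN)
    records.to_csv(out / "cub_records.csv", index=False, na_rep=MISSING_TOKEN)
    pdc_rows = []
    for year, p in assigned["pdc"].items():
        for v in p["draws"]:
            pdc_rows.append({"cohort_year": year, "pdc": v})
    pd.DataFrame(pdc_rows, columns=["cohort_year", "pdc"]).to_csv(
        out / "pdc_draws.csv", index=False
    )
    (out / "stats.json").write_text(json.dumps(stats, indent=2, default=_jsonable))
    cfg = _config_dict(config)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
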