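"""Joint Bayesian parentage assignment with a spatial paternity predictor.

For each annual cub cohort, a Markov chain samples per-cub (dam, sire)
assignments jointly with a log-linear distance coefficient ``beta`` on
paternity and with the numbers of unsampled candidate parents (males per
population, females per social group).  Candidate parents obey life-history
rules: candidate mothers are females aged >= 2 resident in the cub's natal
group in the birth year; candidate fathers are males of any group alive and
>= 1 year old twelve months before birth (delayed implantation).

The sampler alternates
  (i)  an exact joint categorical draw of each cub's (dam, sire) pair from
       cached multilocus transmission likelihoods times the parentage prior,
  (ii) random-walk Metropolis updates of beta, and
  (iii) Metropolis updates of the unsampled-parent masses,
with proposal scales adapted to a target acceptance window during burn-in and
frozen thereafter.  Because genotypes are fixed, all transmission likelihoods
are precomputed once, so desk-scale schedules mix as well per iteration as
the canonical 2-million-iteration schedule.

Per retained iteration the cohort mean paternity distance ``PD_c`` (mean sett
distance over cubs currently assigned a sampled sire) is recorded, giving the
posterior that downstream cohort regressions propagate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import GenotypeTable, LocusPanel, mismatch_count

logger = logging.getLogger(__name__)

UNSAMPLED = "UNSAMPLED"


# ---------------------------------------------------------------------------
# life-history rules and candidate sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateRules:
    """Eligibility rules for candidate parents."""

    dam_min_age: int = 2
    sire_min_age_at_conception: int = 1
    grace_cub: int = 1  # years presumed alive after last capture as a cub
    grace_adult: int = 3  # ... after last capture otherwise
    assumed_age_adult_first_capture: int = 2


@dataclass
class LifeHistory:
    """Per-individual life-history facts derived from the capture table."""

    table: pd.DataFrame  # id, sex, birth_year, age_known, first_year, last_year, alive_until
    memberships: dict[tuple[str, int], frozenset[str]]

    def groups_of(self, ind: str, year: int) -> frozenset[str]:
        return self.memberships.get((ind, year), frozenset())


_AGE_AT_FIRST = {"cub": 0, "yearling": 1, "adult": 2}


def derive_life_history(
    captures: pd.DataFrame, rules: CandidateRules = CandidateRules()
) -> LifeHistory:
    """Derive birth years, presumed-alive windows and yearly group memberships.

    Unknown-age adults are assumed to be ``rules.assumed_age_adult_first_capture``
    years old at first capture.  After the last capture, individuals are
    presumed alive for 1 further year if last seen as a cub, else 3 years.
    In years without captures inside the alive window, the previous year's
    group membership is carried forward.
    """
    required = {"id", "year", "group", "sex", "age_class"}
    missing = required - set(captures.columns)
    if missing:
        raise ValueError(f"capture table lacks columns {sorted(missing)}")

    rows = []
    memberships: dict[tuple[str, int], frozenset[str]] = {}
    for ind, grp in captures.groupby("id", sort=False):
        sexes = grp["sex"].dropna().unique()
        sex = sexes[0] if len(sexes) == 1 else None
        first_year = int(grp["year"].min())
        last_year = int(grp["year"].max())
        first_rows = grp[grp["year"] == first_year]
        ages = [_AGE_AT_FIRST.get(a, 2) for a in first_rows["age_class"]]
        first_age = min(ages)
        age_known = first_age <= 1
        if age_known:
            birth_year = first_year - first_age
        else:
            birth_year = first_year - rules.assumed_age_adult_first_capture
        last_rows = grp[grp["year"] == last_year]
        last_as_cub = all(a == "cub" for a in last_rows["age_class"])
        grace = rules.grace_cub if last_as_cub else rules.grace_adult
        alive_until = last_year + grace
        rows.append(
            {
                "id": str(ind),
                "sex": sex,
                "birth_year": birth_year,
                "age_known": age_known,
                "first_year": first_year,
                "last_year": last_year,
                "alive_until": alive_until,
            }
        )
        seen = {
            int(y): frozenset(sub["group"].dropna().astype(str))
            for y, sub in grp.groupby("year")
        }
        current: frozenset[str] = frozenset()
        for year in range(first_year, alive_until + 1):
            if year in seen and seen[year]:
                current = seen[year]
            memberships[(str(ind), year)] = current
    return LifeHistory(pd.DataFrame(rows).set_index("id", drop=False), memberships)


@dataclass
class CandidateSet:
    """Candidate parents for one cub."""

    cub_id: str
    cohort_year: int
    natal_groups: frozenset[str]
    dams: list[str]
    sires: list[str]
    sire_distances: np.ndarray  # meters, aligned with `sires`
    no_distance: bool = False

    def __post_init__(self) -> None:
        self.sire_distances = np.asarray(self.sire_distances, dtype=float)
        if np.any(self.sire_distances < 0):
            raise ValueError(f"cub {self.cub_id}: negative sire distance")


def build_candidate_sets(
    captures: pd.DataFrame,
    groups: pd.DataFrame,
    cohort_year: int,
    genotypes: GenotypeTable | None = None,
    rules: CandidateRules = CandidateRules(),
    use_distance: bool = True,
) -> tuple[list[CandidateSet], pd.DataFrame]:
    """Apply the life-history rules to one cohort.

    Offspring are individuals of known birth year equal to ``cohort_year``
    (first caught as cubs or yearlings).  Candidates without genotypes are
    folded into the unsampled-parent category, i.e. dropped from the explicit
    lists.  Returns the candidate sets and a log of excluded offspring.
    """
    lh = derive_life_history(captures, rules)
    tab = lh.table
    sett = {str(r.group_id): (float(r.x), float(r.y)) for r in groups.itertuples()}

    def dist(g1: str, g2: str) -> float:
        (x1, y1), (x2, y2) = sett[g1], sett[g2]
        return math.hypot(x1 - x2, y1 - y2)

    y = cohort_year
    # candidate dams: females aged >=2 in birth year, alive, in natal group
    dams_all = tab[
        (tab["sex"] == "F")
        & (tab["birth_year"] <= y - rules.dam_min_age)
        & (tab["first_year"] <= y)
        & (tab["alive_until"] >= y)
    ]
    # candidate sires: males alive and >=1 year old 12 months before birth
    sires_all = tab[
        (tab["sex"] == "M")
        & (tab["birth_year"] <= y - 1 - rules.sire_min_age_at_conception)
        & (tab["first_year"] <= y + 1)
        & (tab["alive_until"] >= y - 1)
    ]

    def genotyped(ind: str) -> bool:
        return genotypes is None or ind in genotypes

    sire_ids = [s for s in sires_all["id"] if genotyped(s)]
    sire_groups: dict[str, frozenset[str]] = {}
    for s in sire_ids:
        gs = lh.groups_of(s, y - 1) or lh.groups_of(s, y)
        sire_groups[s] = frozenset(g for g in gs if g in sett)

    offspring = tab[(tab["birth_year"] == y) & tab["age_known"]]
    out: list[CandidateSet] = []
    excluded: list[dict] = []
    for r in offspring.itertuples():
        cub = r.id
        if r.sex is None:
            excluded.append({"cub_id": cub, "reason": "missing sex"})
            continue
        if genotypes is not None and cub not in genotypes:
            excluded.append({"cub_id": cub, "reason": "not genotyped"})
            continue
        natal = frozenset(g for g in lh.groups_of(cub, r.first_year) if g in sett)
        if not natal:
            excluded.append({"cub_id": cub, "reason": "no natal group"})
            continue
        dams = [
            d
            for d in dams_all["id"]
            if d != cub and genotyped(d) and (lh.groups_of(d, y) & natal)
        ]
        sires, d_m = [], []
        for s in sire_ids:
            if s == cub:
                continue
            sg = sire_groups[s]
            if not sg:
                continue
            sires.append(s)
            d_m.append(min(dist(ng, g) for ng in natal for g in sg))
        out.append(
            CandidateSet(
                cub_id=cub,
                cohort_year=y,
                natal_groups=natal,
                dams=dams,
                sires=sires,
                sire_distances=np.array(d_m),
                no_distance=not use_distance,
            )
        )
    for e in excluded:
        logger.info("cohort %s: excluded %s (%s)", y, e["cub_id"], e["reason"])
    return out, pd.DataFrame(excluded, columns=["cub_id", "reason"])


# ---------------------------------------------------------------------------
# MCMC configuration and chain containers
# ---------------------------------------------------------------------------


@dataclass
class MCMCConfig:
    """Schedule, priors and proposal settings for the parentage sampler."""

    n_iter: int = 2_000_000
    burn_in: int = 500_000
    thin: int = 100
    mismatch_tolerance: int = 1
    use_distance: bool = True
    beta_prior_sd: float = 0.1  # per meter; effectively weakly informative
    beta_prop_scale: float = 0.002
    us_prior_log_median: float = math.log(10.0)
    us_prior_log_sd: float = 1.0
    ud_prior_log_median: float = math.log(1.0)
    ud_prior_log_sd: float = 1.0
    prop_scale_us: float = 0.4
    prop_scale_ud: float = 0.6
    target_accept: tuple[float, float] = (0.2, 0.5)
    adapt_interval: int = 200
    seed: int = 0
    # fixing hyperparameters turns off their updates (diagnostics / oracles)
    fixed_beta: float | None = None
    fixed_us: float | None = None
    fixed_ud: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_retained == 0:
            raise ValueError("schedule retains no samples")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def retention_iterations(n_iter: int, burn_in: int, thin: int) -> np.ndarray:
    """Post-burn-in iteration numbers at which states are retained."""
    return np.arange(burn_in + thin, n_iter + 1, thin)


@dataclass
class PosteriorChain:
    """Retained MCMC samples for one cohort."""

    cohort_year: int
    cub_ids: list[str]
    dam_lists: list[list[str]]  # per cub; index 0 in samples = UNSAMPLED
    sire_list: list[str]  # shared across cubs; index 0 = UNSAMPLED
    sire_distances: np.ndarray  # (n_cubs, n_sires)
    dam_samples: np.ndarray  # (n_ret, n_cubs) int16
    sire_samples: np.ndarray  # (n_ret, n_cubs) int16
    beta: np.ndarray  # (n_ret,)
    us: np.ndarray
    ud: np.ndarray  # (n_ret, n_groups)
    group_ids: list[str]
    pdc: np.ndarray | None  # (n_ret,), NaN where no sampled-sire cub
    diagnostics: dict = field(default_factory=dict)
    config: MCMCConfig | None = None

    @property
    def n_retained(self) -> int:
        return self.dam_samples.shape[0]

    def posterior_probs(self, cub_index: int, role: str) -> dict[str, float]:
        """Posterior assignment probabilities over candidates plus UNSAMPLED."""
        if role == "dam":
            samples = self.dam_samples[:, cub_index]
            labels = [UNSAMPLED] + self.dam_lists[cub_index]
        elif role == "sire":
            samples = self.sire_samples[:, cub_index]
            labels = [UNSAMPLED] + self.sire_list
        else:
            raise ValueError("role must be 'dam' or 'sire'")
        counts = np.bincount(samples, minlength=len(labels))
        return {lab: c / len(samples) for lab, c in zip(labels, counts)}

    def lag1_autocorrelation(self) -> dict[str, float]:
        out = {}
        for name, series in [("beta", self.beta), ("us", self.us)]:
            x = series - series.mean()
            denom = float(x @ x)
            out[name] = float(x[:-1] @ x[1:]) / denom if denom > 0 else 0.0
        return out


# ---------------------------------------------------------------------------
# likelihood grids
# ---------------------------------------------------------------------------


def _encode_genotypes(
    ind: str | None, genotypes: GenotypeTable, panel: LocusPanel
) -> np.ndarray:
    """Per-locus extended genotype codes; the marginal (unsampled) slot for missing."""
    codes = np.empty(len(panel), dtype=np.int64)
    for k, locus in enumerate(panel):
        marg = len(locus.genotypes)
        if ind is None:
            codes[k] = marg
            continue
        gt = genotypes.get(ind, locus.name)
        codes[k] = marg if gt is None else locus.encode(gt)
    return codes


def _extended_obs_like(locus) -> np.ndarray:
    """OLe[d, s, o] with an extra 'marginalized parent' index on both axes."""
    ng = len(locus.genotypes)
    ole = np.empty((ng + 1, ng + 1, ng))
    ole[:ng, :ng, :] = locus.obs_like
    ole[ng, :ng, :] = locus.obs_like_one
    ole[:ng, ng, :] = locus.obs_like_one
    ole[ng, ng, :] = locus.obs_like_none
    return ole


def build_likelihood_grids(
    candidates: list[CandidateSet],
    genotypes: GenotypeTable,
    panel: LocusPanel,
    mismatch_tolerance: int = 1,
) -> tuple[list[np.ndarray], list[list[str]], list[str]]:
    """Cache P(cub genotype | dam, sire) over every (dam, sire) pair per cub.

    Returns ``(grids, dam_lists, sire_list)`` where ``grids[i][a, b]`` is the
    multilocus transmission likelihood for cub i with dam index a and sire
    index b (index 0 = UNSAMPLED on both axes).  Candidates exceeding the
    opposing-homozygote mismatch tolerance against the cub are zeroed out
    (pre-excluded).  Each grid is rescaled to max 1 -- the absolute scale
    cancels in every sampler conditional.
    """
    sire_list = list(candidates[0].sires) if candidates else []
    for cs in candidates:
        if list(cs.sires) != sire_list:
            raise ValueError("all cubs in a cohort must share the candidate sire list")
    oles = [_extended_obs_like(locus) for locus in panel]
    sire_codes = np.stack(
        [_encode_genotypes(None, genotypes, panel)]
        + [_encode_genotypes(s, genotypes, panel) for s in sire_list]
    )  # (S+1, n_loci)
    dam_lists = [cs.dams for cs in candidates]
    n_s = len(sire_list)
    grids: list[np.ndarray] = []
    for cs in candidates:
        cub_codes = _encode_genotypes(cs.cub_id, genotypes, panel)
        dam_codes = np.stack(
            [_encode_genotypes(None, genotypes, panel)]
            + [_encode_genotypes(d, genotypes, panel) for d in cs.dams]
        )
        nd = len(cs.dams)
        grid = np.ones((nd + 1, n_s + 1))
        for k, locus in enumerate(panel):
            o = cub_codes[k]
            if o >= len(locus.genotypes):  # cub missing at this locus
                continue
            grid *= oles[k][dam_codes[:, k][:, None], sire_codes[:, k][None, :], o]
        # mismatch-tolerance pre-exclusion
        cub_gt = genotypes.genotypes_of(cs.cub_id)
        for a, d in enumerate(cs.dams, start=1):
            if mismatch_count(cub_gt, genotypes.genotypes_of(d)) > mismatch_tolerance:
                grid[a, :] = 0.0
        for b, s in enumerate(sire_list, start=1):
            if mismatch_count(cub_gt, genotypes.genotypes_of(s)) > mismatch_tolerance:
                grid[:, b] = 0.0
        top = grid.max()
        if top > 0:
            grid /= top
            grid[grid < 1e-120] = 0.0
        grids.append(grid)
    return grids, dam_lists, sire_list


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _Adaptive:
    """Robbins-Monro-free window adaptation of a random-walk proposal scale."""

    def __init__(self, scale: float, window: tuple[float, float]):
        self.scale = scale
        self.lo, self.hi = window
        self.accepts = 0
        self.trials = 0

    def record(self, accepted: bool) -> None:
        self.trials += 1
        self.accepts += accepted

    def maybe_adapt(self) -> None:
        if self.trials == 0:
            return
        rate = self.accepts / self.trials
        if rate > self.hi:
            self.scale *= 1.4
        elif rate < self.lo:
            self.scale *= 0.7
        self.accepts = 0
        self.trials = 0


def run_mcmc(
    candidates: list[CandidateSet],
    genotypes: GenotypeTable,
    panel: LocusPanel,
    config: MCMCConfig = MCMCConfig(),
) -> PosteriorChain:
    """Run the per-cohort joint parentage sampler.

    See the module docstring for the update scheme.  With
    ``config.use_distance`` false the distance predictor is dropped (beta
    fixed at 0 and no ``PD_c`` posterior is produced) -- the supported
    fallback for cohorts whose spatial data break the distance model.
    """
    if not candidates:
        raise ValueError("no candidate sets supplied")
    rng = np.random.default_rng(config.seed)
    cohort = candidates[0].cohort_year
    use_dist = config.use_distance and not any(cs.no_distance for cs in candidates)

    grids, dam_lists, sire_list = build_likelihood_grids(
        candidates, genotypes, panel, config.mismatch_tolerance
    )
    n_cubs = len(grids)
    n_s = len(sire_list)
    n_s1 = n_s + 1
    bad = [candidates[i].cub_id for i, g in enumerate(grids) if not g.max() > 0]
    if bad:
        raise ValueError(f"non-finite/zero likelihood for cubs {bad}")

    # distances: column 0 carries the per-cub mean candidate distance, which
    # anchors the unsampled-sire mass on the distance scale and keeps beta
    # identified when unsampled paternity is common
    dmat = np.zeros((n_cubs, n_s1))
    for i, cs in enumerate(candidates):
        if n_s:
            dmat[i, 1:] = cs.sire_distances
            dmat[i, 0] = cs.sire_distances.mean() if len(cs.sire_distances) else 0.0

    # packed ragged layout: cub i's (dams+1) x (sires+1) grid flattened
    # row-major into one array, with segmented-cumsum categorical sampling
    sizes = np.array([g.size for g in grids])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    ends = np.cumsum(sizes)
    Lp = np.concatenate([g.ravel() for g in grids])
    elem_cub = np.repeat(np.arange(n_cubs), sizes)
    elem_sire = np.concatenate(
        [np.tile(np.arange(n_s1), g.shape[0]) for g in grids]
    ).astype(np.int64)
    elem_flat_sp = elem_cub * n_s1 + elem_sire  # gather index into sp.ravel()
    dam0_mask = np.concatenate(
        [np.arange(g.size) < n_s1 for g in grids]
    )  # elements in the UNSAMPLED-dam row
    dam0_pos = np.where(dam0_mask)[0]

    group_ids = sorted({min(cs.natal_groups) for cs in candidates})
    gindex = {g: k for k, g in enumerate(group_ids)}
    cub_group = np.array([gindex[min(cs.natal_groups)] for cs in candidates])
    n_groups = len(group_ids)
    n_dams = np.array([len(dl) for dl in dam_lists], dtype=float)

    # state
    beta = config.fixed_beta if config.fixed_beta is not None else 0.0
    if not use_dist:
        beta = 0.0
    us = config.fixed_us if config.fixed_us is not None else 5.0
    ud = np.full(n_groups, config.fixed_ud if config.fixed_ud is not None else 0.5)
    update_beta = use_dist and config.fixed_beta is None
    update_us = config.fixed_us is None
    update_ud = config.fixed_ud is None

    retained = retention_iterations(config.n_iter, config.burn_in, config.thin)
    n_ret = len(retained)
    dam_samples = np.zeros((n_ret, n_cubs), dtype=np.int16)
    sire_samples = np.zeros((n_ret, n_cubs), dtype=np.int16)
    beta_tr = np.zeros(n_ret)
    us_tr = np.zeros(n_ret)
    ud_tr = np.zeros((n_ret, n_groups))
    pdc_tr = np.full(n_ret, np.nan) if use_dist else None

    ad_beta = _Adaptive(config.beta_prop_scale, config.target_accept)
    ad_us = _Adaptive(config.prop_scale_us, config.target_accept)
    ad_ud = _Adaptive(config.prop_scale_ud, config.target_accept)
    post_accept = {"beta": [0, 0], "us": [0, 0]}

    lp_beta = lambda b: -0.5 * (b / config.beta_prior_sd) ** 2
    lp_us = lambda u: -0.5 * ((math.log(u) - config.us_prior_log_median) / config.us_prior_log_sd) ** 2
    def lp_ud(u: np.ndarray) -> np.ndarray:
        return -0.5 * ((np.log(u) - config.ud_prior_log_median) / config.ud_prior_log_sd) ** 2

    ret_ptr = 0
    arange_cubs = np.arange(n_cubs)
    dam0_cub_group = cub_group[elem_cub[dam0_pos]]
    Eb = np.exp(beta * dmat)  # col 0 = exp(beta * mean candidate distance)
    for it in range(1, config.n_iter + 1):
        in_burn = it <= config.burn_in

        # (i) joint (dam, sire) draw per cub -- exact conditional
        sp = Eb.copy()
        sp[:, 0] *= us
        W = Lp * sp.ravel()[elem_flat_sp]
        W[dam0_pos] *= ud[dam0_cub_group]
        cs_all = np.cumsum(W)
        base = np.concatenate([[0.0], cs_all[ends[:-1] - 1]])
        tot = cs_all[ends - 1] - base
        targets = base + rng.random(n_cubs) * tot
        pos = np.searchsorted(cs_all, targets, side="left")
        pos = np.minimum(pos, ends - 1)
        local = pos - starts
        dam_idx = local // n_s1
        sire_idx = local % n_s1

        # log-prior likelihood of the current sire draws given (beta, us):
        # sum_i [beta * d_i(s_i) + 1(s_i = U) log us] - sum_i log Z_i
        d_sel = float(dmat[arange_cubs, sire_idx].sum())
        n_uns_sires = int((sire_idx == 0).sum())
        rowsum_sampled = Eb[:, 1:].sum(axis=1)

        def sire_ll(b: float, usv: float, E: np.ndarray, rs: np.ndarray, dsel: float) -> float:
            Z = rs + usv * E[:, 0]
            return b * dsel + n_uns_sires * math.log(usv) - float(np.log(Z).sum())

        # (ii) beta update (random-walk Metropolis)
        if update_beta:
            cur = sire_ll(beta, us, Eb, rowsum_sampled, d_sel) + lp_beta(beta)
            prop = beta + rng.normal(0, ad_beta.scale)
            Ep = np.exp(prop * dmat)
            new = sire_ll(prop, us, Ep, Ep[:, 1:].sum(axis=1), d_sel) + lp_beta(prop)
            acc = math.log(rng.random()) < new - cur
            if acc:
                beta = prop
                Eb = Ep
                rowsum_sampled = Ep[:, 1:].sum(axis=1)
            if in_burn:
                ad_beta.record(acc)
                if it % config.adapt_interval == 0:
                    ad_beta.maybe_adapt()
            else:
                post_accept["beta"][0] += acc
                post_accept["beta"][1] += 1

        # (iii) unsampled-sire mass (log-scale random walk, Jacobian included)
        if update_us:
            cur = sire_ll(beta, us, Eb, rowsum_sampled, d_sel) + lp_us(us)
            prop = us * math.exp(rng.normal(0, ad_us.scale))
            new = sire_ll(beta, prop, Eb, rowsum_sampled, d_sel) + lp_us(prop)
            acc = math.log(rng.random()) < (new + math.log(prop)) - (cur + math.log(us))
            if acc:
                us = prop
            if in_burn:
                ad_us.record(acc)
                if it % config.adapt_interval == 0:
                    ad_us.maybe_adapt()
            else:
                post_accept["us"][0] += acc
                post_accept["us"][1] += 1

        if update_ud:
            n_uns = np.bincount(
                cub_group[dam_idx == 0], minlength=n_groups
            ).astype(float)
            n_per_group = np.bincount(cub_group, minlength=n_groups).astype(float)
            denom_cur = np.log(n_dams + ud[cub_group])
            sum_denom_cur = np.bincount(cub_group, weights=denom_cur, minlength=n_groups)
            prop = ud * np.exp(rng.normal(0, ad_ud.scale, n_groups))
            denom_prop = np.log(n_dams + prop[cub_group])
            sum_denom_prop = np.bincount(cub_group, weights=denom_prop, minlength=n_groups)
            ll_cur = n_uns * np.log(ud) - sum_denom_cur + lp_ud(ud) + np.log(ud)
            ll_prop = n_uns * np.log(prop) - sum_denom_prop + lp_ud(prop) + np.log(prop)
            acc_vec = np.log(rng.random(n_groups)) < ll_prop - ll_cur
            ud = np.where(acc_vec, prop, ud)
            if in_burn:
                ad_ud.record(bool(acc_vec.mean() > 0.5))
                if it % config.adapt_interval == 0:
                    ad_ud.maybe_adapt()

        # retention
        if ret_ptr < n_ret and it == retained[ret_ptr]:
            dam_samples[ret_ptr] = dam_idx
            sire_samples[ret_ptr] = sire_idx
            beta_tr[ret_ptr] = beta
            us_tr[ret_ptr] = us
            ud_tr[ret_ptr] = ud
            if use_dist:
                sampled = sire_idx > 0
                if sampled.any():
                    pdc_tr[ret_ptr] = dmat[np.arange(n_cubs), sire_idx][sampled].mean()
            ret_ptr += 1

    diag = {
        "beta_accept": (
            post_accept["beta"][0] / post_accept["beta"][1]
            if post_accept["beta"][1]
            else None
        ),
        "us_accept": (
            post_accept["us"][0] / post_accept["us"][1] if post_accept["us"][1] else None
        ),
        "beta_prop_scale": ad_beta.scale,
        "use_distance": use_dist,
    }
    chain = PosteriorChain(
        cohort_year=cohort,
        cub_ids=[cs.cub_id for cs in candidates],
        dam_lists=dam_lists,
        sire_list=sire_list,
        sire_distances=dmat[:, 1:],
        dam_samples=dam_samples,
        sire_samples=sire_samples,
        beta=beta_tr,
        us=us_tr,
        ud=ud_tr,
        group_ids=group_ids,
        pdc=pdc_tr,
        diagnostics=diag,
        config=config,
    )
    chain.diagnostics.update({"lag1": chain.lag1_autocorrelation()})
    return chain


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def summarize_assignments(chain: PosteriorChain, threshold: float = 0.8) -> pd.DataFrame:
    """Threshold the per-cub assignment posteriors into a pedigree table.

    A parent is assigned when the modal candidate is sampled (not UNSAMPLED)
    and its posterior probability is at least ``threshold``.  Columns:
    cub_id, dam_id, dam_prob, sire_id, sire_prob, cohort.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    rows = []
    for i, cub in enumerate(chain.cub_ids):
        rec: dict[str, object] = {"cub_id": cub, "cohort": chain.cohort_year}
        for role in ("dam", "sire"):
            probs = chain.posterior_probs(i, role)
            modal, p = max(probs.items(), key=lambda kv: kv[1])
            if modal != UNSAMPLED and p >= threshold:
                rec[f"{role}_id"] = modal
                rec[f"{role}_prob"] = p
            else:
                rec[f"{role}_id"] = None
                rec[f"{role}_prob"] = p
        rows.append(rec)
    return pd.DataFrame(
        rows, columns=["cub_id", "dam_id", "dam_prob", "sire_id", "sire_prob", "cohort"]
    )


def pdc_posterior(chain: PosteriorChain) -> dict:
    """Cohort mean paternity-distance posterior: draws, mean and 95% interval.

    Iterations in which no cub was assigned a sampled sire contribute no draw
    (their count is reported).
    """
    if chain.pdc is None:
        raise ValueError("chain was run without the distance predictor")
    draws = chain.pdc[~np.isnan(chain.pdc)]
    dropped = int(np.isnan(chain.pdc).sum())
    if dropped:
        logger.info("cohort %s: %d iterations with no sampled-sire cubs", chain.cohort_year, dropped)
    if len(draws) == 0:
        raise ValueError("no PD_c draws: no iteration assigned any sampled sire")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "cohort_year": chain.cohort_year,
        "draws": draws,
        "mean": float(draws.mean()),
        "ci95": (float(lo), float(hi)),
        "n_dropped_iterations": dropped,
    }
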