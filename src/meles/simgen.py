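"""Synthetic population generator for a group-living, polygynandrous mammal.

Emulates a high-density badger-like study system: territorial social groups
represented by main-sett point coordinates on a grid, overlapping generations,
delayed-implantation reproductive timing (sires must be alive and >=1 year old
twelve months before a cub's birth), distance-decaying extra-group paternity,
immigration, and incomplete trapping-based observation.

Sire choice is a softmax over all eligible males with utility

    beta * d(natal sett, sire's sett)
    + (u_dam + u_sire + m[natal group] + p[sire's group]) * 1[extra-group]

where ``u`` are per-individual excursion propensities and ``(m_g, p_g)`` are
per-group latent effects in maternal and paternal role, drawn from a 2x2
covariance.  The heterogeneity terms act on extra-group candidacies only: a
bonus applied uniformly to a male at home and away would cancel out of the
distance composition of the cubs he sires and generate no paternal variance
in paternity distance.  A negative m-p correlation generates source-sink gene flow: the
single mechanism yields among-year, among-parent and among-group variance in
paternity distance, plus the negative maternal-group x paternal-group
covariance, downstream.

A separate generator (:func:`simulate_lmm_records`) draws cub records directly
from the crossed-random-effects linear model, for variance-partitioning
calibration studies that do not need the full pedigree machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import GenotypeTable, Locus, LocusPanel


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_survival() -> list[float]:
    # age-specific annual survival: cubs lowest, senescent decline after ~8 y
    return [0.65, 0.8, 0.85, 0.85, 0.85, 0.8, 0.75, 0.65, 0.5, 0.35, 0.2, 0.0]


@dataclass
class SimConfig:
    """Parameters of the synthetic study system.

    Defaults are calibrated to the descriptive statistics of a high-density
    badger population: ~25 groups at ~355 m nearest-neighbour sett spacing,
    mean group size ~6.4, adult sex ratio ~0.4 (proportion male), annual
    capture probabilities within the reported per-sex ranges, and a
    distance-decay coefficient giving ~35-40% extra-group paternity.
    """

    n_groups: int = 25
    sett_spacing: float = 355.0  # grid spacing, meters
    sett_coords: np.ndarray | None = None  # (n_groups, 2), overrides grid
    n_years: int = 30
    mean_group_size: float = 6.4
    group_sex_ratio: float = 0.4  # males / (males + females)
    survival_by_age: list[float] = field(default_factory=_default_survival)
    litter_size_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    litter_new_sire_prob: float = 0.25  # per later cub; calibrates multiple paternity
    breeding_prob: float = 0.48  # per eligible female per year, density-adjusted
    beta_distance: float = -0.007  # log-linear distance coefficient, per meter
    sigma_individual: tuple[float, float] = (0.5, 0.5)  # (dam, sire) propensity SDs
    group_effect_cov: np.ndarray = field(
        default_factory=lambda: np.array([[0.25, -0.15], [-0.15, 0.25]])
    )
    capture_prob: dict[str, float] = field(
        default_factory=lambda: {"F": 0.65, "M": 0.7}
    )
    immigrant_rate: float = 0.2  # expected adult immigrants per group per year
    move_prob: float = 0.05  # per adult-year prob of joint membership next door
    relocate_prob: float = 0.02  # per adult-year prob of permanent group change
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ConfigError("n_groups must be >= 2")
        cov = np.asarray(self.group_effect_cov, dtype=float)
        if cov.shape != (2, 2) or abs(cov[0, 1] - cov[1, 0]) > 1e-12:
            raise ConfigError("group_effect_cov must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-9:
            raise ConfigError("group_effect_cov must be positive semi-definite")
        self.group_effect_cov = cov
        probs = list(self.capture_prob.values()) if isinstance(
            self.capture_prob, dict
        ) else [self.capture_prob]
        for p in probs + [self.group_sex_ratio, self.breeding_prob, self.move_prob]:
            if not (0 <= p <= 1):
                raise ConfigError("all probabilities must lie in [0, 1]")
        if abs(sum(self.litter_size_dist.values()) - 1.0) > 1e-9:
            raise ConfigError("litter_size_dist must sum to 1")

    def capture_prob_for(self, sex: str) -> float:
        if isinstance(self.capture_prob, dict):
            return self.capture_prob[sex]
        return float(self.capture_prob)


def grid_setts(n_groups: int, spacing: float) -> np.ndarray:
    """Main-sett coordinates on a near-square grid with the given spacing."""
    side = math.ceil(math.sqrt(n_groups))
    pts = [(spacing * (i % side), spacing * (i // side)) for i in range(n_groups)]
    return np.asarray(pts, dtype=float)


# ---------------------------------------------------------------------------
# population truth
# ---------------------------------------------------------------------------


@dataclass
class PopulationTruth:
    """Ground truth of one simulated population."""

    individuals: pd.DataFrame  # id, sex, birth_year, death_year, immigrant, propensity
    groups: pd.DataFrame  # group_id, x, y
    memberships: dict[tuple[str, int], frozenset[str]]  # (id, year) -> group ids
    pedigree: pd.DataFrame  # cub, dam, sire, birth_year, natal_group, sire_group, distance
    group_effects: pd.DataFrame  # group_id, maternal_effect, paternal_effect
    config: SimConfig

    def sett_xy(self) -> dict[str, np.ndarray]:
        return {
            r.group_id: np.array([r.x, r.y]) for r in self.groups.itertuples()
        }

    def egp_rate(self) -> float:
        """True extra-group paternity rate across all simulated cubs."""
        ped = self.pedigree
        return float((ped["natal_group"] != ped["sire_group"]).mean())

    def alive_in(self, year: int) -> pd.DataFrame:
        ind = self.individuals
        return ind[(ind["birth_year"] <= year) & (ind["death_year"] >= year)]


def simulate_population(config: SimConfig) -> PopulationTruth:
    """Run the forward demographic simulation and return its ground truth."""
    rng = np.random.default_rng(config.seed)
    G = config.n_groups
    group_ids = [f"g{i:02d}" for i in range(G)]
    coords = (
        np.asarray(config.sett_coords, dtype=float)
        if config.sett_coords is not None
        else grid_setts(G, config.sett_spacing)
    )
    if coords.shape != (G, 2):
        raise ConfigError("sett coordinates must have shape (n_groups, 2)")
    dist = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    )  # (G, G) meters

    # latent group effects: (maternal-role, paternal-role)
    g_eff = rng.multivariate_normal(
        np.zeros(2), config.group_effect_cov, size=G, method="cholesky"
    )

    sd_dam, sd_sire = config.sigma_individual
    surv = np.asarray(config.survival_by_age, dtype=float)
    litter_sizes = np.array(sorted(config.litter_size_dist))
    litter_probs = np.array([config.litter_size_dist[k] for k in litter_sizes])

    # individual state, kept in parallel lists indexed by integer handle
    ids: list[str] = []
    sex: list[str] = []
    birth: list[int] = []
    death: list[int] = []  # provisional: n_years while alive
    immigrant: list[bool] = []
    propensity: list[float] = []
    primary: list[int] = []  # current primary group index
    base_mass: list[float] = []
    alive: list[bool] = []
    memberships: dict[tuple[str, int], frozenset[str]] = {}
    ped_rows: list[dict] = []
    counter = 0

    def new_ind(sx: str, by: int, grp: int, imm: bool) -> int:
        nonlocal counter
        handle = len(ids)
        ids.append(f"b{counter:05d}")
        counter += 1
        sex.append(sx)
        birth.append(by)
        death.append(config.n_years)
        immigrant.append(imm)
        propensity.append(rng.normal(0.0, sd_dam if sx == "F" else sd_sire))
        primary.append(grp)
        base_mass.append(rng.normal(10.6, 1.2) if sx == "M" else rng.normal(9.9, 1.1))
        alive.append(True)
        return handle

    # founders in year 1, ages from a rough stationary distribution
    for g in range(G):
        n0 = max(2, int(round(rng.normal(config.mean_group_size, 3.6))))
        for _ in range(n0):
            sx = "M" if rng.random() < config.group_sex_ratio else "F"
            age = int(1 + rng.geometric(0.35))
            new_ind(sx, 1 - min(age, 10), g, imm=False)

    def record_membership(h: int, year: int, groups_set: frozenset[str]) -> None:
        memberships[(ids[h], year)] = groups_set

    for year in range(1, config.n_years + 1):
        # snapshot of conception-year (previous-year) primary groups: with
        # delayed implantation the sire's location 12 months before birth is
        # what defines his group for paternity distance
        prev_primary = list(primary)

        # 1. mortality (not applied in the first year: founders enter alive)
        if year > 1:
            for h in range(len(ids)):
                if not alive[h]:
                    continue
                age_prev = (year - 1) - birth[h]
                s = surv[min(age_prev, len(surv) - 1)]
                if rng.random() >= s:
                    alive[h] = False
                    death[h] = year - 1

        # 2. immigration: adults of unknown provenance join random groups
        n_imm = rng.poisson(config.immigrant_rate * G)
        for _ in range(n_imm):
            sx = "M" if rng.random() < 0.5 else "F"
            age = 2 + int(rng.poisson(1.0))
            new_ind(sx, year - age, int(rng.integers(G)), imm=True)

        # 3. membership: occasional relocation / temporary joint membership
        year_groups: dict[int, frozenset[str]] = {}
        for h in range(len(ids)):
            if not alive[h]:
                continue
            age = year - birth[h]
            if age >= 1:
                if rng.random() < config.relocate_prob:
                    primary[h] = int(rng.integers(G))
                if rng.random() < config.move_prob:
                    order = np.argsort(dist[primary[h]])
                    neigh = int(order[1])  # nearest other group
                    gs = frozenset({group_ids[primary[h]], group_ids[neigh]})
                else:
                    gs = frozenset({group_ids[primary[h]]})
            else:
                gs = frozenset({group_ids[primary[h]]})
            year_groups[h] = gs
            record_membership(h, year, gs)

        # 4. breeding: cubs born in `year`, conceived in `year - 1`
        group_sizes = np.zeros(G, dtype=int)
        for h in year_groups:
            if (year - birth[h]) >= 1:
                group_sizes[primary[h]] += 1
        # eligible sires: alive at conception (end of year-1), age >=1 then
        sire_handles = [
            h
            for h in range(len(ids))
            if sex[h] == "M"
            and birth[h] <= year - 2
            and (death[h] >= year - 1)
            and (birth[h] <= year - 1)
            and (alive[h] or death[h] == year - 1)
        ]
        if sire_handles:
            # conception-year group; new arrivals (this year's immigrants)
            # fall back to their entry group
            sire_grp = np.array(
                [
                    prev_primary[h] if h < len(prev_primary) else primary[h]
                    for h in sire_handles
                ]
            )
            sire_u = np.array([propensity[h] for h in sire_handles])
            sire_p = g_eff[sire_grp, 1]
        for h in list(year_groups):
            if sex[h] != "F" or not alive[h]:
                continue
            age = year - birth[h]
            if age < 2 or birth[h] > year - 2:
                continue
            if death[h] < year - 1:  # must have been alive at conception
                continue
            g = primary[h]
            adj = config.breeding_prob * min(
                1.5, max(0.5, config.mean_group_size / max(group_sizes[g], 1))
            )
            if rng.random() >= min(adj, 0.95) or not sire_handles:
                continue
            # softmax sire utilities for this dam
            d = dist[g, sire_grp]
            extra = (sire_grp != g).astype(float)
            # propensities and group effects act on extra-group candidacies
            # only: a uniform (multiplicative) bonus would cancel out of the
            # distance composition of a male's or group's sired cubs
            util = (
                config.beta_distance * d
                + (sire_u + sire_p + propensity[h] + g_eff[g, 0]) * extra
            )
            w = np.exp(util - util.max())
            w /= w.sum()
            n_cubs = int(rng.choice(litter_sizes, p=litter_probs))
            j = -1
            for c in range(n_cubs):
                # litters share a sire unless a later cub redraws: mixed
                # paternity occurs in a calibrated fraction of litters
                if c == 0 or rng.random() < config.litter_new_sire_prob:
                    j = int(rng.choice(len(sire_handles), p=w))
                sh = sire_handles[j]
                cub = new_ind(
                    "M" if rng.random() < config.group_sex_ratio else "F",
                    year,
                    g,
                    imm=False,
                )
                record_membership(cub, year, frozenset({group_ids[g]}))
                year_groups[cub] = frozenset({group_ids[g]})
                ped_rows.append(
                    {
                        "cub": ids[cub],
                        "dam": ids[h],
                        "sire": ids[sh],
                        "birth_year": year,
                        "natal_group": group_ids[g],
                        "sire_group": group_ids[sire_grp[j]],
                        "distance": float(dist[g, sire_grp[j]]),
                        "natal_male_available": bool((sire_grp == g).any()),
                    }
                )

    individuals = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "birth_year": birth,
            "death_year": [min(d, config.n_years) for d in death],
            "immigrant": immigrant,
            "propensity": propensity,
            "base_mass": base_mass,
        }
    )
    groups = pd.DataFrame(
        {"group_id": group_ids, "x": coords[:, 0], "y": coords[:, 1]}
    )
    pedigree = pd.DataFrame(
        ped_rows,
        columns=[
            "cub",
            "dam",
            "sire",
            "birth_year",
            "natal_group",
            "sire_group",
            "distance",
            "natal_male_available",
        ],
    )
    effects = pd.DataFrame(
        {
            "group_id": group_ids,
            "maternal_effect": g_eff[:, 0],
            "paternal_effect": g_eff[:, 1],
        }
    )
    return PopulationTruth(individuals, groups, memberships, pedigree, effects, config)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def random_panel(
    n_loci: int = 22,
    seed: int = 0,
    allele_counts: Sequence[int] = (4, 5, 6),
    allele_count_probs: Sequence[float] = (0.35, 0.45, 0.2),
    dirichlet_alpha: float = 0.7,
    e1: float = 0.01,
    e2: float = 0.01,
) -> LocusPanel:
    """Random microsatellite panel.

    Defaults give ~4.85 alleles per locus and mean expected heterozygosity
    ~0.61, matching a moderately polymorphic badger panel.
    """
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_loci):
        k = int(rng.choice(allele_counts, p=allele_count_probs))
        freqs = rng.dirichlet(np.full(k, dirichlet_alpha))
        # keep every allele observable
        freqs = np.maximum(freqs, 0.02)
        freqs /= freqs.sum()
        alleles = [100 + 2 * j for j in range(k)]
        loci.append(Locus(f"L{i+1:02d}", alleles, freqs, e1=e1, e2=e2))
    return LocusPanel(loci)


def simulate_genotypes(
    truth: PopulationTruth,
    panel: LocusPanel,
    seed: int,
    missing_rate: float = 0.0,
) -> tuple[GenotypeTable, GenotypeTable]:
    """Gene-drop genotypes through the true pedigree and corrupt them.

    Returns ``(true_table, observed_table)``.  Founders (initial individuals
    and immigrants) draw genotypes from panel frequencies under random union
    of gametes; offspring inherit one allele per parent per locus.  Observed
    genotypes pass through the per-locus dropout-then-miscall channel and an
    optional per-(individual, locus) missing-data process.
    """
    if not (0 <= missing_rate < 1):
        raise ConfigError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    parents = {r.cub: (r.dam, r.sire) for r in truth.pedigree.itertuples()}
    order = truth.individuals.sort_values("birth_year")["id"].tolist()

    true_data: dict[str, dict[str, tuple[int, int]]] = {i: {} for i in order}
    for locus in panel:
        alleles = np.asarray(locus.alleles)
        for ind in order:
            if ind in parents:
                dam, sire = parents[ind]
                a1 = true_data[dam][locus.name][int(rng.integers(2))]
                a2 = true_data[sire][locus.name][int(rng.integers(2))]
            else:
                a1, a2 = rng.choice(alleles, size=2, p=locus.freqs)
            a1, a2 = int(a1), int(a2)
            true_data[ind][locus.name] = (min(a1, a2), max(a1, a2))

    obs_data: dict[str, dict[str, tuple[int, int] | None]] = {i: {} for i in order}
    for locus in panel:
        alleles = np.asarray(locus.alleles)
        for ind in order:
            if missing_rate and rng.random() < missing_rate:
                obs_data[ind][locus.name] = None
                continue
            a1, a2 = true_data[ind][locus.name]
            if a1 != a2:  # allelic dropout on heterozygotes
                u = rng.random()
                if u < locus.e1:
                    a1 = a2
                elif u < 2 * locus.e1:
                    a2 = a1
            out = []
            for a in (a1, a2):  # per-allele miscall
                if locus.e2 and rng.random() < locus.e2:
                    a = int(rng.choice(alleles, p=locus.freqs))
                out.append(int(a))
            obs_data[ind][locus.name] = (min(out), max(out))

    names = panel.locus_names
    return GenotypeTable(true_data, names), GenotypeTable(obs_data, names)


# ---------------------------------------------------------------------------
# observation process
# ---------------------------------------------------------------------------


def simulate_observation(
    truth: PopulationTruth, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Trapping records: one row per (individual, year, group) capture.

    Columns: id, year, group, sex, age_class, body_mass.  Individuals never
    captured leave no genotype and become unsampled parents downstream.
    Immigrants are first captured as adults, so their true birth year is not
    observable from this table.
    """
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    rows = []
    for r in truth.individuals.itertuples():
        p_cap = config.capture_prob_for(r.sex)
        for year in range(max(1, r.birth_year), int(r.death_year) + 1):
            if rng.random() >= p_cap:
                continue
            age = year - r.birth_year
            age_class = "cub" if age == 0 else ("yearling" if age == 1 else "adult")
            mass = r.base_mass * (0.55 if age == 0 else 1.0) + rng.normal(0, 0.5)
            grps = sorted(truth.memberships.get((r.id, year), frozenset()))
            if not grps:
                continue
            recorded = [grps[0]] + [g for g in grps[1:] if rng.random() < 0.5]
            for g in recorded:
                rows.append(
                    {
                        "id": r.id,
                        "year": year,
                        "group": g,
                        "sex": r.sex,
                        "age_class": age_class,
                        "body_mass": round(float(mass), 2),
                    }
                )
    return pd.DataFrame(rows, columns=["id", "year", "group", "sex", "age_class", "body_mass"])


# ---------------------------------------------------------------------------
# direct LMM-mode records
# ---------------------------------------------------------------------------

FIXED_COVARIATES = [
    "dam_age",
    "dam_mass",
    "msg_group_size",
    "msg_sex_ratio",
    "sire_age",
    "sire_mass",
    "psg_group_size",
    "psg_sex_ratio",
]


@dataclass
class LmmTruth:
    """Generating values for the crossed random-effects model.

    Defaults are the (co)variance components estimated for ln paternity
    distance in the motivating study system (responses in SD units):
    V_year=0.02, V_M=0.26, V_P=0.31, V_MSG=0.39, V_PSG=0.59,
    COV_MSG.PSG=-0.48, V_R=0.32.  As printed, |COV| exceeds
    sqrt(V_MSG*V_PSG) by ~0.06%% (a rounding artifact); covariances within
    1%% of the boundary are clipped to the valid r = +/-1 edge, larger
    violations raise.
    """

    v_year: float = 0.02
    v_m: float = 0.26
    v_p: float = 0.31
    v_msg: float = 0.39
    v_psg: float = 0.59
    cov_msg_psg: float = -0.48
    v_r: float = 0.32
    mu: float = 0.0
    fixed_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in [
            ("v_year", self.v_year),
            ("v_m", self.v_m),
            ("v_p", self.v_p),
            ("v_msg", self.v_msg),
            ("v_psg", self.v_psg),
            ("v_r", self.v_r),
        ]:
            if v < 0:
                raise ConfigError(f"{name} must be >= 0")
        bound = math.sqrt(self.v_msg * self.v_psg)
        if abs(self.cov_msg_psg) > bound * 1.01:
            raise ConfigError("|COV_MSG.PSG| exceeds sqrt(V_MSG*V_PSG)")
        if abs(self.cov_msg_psg) > bound:
            self.cov_msg_psg = math.copysign(bound, self.cov_msg_psg)
        unknown = set(self.fixed_effects) - set(FIXED_COVARIATES)
        if unknown:
            raise ConfigError(f"unknown fixed covariates: {sorted(unknown)}")

    def group_cov(self) -> np.ndarray:
        return np.array(
            [[self.v_msg, self.cov_msg_psg], [self.cov_msg_psg, self.v_psg]]
        )


def simulate_lmm_records(
    variance_config: LmmTruth,
    n_cubs: int,
    seed: int,
    n_years: int = 10,
    n_groups: int = 20,
    dams_per_group: int = 5,
    sires_per_group: int = 5,
    p_within_group: float = 0.6,
) -> pd.DataFrame:
    """Draw cub records directly from the crossed random-effects model.

    Each cub gets a maternal social group (MSG), a paternal social group
    (PSG; equal to MSG with probability ``p_within_group``), a dam nested in
    MSG, a sire nested in PSG, and a year.  The same physical group
    contributes correlated maternal-role and paternal-role effects with the
    configured 2x2 covariance; dams and sires recur across cubs, giving the
    repeated structure the variance partition needs.
    """
    vc = variance_config
    rng = np.random.default_rng(seed)
    year_eff = rng.normal(0, math.sqrt(vc.v_year), n_years)
    g_eff = rng.multivariate_normal(
        np.zeros(2), vc.group_cov(), size=n_groups, method="svd"
    )
    n_dams, n_sires = n_groups * dams_per_group, n_groups * sires_per_group
    dam_eff = rng.normal(0, math.sqrt(vc.v_m), n_dams)
    sire_eff = rng.normal(0, math.sqrt(vc.v_p), n_sires)

    msg = rng.integers(n_groups, size=n_cubs)
    same = rng.random(n_cubs) < p_within_group
    psg = np.where(same, msg, rng.integers(n_groups, size=n_cubs))
    dam = msg * dams_per_group + rng.integers(dams_per_group, size=n_cubs)
    sire = psg * sires_per_group + rng.integers(sires_per_group, size=n_cubs)
    year = rng.integers(n_years, size=n_cubs)

    X = rng.standard_normal((n_cubs, len(FIXED_COVARIATES)))
    beta = np.array([vc.fixed_effects.get(c, 0.0) for c in FIXED_COVARIATES])
    y = (
        vc.mu
        + X @ beta
        + year_eff[year]
        + dam_eff[dam]
        + sire_eff[sire]
        + g_eff[msg, 0]
        + g_eff[psg, 1]
        + rng.normal(0, math.sqrt(vc.v_r), n_cubs)
    )
    out = pd.DataFrame(X, columns=FIXED_COVARIATES)
    out.insert(0, "cub_id", [f"c{i:05d}" for i in range(n_cubs)])
    out["cohort_year"] = year + 1
    out["dam_id"] = [f"d{i:03d}" for i in dam]
    out["sire_id"] = [f"s{i:03d}" for i in sire]
    out["msg"] = [f"g{i:02d}" for i in msg]
    out["psg"] = [f"g{i:02d}" for i in psg]
    out["response"] = y
    return out
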