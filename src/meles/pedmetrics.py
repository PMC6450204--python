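"""Pedigree compilation and cub-level breeding-excursion metrics.

From thresholded parentage assignments this module derives, per cub:

* ``pd_i`` -- paternity distance: Euclidean distance (m) between the main
  sett of the father's social group and that of the cub's natal group;
* ``egp_i`` -- extra-group paternity: 1 if the assigned father belonged to no
  natal group of the cub in the conception year, else 0.  A father recorded
  in both the natal group and elsewhere makes the cub within-group offspring
  (the tie rule), and then ``pd_i = 0``.  For extra-group fathers holding
  several non-natal memberships the minimum sett distance is used.

Parental covariates (age, body mass, group size, group sex ratio in maternal
and paternal role) are attached for the downstream variance partition, and
pedigree summary statistics (sibships, litters, multiple paternity, annual
extra-group paternity rates) are computed.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd

from .parentage import CandidateRules, derive_life_history

logger = logging.getLogger(__name__)


class PedigreeError(ValueError):
    pass


def compile_pedigree(assignments: pd.DataFrame) -> pd.DataFrame:
    """Merge per-cohort thresholded assignments into one validated pedigree.

    Input columns: cub_id, dam_id, sire_id, cohort (from
    :func:`meles.parentage.summarize_assignments`; missing parents allowed).
    Validates unique offspring ids, acyclicity and that no individual appears
    in both parental roles.
    """
    ped = assignments.rename(
        columns={"cub_id": "id", "dam_id": "dam", "sire_id": "sire", "cohort": "birth_year"}
    )[["id", "dam", "sire", "birth_year"]].copy()
    if ped["id"].duplicated().any():
        dupes = ped.loc[ped["id"].duplicated(), "id"].tolist()
        raise PedigreeError(f"duplicate offspring ids: {dupes}")
    dams = set(ped["dam"].dropna())
    sires = set(ped["sire"].dropna())
    dual = dams & sires
    if dual:
        raise PedigreeError(f"ids in both parental roles: {sorted(dual)}")
    g = nx.DiGraph()
    for r in ped.itertuples():
        for parent in (r.dam, r.sire):
            if parent is not None and not (isinstance(parent, float) and math.isnan(parent)):
                if parent == r.id:
                    raise PedigreeError(f"self-parentage for {r.id}")
                g.add_edge(parent, r.id)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise PedigreeError(f"pedigree contains a cycle: {cycle}")
    return ped.reset_index(drop=True)


# ---------------------------------------------------------------------------
# residency and group composition
# ---------------------------------------------------------------------------


def residency(
    captures: pd.DataFrame, year: int, rules: CandidateRules = CandidateRules()
) -> pd.DataFrame:
    """Resident group members (yearlings + adults) for one year.

    An individual is resident in the group(s) where it was captured most
    often that year (ties keep all tied groups).  With one capture record per
    year this reduces to the capture group.  Cubs (age 0 that year) are
    excluded, as are individuals without a capture that year.
    Returns columns id, group, sex.
    """
    lh = derive_life_history(captures, rules)
    caps = captures[captures["year"] == year]
    rows = []
    for ind, grp in caps.groupby("id"):
        info = lh.table.loc[str(ind)]
        age = year - info["birth_year"]
        if age < 1 or info["sex"] is None:
            continue
        counts = grp["group"].value_counts()
        top = counts[counts == counts.max()].index
        for g in top:
            rows.append({"id": str(ind), "group": g, "sex": info["sex"]})
    return pd.DataFrame(rows, columns=["id", "group", "sex"])


def group_composition(captures: pd.DataFrame, year: int) -> pd.DataFrame:
    """Per-group size and sex ratio (males / (males + females)) of residents."""
    res = residency(captures, year)
    if res.empty:
        return pd.DataFrame(columns=["group", "group_size", "sex_ratio"])
    out = (
        res.groupby("group")
        .agg(group_size=("id", "nunique"), males=("sex", lambda s: (s == "M").sum()))
        .reset_index()
    )
    out["sex_ratio"] = out["males"] / out["group_size"]
    return out[["group", "group_size", "sex_ratio"]]


# ---------------------------------------------------------------------------
# cub records
# ---------------------------------------------------------------------------


def cub_metrics(
    pedigree: pd.DataFrame,
    captures: pd.DataFrame,
    groups: pd.DataFrame,
    rules: CandidateRules = CandidateRules(),
) -> pd.DataFrame:
    """Per-cub paternity distance, extra-group paternity and parental covariates.

    Only cubs with both parents assigned yield a complete record; cubs whose
    sire has no recorded group in the conception year are dropped (logged).
    Group size and sex ratio refer to the conception year (birth year - 1,
    delayed implantation); parental body mass is averaged over the birth-year
    capture records of the parent.
    """
    lh = derive_life_history(captures, rules)
    sett = {str(r.group_id): (float(r.x), float(r.y)) for r in groups.itertuples()}

    def dist(g1: str, g2: str) -> float:
        (x1, y1), (x2, y2) = sett[g1], sett[g2]
        return math.hypot(x1 - x2, y1 - y2)

    comp_cache: dict[int, pd.DataFrame] = {}

    def composition(year: int) -> pd.DataFrame:
        if year not in comp_cache:
            comp_cache[year] = group_composition(captures, year).set_index("group")
        return comp_cache[year]

    mass_by_year = (
        captures.groupby(["id", "year"])["body_mass"].mean()
        if "body_mass" in captures.columns
        else None
    )

    rows = []
    for r in pedigree.itertuples():
        if pd.isna(r.dam) or pd.isna(r.sire):
            continue
        cub, dam, sire, by = r.id, r.dam, r.sire, int(r.birth_year)
        conception = by - 1
        info_cub = lh.table.loc[cub]
        natal = frozenset(g for g in lh.groups_of(cub, info_cub["first_year"]) if g in sett)
        sire_grps = frozenset(
            g for g in (lh.groups_of(sire, conception) or lh.groups_of(sire, by)) if g in sett
        )
        if not natal:
            logger.info("cub %s dropped: no natal group", cub)
            continue
        if not sire_grps:
            logger.info("cub %s dropped: sire %s has no recorded group in %d", cub, sire, conception)
            continue
        if natal & sire_grps:
            egp, pd_i = 0, 0.0
            psg = min(natal & sire_grps)
        else:
            egp = 1
            pairs = [(dist(ng, sg), sg) for ng in natal for sg in sire_grps]
            pd_i, psg = min(pairs)
        msg = min(natal)

        def parent_cov(pid: str, prefix: str) -> dict:
            info = lh.table.loc[pid]
            age = float(by - info["birth_year"]) if info["age_known"] else np.nan
            mass = np.nan
            if mass_by_year is not None and (pid, by) in mass_by_year.index:
                mass = float(mass_by_year.loc[(pid, by)])
            return {f"{prefix}_age": age, f"{prefix}_mass": mass}

        def group_cov(gid: str, prefix: str) -> dict:
            comp = composition(conception)
            if gid in comp.index:
                return {
                    f"{prefix}_group_size": float(comp.loc[gid, "group_size"]),
                    f"{prefix}_sex_ratio": float(comp.loc[gid, "sex_ratio"]),
                }
            return {f"{prefix}_group_size": np.nan, f"{prefix}_sex_ratio": np.nan}

        rec = {
            "cub_id": cub,
            "cohort_year": by,
            "dam_id": dam,
            "sire_id": sire,
            "msg": msg,
            "psg": psg,
            "pd_i": pd_i,
            "egp_i": egp,
        }
        rec.update(parent_cov(dam, "dam"))
        rec.update(parent_cov(sire, "sire"))
        rec.update(group_cov(msg, "msg"))
        rec.update(group_cov(psg, "psg"))
        rows.append(rec)
    cols = [
        "cub_id",
        "cohort_year",
        "dam_id",
        "sire_id",
        "msg",
        "psg",
        "pd_i",
        "egp_i",
        "dam_age",
        "dam_mass",
        "msg_group_size",
        "msg_sex_ratio",
        "sire_age",
        "sire_mass",
        "psg_group_size",
        "psg_sex_ratio",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# pedigree summary statistics
# ---------------------------------------------------------------------------


def pedigree_stats(pedigree: pd.DataFrame, egp: pd.Series | None = None) -> dict:
    """Summary statistics of a compiled pedigree.

    ``pedigree`` needs columns id, dam, sire, birth_year.  ``egp`` is an
    optional per-cub 0/1 series (indexed by cub id) from which annual
    extra-group paternity rates and their across-year mean and SD are
    computed.  Multiple-paternity fractions use litters of more than one cub
    as the denominator.
    """
    ped = pedigree
    has_dam, has_sire = ped["dam"].notna(), ped["sire"].notna()
    maternities = int(has_dam.sum())
    paternities = int(has_sire.sum())
    both = int((has_dam & has_sire).sum())

    def sibship_sizes(col: str) -> list[int]:
        return ped.loc[ped[col].notna(), col].value_counts().tolist()

    mat_sib, pat_sib = sibship_sizes("dam"), sibship_sizes("sire")
    full_sibs = int(
        (
            ped.loc[has_dam & has_sire]
            .groupby(["dam", "sire"])
            .size()
            .pipe(lambda s: s[s > 1])
        ).shape[0]
    )

    # grandparental links: cub -> parent -> grandparent
    dam_of = ped.set_index("id")["dam"].dropna().to_dict()
    sire_of = ped.set_index("id")["sire"].dropna().to_dict()
    links = {"mat_grandmaternal": 0, "mat_grandpaternal": 0, "pat_grandmaternal": 0, "pat_grandpaternal": 0}
    for r in ped.itertuples():
        if not pd.isna(r.dam):
            links["mat_grandmaternal"] += r.dam in dam_of
            links["mat_grandpaternal"] += r.dam in sire_of
        if not pd.isna(r.sire):
            links["pat_grandmaternal"] += r.sire in dam_of
            links["pat_grandpaternal"] += r.sire in sire_of

    litters = ped.loc[has_dam].groupby(["dam", "birth_year"])
    litter_sizes = litters.size()
    multi = litter_sizes[litter_sizes > 1]
    n_multi_pat = 0
    multi_detail = {"two_sires": 0, "all_different": 0}
    for key in multi.index:
        sires = litters.get_group(key)["sire"].dropna()
        k = sires.nunique()
        if k > 1:
            n_multi_pat += 1
            if k == len(sires) and len(sires) > 2:
                multi_detail["all_different"] += 1
            else:
                multi_detail["two_sires"] += 1

    out = {
        "n_offspring": int(len(ped)),
        "n_assigned_any": int((has_dam | has_sire).sum()),
        "n_assigned_both": both,
        "n_dam_only": int((has_dam & ~has_sire).sum()),
        "n_sire_only": int((~has_dam & has_sire).sum()),
        "maternities": maternities,
        "paternities": paternities,
        "n_mothers": int(ped["dam"].nunique()),
        "n_fathers": int(ped["sire"].nunique()),
        "maternal_sibship_mean": float(np.mean(mat_sib)) if mat_sib else 0.0,
        "maternal_sibship_max": int(max(mat_sib)) if mat_sib else 0,
        "paternal_sibship_mean": float(np.mean(pat_sib)) if pat_sib else 0.0,
        "paternal_sibship_max": int(max(pat_sib)) if pat_sib else 0,
        "n_full_sibships": full_sibs,
        "grandparental_links": links,
        "n_litters": int(len(litter_sizes)),
        "litter_size_mean": float(litter_sizes.mean()) if len(litter_sizes) else float("nan"),
        "litter_size_range": (
            [int(litter_sizes.min()), int(litter_sizes.max())] if len(litter_sizes) else [0, 0]
        ),
        "n_litters_gt1": int(len(multi)),
        "multiple_paternity_fraction": (n_multi_pat / len(multi)) if len(multi) else float("nan"),
        "multiple_paternity_detail": multi_detail,
    }
    if egp is not None:
        joined = ped.loc[has_sire, ["id", "birth_year"]].merge(
            egp.rename("egp").rename_axis("id").reset_index(), on="id"
        )
        per_year = joined.groupby("birth_year")["egp"].mean()
        out["egp_rate_by_year"] = {int(k): float(v) for k, v in per_year.items()}
        out["egp_rate_mean"] = float(per_year.mean())
        out["egp_rate_sd"] = float(per_year.std(ddof=1)) if len(per_year) > 1 else 0.0
    return out
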