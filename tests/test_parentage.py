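"""Candidate rules, MCMC schedule/retention, posterior correctness."""

import numpy as np
import pandas as pd
import pytest

from meles.genetics import GenotypeTable, Locus, LocusPanel, transmission_likelihood
from meles.parentage import (
    UNSAMPLED,
    CandidateSet,
    MCMCConfig,
    PosteriorChain,
    build_candidate_sets,
    build_likelihood_grids,
    derive_life_history,
    pdc_posterior,
    retention_iterations,
    run_mcmc,
    summarize_assignments,
)


def _cap(ind, year, group, sex, age_class, mass=10.0):
    return {
        "id": ind, "year": year, "group": group, "sex": sex,
        "age_class": age_class, "body_mass": mass,
    }


@pytest.fixture
def toy_groups():
    return pd.DataFrame(
        {"group_id": ["gA", "gB"], "x": [0.0, 300.0], "y": [0.0, 400.0]}
    )


class TestCandidateRules:
    def test_one_year_old_female_excluded_as_dam(self, toy_groups):
        caps = pd.DataFrame(
            [
                _cap("cub1", 5, "gA", "F", "cub"),
                _cap("f_young", 4, "gA", "F", "cub"),  # age 1 in year 5
                _cap("f_young", 5, "gA", "F", "yearling"),
                _cap("f_old", 1, "gA", "F", "cub"),  # age 4 in year 5
                _cap("f_old", 5, "gA", "F", "adult"),
            ]
        )
        cands, _ = build_candidate_sets(caps, toy_groups, 5)
        assert cands[0].dams == ["f_old"]

    def test_male_aged_exactly_one_at_conception_included(self, toy_groups):
        caps = pd.DataFrame(
            [
                _cap("cub1", 5, "gA", "F", "cub"),
                _cap("f_old", 1, "gA", "F", "cub"),
                _cap("f_old", 5, "gA", "F", "adult"),
                # born year 3: age 1 in year 4 (12 months pre-birth) -> eligible
                _cap("m_edge", 3, "gB", "M", "cub"),
                _cap("m_edge", 5, "gB", "M", "adult"),
                # born year 4: age 0 at conception -> not eligible
                _cap("m_late", 4, "gB", "M", "cub"),
                _cap("m_late", 5, "gB", "M", "yearling"),
            ]
        )
        cands, _ = build_candidate_sets(caps, toy_groups, 5)
        assert cands[0].sires == ["m_edge"]

    def test_male_distance_345_triangle(self, toy_groups):
        caps = pd.DataFrame(
            [
                _cap("cub1", 5, "gB", "F", "cub"),
                _cap("f_old", 1, "gB", "F", "cub"),
                _cap("f_old", 5, "gB", "F", "adult"),
                _cap("m1", 1, "gA", "M", "cub"),
                _cap("m1", 4, "gA", "M", "adult"),
            ]
        )
        cands, _ = build_candidate_sets(caps, toy_groups, 5)
        cs = cands[0]
        assert cs.natal_groups == frozenset({"gB"})
        assert cs.sires == ["m1"]
        assert cs.sire_distances[0] == pytest.approx(500.0)

    def test_unknown_age_adult_assumed_two_at_first_capture(self):
        caps = pd.DataFrame(
            [_cap("ad1", 6, "gA", "F", "adult"), _cap("ad1", 7, "gA", "F", "adult")]
        )
        lh = derive_life_history(caps)
        row = lh.table.loc["ad1"]
        assert row["birth_year"] == 4
        assert not row["age_known"]

    def test_grace_years_cub_vs_adult(self):
        caps = pd.DataFrame(
            [_cap("c", 5, "gA", "F", "cub"), _cap("a", 5, "gA", "M", "adult")]
        )
        lh = derive_life_history(caps)
        assert lh.table.loc["c", "alive_until"] == 6  # +1 year for cubs
        assert lh.table.loc["a", "alive_until"] == 8  # +3 years otherwise

    def test_membership_carried_forward_when_uncaught(self):
        caps = pd.DataFrame(
            [_cap("a", 3, "gA", "M", "adult"), _cap("a", 6, "gB", "M", "adult")]
        )
        lh = derive_life_history(caps)
        assert lh.groups_of("a", 4) == frozenset({"gA"})
        assert lh.groups_of("a", 6) == frozenset({"gB"})

    def test_cub_without_natal_group_excluded(self, toy_groups):
        caps = pd.DataFrame(
            [
                _cap("cub1", 5, "unknown_territory", "F", "cub"),
                _cap("f_old", 1, "gA", "F", "cub"),
                _cap("f_old", 5, "gA", "F", "adult"),
            ]
        )
        cands, excluded = build_candidate_sets(caps, toy_groups, 5)
        assert not cands
        assert excluded.iloc[0]["reason"] == "no natal group"


class TestSchedule:
    def test_canonical_schedule_retains_15000(self):
        # 2M iterations, 500k burn-in, thinning 100
        cfg = MCMCConfig(n_iter=2_000_000, burn_in=500_000, thin=100)
        assert cfg.n_retained == 15_000
        assert len(retention_iterations(2_000_000, 500_000, 100)) == 15_000

    def test_degenerate_schedule_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=90, thin=20)
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=200, thin=1)

    def test_retention_indices_are_post_burnin_and_spaced(self):
        idx = retention_iterations(1000, 200, 50)
        assert idx[0] == 250 and idx[-1] == 1000
        assert np.all(np.diff(idx) == 50)


def _uninformative_setup(n_sires=2):
    """Cub with all loci missing, one dam, n sires: pure-prior posterior."""
    panel = LocusPanel([Locus("L", [1, 2], np.array([0.5, 0.5]))])
    data = {"cub": {"L": None}, "dam": {"L": (1, 2)}}
    sires = [f"s{i}" for i in range(n_sires)]
    for s in sires:
        data[s] = {"L": (1, 2)}
    gts = GenotypeTable(data, ["L"])
    cs = CandidateSet(
        cub_id="cub", cohort_year=1, natal_groups=frozenset({"g"}),
        dams=["dam"], sires=sires, sire_distances=np.zeros(n_sires),
    )
    return [cs], gts, panel


class TestSampler:
    def test_symmetric_sires_get_equal_posterior(self):
        cands, gts, panel = _uninformative_setup(2)
        cfg = MCMCConfig(
            n_iter=20000, burn_in=1000, thin=1, seed=3, use_distance=False,
            fixed_us=1e-9, fixed_ud=1e-9,
        )
        chain = run_mcmc(cands, gts, panel, cfg)
        probs = chain.posterior_probs(0, "sire")
        se = np.sqrt(0.25 / chain.n_retained)
        assert probs["s0"] == pytest.approx(0.5, abs=4 * se)
        assert probs["s1"] == pytest.approx(0.5, abs=4 * se)

    def test_posterior_probs_sum_to_one(self):
        cands, gts, panel = _uninformative_setup(3)
        cfg = MCMCConfig(n_iter=2000, burn_in=500, thin=5, seed=1, use_distance=False)
        chain = run_mcmc(cands, gts, panel, cfg)
        for role in ("dam", "sire"):
            assert sum(chain.posterior_probs(0, role).values()) == pytest.approx(1.0)

    def test_mendelian_excluded_candidate_never_sampled(self, small_world):
        truth, og, panel = (
            small_world["truth"], small_world["genotypes"], small_world["panel"],
        )
        caps = small_world["captures"]
        cands, _ = build_candidate_sets(caps, truth.groups, 9, genotypes=og)
        cands = cands[:10]
        grids, dam_lists, sire_list = build_likelihood_grids(cands, og, panel, 1)
        cfg = MCMCConfig(n_iter=4000, burn_in=500, thin=5, seed=2)
        chain = run_mcmc(cands, og, panel, cfg)
        for i in range(len(cands)):
            sampled_sires = set(chain.sire_samples[:, i].tolist())
            for b in sampled_sires:
                if b > 0:
                    assert grids[i][:, b].max() > 0

    def test_chain_retention_matches_schedule(self, small_world):
        truth, og, panel = (
            small_world["truth"], small_world["genotypes"], small_world["panel"],
        )
        cands, _ = build_candidate_sets(
            small_world["captures"], truth.groups, 8, genotypes=og
        )
        cfg = MCMCConfig(n_iter=3000, burn_in=1000, thin=10, seed=0)
        chain = run_mcmc(cands[:5], og, panel, cfg)
        assert chain.n_retained == cfg.n_retained == 200

    def test_exact_enumeration_oracle(self, small_world):
        # <=5 cubs, weakly informative loci, fixed hyperparameters: the MCMC
        # posterior must match the enumerated conditional within MC error
        truth, og = small_world["truth"], small_world["genotypes"]
        from meles.simgen import random_panel, simulate_genotypes

        panel = random_panel(4, seed=21, e1=0.02, e2=0.02)
        _, weak = simulate_genotypes(truth, panel, seed=23)
        caps = small_world["captures"]
        cands, _ = build_candidate_sets(caps, truth.groups, 10, genotypes=weak)
        cands = cands[:4]
        beta, us, ud = -0.003, 2.0, 0.7
        cfg = MCMCConfig(
            n_iter=42000, burn_in=2000, thin=2, seed=5,
            fixed_beta=beta, fixed_us=us, fixed_ud=ud,
        )
        chain = run_mcmc(cands, weak, panel, cfg)
        n = chain.n_retained
        for i, cs in enumerate(cands):
            dams = [None] + list(cs.dams)
            sires = [None] + list(cs.sires)
            dbar = cs.sire_distances.mean()
            W = np.zeros((len(dams), len(sires)))
            from meles.genetics import mismatch_count

            cub_gt = weak.genotypes_of(cs.cub_id)
            for a, d in enumerate(dams):
                for b, s in enumerate(sires):
                    # the mismatch tolerance (1 opposing-homozygote locus) is
                    # part of the model: excluded candidates carry no mass
                    if d is not None and mismatch_count(cub_gt, weak.genotypes_of(d)) > 1:
                        continue
                    if s is not None and mismatch_count(cub_gt, weak.genotypes_of(s)) > 1:
                        continue
                    L = transmission_likelihood(
                        weak.genotypes_of(cs.cub_id),
                        None if d is None else weak.genotypes_of(d),
                        None if s is None else weak.genotypes_of(s),
                        panel,
                    )
                    pd_w = ud if d is None else 1.0
                    dist = dbar if s is None else cs.sire_distances[b - 1]
                    ps_w = (us if s is None else 1.0) * np.exp(beta * dist)
                    W[a, b] = L * pd_w * ps_w
            W /= W.sum()
            post = chain.posterior_probs(i, "sire")
            for b, s in enumerate(sires):
                label = UNSAMPLED if s is None else s
                p = W[:, b].sum()
                se = np.sqrt(p * (1 - p) / n)
                # + 3/n guards the Poisson tail where the normal
                # approximation undercovers (many cells with tiny p)
                assert abs(post[label] - p) < 3.5 * se + 3.0 / n, (cs.cub_id, label)

    def test_beta_acceptance_in_target_window(self, small_world):
        truth, og, panel = (
            small_world["truth"], small_world["genotypes"], small_world["panel"],
        )
        cands, _ = build_candidate_sets(
            small_world["captures"], truth.groups, 10, genotypes=og
        )
        cfg = MCMCConfig(n_iter=12000, burn_in=4000, thin=10, seed=4)
        chain = run_mcmc(cands, og, panel, cfg)
        assert 0.2 <= chain.diagnostics["beta_accept"] <= 0.5

    def test_no_distance_mode_has_no_pdc(self, small_world):
        truth, og, panel = (
            small_world["truth"], small_world["genotypes"], small_world["panel"],
        )
        cands, _ = build_candidate_sets(
            small_world["captures"], truth.groups, 9, genotypes=og, use_distance=False
        )
        cfg = MCMCConfig(n_iter=2000, burn_in=500, thin=10, seed=0, use_distance=False)
        chain = run_mcmc(cands[:8], og, panel, cfg)
        assert chain.pdc is None
        assert np.all(chain.beta == 0.0)
        with pytest.raises(ValueError):
            pdc_posterior(chain)


def _chain_with_counts(counts: dict[str, int], n: int) -> PosteriorChain:
    """Hand-built single-cub chain whose sire draws follow `counts`."""
    sires = [s for s in counts if s != UNSAMPLED]
    samples = []
    for label, c in counts.items():
        idx = 0 if label == UNSAMPLED else sires.index(label) + 1
        samples += [idx] * c
    arr = np.array(samples, dtype=np.int16)[:, None]
    dists = np.linspace(100, 100 * len(sires), len(sires))[None, :]
    return PosteriorChain(
        cohort_year=1, cub_ids=["cub"], dam_lists=[[]], sire_list=sires,
        sire_distances=dists, dam_samples=np.zeros((n, 1), dtype=np.int16),
        sire_samples=arr, beta=np.zeros(n), us=np.ones(n),
        ud=np.ones((n, 1)), group_ids=["g"],
        pdc=np.where(arr[:, 0] > 0, dists[0][np.maximum(arr[:, 0] - 1, 0)], np.nan),
    )


class TestSummaries:
    def test_threshold_boundary(self):
        chain = _chain_with_counts({"sA": 790, UNSAMPLED: 210}, 1000)
        out = summarize_assignments(chain, 0.8)
        assert out.iloc[0]["sire_id"] is None  # 0.79 < 0.80
        chain2 = _chain_with_counts({"sA": 800, UNSAMPLED: 200}, 1000)
        out2 = summarize_assignments(chain2, 0.8)
        assert out2.iloc[0]["sire_id"] == "sA"
        assert out2.iloc[0]["sire_prob"] == pytest.approx(0.8)

    def test_high_probability_assigned_at_both_thresholds(self):
        chain = _chain_with_counts({"sA": 950, "sB": 50}, 1000)
        assert summarize_assignments(chain, 0.8).iloc[0]["sire_id"] == "sA"
        assert summarize_assignments(chain, 0.95).iloc[0]["sire_id"] == "sA"

    def test_modal_unsampled_never_assigned(self):
        chain = _chain_with_counts({UNSAMPLED: 900, "sA": 100}, 1000)
        assert summarize_assignments(chain, 0.8).iloc[0]["sire_id"] is None

    def test_assignment_rate_monotone_in_threshold(self, small_world):
        truth, og, panel = (
            small_world["truth"], small_world["genotypes"], small_world["panel"],
        )
        cands, _ = build_candidate_sets(
            small_world["captures"], truth.groups, 10, genotypes=og
        )
        cfg = MCMCConfig(n_iter=4000, burn_in=1000, thin=5, seed=6)
        chain = run_mcmc(cands, og, panel, cfg)
        r80 = summarize_assignments(chain, 0.8)["sire_id"].notna().mean()
        r95 = summarize_assignments(chain, 0.95)["sire_id"].notna().mean()
        assert r95 <= r80

    def test_invalid_threshold_rejected(self):
        chain = _chain_with_counts({"sA": 10}, 10)
        with pytest.raises(ValueError):
            summarize_assignments(chain, 0.5)

    def test_pdc_is_iteration_mean_of_assigned_distances(self):
        chain = _chain_with_counts({"sA": 3, "sB": 2, UNSAMPLED: 5}, 10)
        p = pdc_posterior(chain)
        # sA at 100 m (3 draws), sB at 200 m (2 draws); unsampled iterations drop
        assert sorted(set(p["draws"])) == [100.0, 200.0]
        assert len(p["draws"]) == 5
        assert p["n_dropped_iterations"] == 5
        assert p["mean"] == pytest.approx((3 * 100 + 2 * 200) / 5)
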