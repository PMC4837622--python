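"""Gibbs sampler contracts: truncation, thresholds, location conditionals,
variance draws, missing-data handling, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wstripe.pedigree import Pedigree
from wstripe.simulate import SimulationConfig, simulate_population
from wstripe.threshold_model import (
    McmcConfig,
    ModelError,
    ModelSpec,
    draw_truncated_normal,
    gibbs_run,
    handle_missing,
    sample_threshold,
    solve_mme,
)


# ------------------------------------------------- truncated-normal draws


def test_truncated_draws_respect_interval():
    rng = np.random.default_rng(0)
    for lo, hi in [(-np.inf, 0.0), (0.0, 1.0), (1.0, np.inf), (0.999, 1.001)]:
        x = draw_truncated_normal(rng, mean=0.3, sd=1.2, lo=lo, hi=hi, size=2000)
        assert (x > lo).all() and (x < hi).all()


def test_truncated_mean_matches_closed_form():
    """N(0,1) truncated to (0, ∞): E[X] = φ(0)/(1−Φ(0)) = 0.7979."""
    rng = np.random.default_rng(1)
    x = draw_truncated_normal(rng, 0.0, 1.0, lo=0.0, size=100_000)
    expected = stats.norm.pdf(0) / stats.norm.sf(0)
    se = np.sqrt((1 + 0 * expected - expected**2) / len(x))  # var = 1 − λ(λ−0)
    assert abs(x.mean() - expected) < 3 * np.sqrt(x.var() / len(x))
    assert abs(x.mean() - expected) < 0.01


# ------------------------------------------------------- threshold update


def test_threshold_draw_support():
    rng = np.random.default_rng(2)
    y1 = np.array([-0.5, 0.2, 0.9, 1.1, 2.0])
    code = np.array([0, 1, 1, 2, 2])
    for _ in range(200):
        t2 = sample_threshold(rng, y1, code)
        assert 0.9 < t2 < 1.1


def test_threshold_draw_degenerate_interval():
    rng = np.random.default_rng(3)
    y1 = np.array([0.5, 0.5 + 1e-12])
    code = np.array([1, 2])
    t2 = sample_threshold(rng, y1, code)
    assert 0.5 <= t2 <= 0.5 + 1e-12


def test_empty_category_is_hard_error(small_bivariate_dataset):
    """A WS category with zero observations leaves its threshold
    unidentifiable and must abort the fit."""
    ds = small_bivariate_dataset
    bad = ds.phenotypes.copy()
    bad.loc[bad["WS"] == "MOD", "WS"] = "NORM"  # empty the MOD category
    with pytest.raises(ModelError, match="zero observations"):
        gibbs_run(
            ds.pedigree, bad, ModelSpec(trait1="WS", trait2="BMY"),
            McmcConfig(iterations=200, burnin=50, thin=2, seed=1),
        )


# ------------------------------------------------------- chain bookkeeping


def test_default_schedule_retains_4000_draws():
    cfg = McmcConfig()
    assert cfg.iterations == 100_000
    assert cfg.burnin == 20_000 and cfg.thin == 20
    assert cfg.retained == 4000


def test_reduced_run_retains_expected_draws(small_bivariate_dataset):
    ds = small_bivariate_dataset
    cfg = McmcConfig(iterations=1200, burnin=200, thin=10, seed=5)
    chain = gibbs_run(
        ds.pedigree, ds.phenotypes, ModelSpec(trait1="WS", trait2="BMY"), cfg
    )
    assert len(chain) == cfg.retained == 100
    assert chain.draws["iter"].iloc[0] > cfg.burnin
    assert chain.draws["iter"].iloc[-1] == cfg.iterations


def test_invalid_schedule_rejected():
    with pytest.raises(ValueError):
        McmcConfig(iterations=100, burnin=200)
    with pytest.raises(ValueError):
        McmcConfig(thin=0)


def test_same_seed_identical_chain(small_bivariate_dataset):
    ds = small_bivariate_dataset
    spec = ModelSpec(trait1="WS", trait2="BMY")
    cfg = McmcConfig(iterations=400, burnin=100, thin=3, seed=11)
    a = gibbs_run(ds.pedigree, ds.phenotypes, spec, cfg)
    b = gibbs_run(ds.pedigree, ds.phenotypes, spec, cfg)
    pd.testing.assert_frame_equal(a.draws, b.draws)


# ------------------------------------------- draw-level model invariants


def test_every_retained_draw_is_valid(recovery_chain_rg068):
    _, chain = recovery_chain_rg068
    d = chain.draws
    assert (d["sigma2_e1"] == 1.0).all()  # identifiability constraint
    assert (d["sigma2_g1"] > 0).all() and (d["sigma2_g2"] > 0).all()
    det = d["sigma2_g1"] * d["sigma2_g2"] - d["sigma_g12"] ** 2
    assert (det > 0).all()  # G positive definite at every draw
    detR = d["sigma2_e1"] * d["sigma2_e2"] - d["sigma_e12"] ** 2
    assert (detR > 0).all()
    assert d["rg"].between(-1, 1).all()
    assert d["h2_1"].between(0, 1).all() and d["h2_2"].between(0, 1).all()
    assert (d["t2"] > 0).all()  # above the anchored t1 = 0


def test_threshold_posterior_covers_simulating_value(recovery_chain_rg068):
    ds, chain = recovery_chain_rg068
    t_true = ds.config.thresholds[1]
    t2 = chain.draws["t2"]
    assert abs(t2.mean() - t_true) < 3 * t2.std()


# ----------------------------------------------- location-effect oracles


def _small_continuous_dataset(seed=5):
    cfg = SimulationConfig(
        n_generations=1, base_size=30, sires_per_line=2, dams_per_line=4,
        offspring_per_dam=3, trait_names=("y1", "y2"), liability_trait=None,
        true_G=[[1.0, 0.3], [0.3, 0.8]], true_R=[[1.2, 0.2], [0.2, 1.0]],
        maternal_trait="y2", c2=0.15, selection_trait="y1", seed=seed,
    )
    return simulate_population(cfg)


def test_gibbs_location_means_match_mme_solution():
    """Chain means of all location effects match the dense mixed-model
    equations at fixed variances, within Monte-Carlo error (50-bird case)."""
    ds = _small_continuous_dataset()
    spec = ModelSpec(trait1="y1", trait2="y2", maternal_traits=("y2",))
    G = np.array([[1.0, 0.3], [0.3, 0.8]])
    R = np.array([[1.2, 0.2], [0.2, 1.0]])
    mme = solve_mme(ds.pedigree, ds.phenotypes, spec, G, R, sigma2_c=0.2)
    chain = gibbs_run(
        ds.pedigree, ds.phenotypes, spec,
        McmcConfig(iterations=42_000, burnin=2_000, seed=3,
                   initial={"G": G, "R": R, "sigma2_c": 0.2}, fix_variances=True),
    )
    for key, oracle in mme.items():
        got = np.asarray(chain.effect_means[key])
        assert np.abs(got - np.asarray(oracle)).max() < 0.06, key


def test_vanishing_genetic_variance_recovers_ols():
    """σ²_g → 0: the MME location solution equals ordinary least squares."""
    import statsmodels.formula.api as smf

    ds = _small_continuous_dataset()
    spec = ModelSpec(trait1="y1", trait2=None, maternal_traits=())
    mme = solve_mme(ds.pedigree, ds.phenotypes, spec, [[1e-10]], [[1.0]])
    df = ds.phenotypes.merge(ds.pedigree.table[["id", "hatch", "sex"]], on="id")
    ols = smf.ols("y1 ~ C(hatch) + C(sex)", data=df).fit()
    pred = (
        mme["y1:mu"][0]
        + mme["y1:hatch"][pd.factorize(df["hatch"].astype(str), sort=True)[0]]
        + mme["y1:sex"][pd.factorize(df["sex"].astype(str), sort=True)[0]]
    )
    np.testing.assert_allclose(pred, ols.fittedvalues.to_numpy(), atol=1e-6)


def test_single_bird_shrinkage_closed_form():
    """One founder, no fixed effects: E[a|y] = y·σ²_g/(σ²_g + σ²_e)."""
    ped = Pedigree.from_frame(
        pd.DataFrame(
            {"id": [1], "sire": [0], "dam": [0], "line": ["base"],
             "sex": ["M"], "hatch": [1], "generation": [0]}
        )
    )
    pheno = pd.DataFrame({"id": [1], "y": [2.0]})
    spec = ModelSpec(trait1="y", trait2=None, fixed_effects=(), maternal_traits=())
    mme = solve_mme(ped, pheno, spec, [[0.5]], [[1.0]])
    assert mme["breeding_values"][0, 0] == pytest.approx(2.0 * 0.5 / 1.5)


# ------------------------------------------------------- variance draws


def test_univariate_genetic_draw_matches_scaled_inv_chi2(small_bivariate_dataset):
    """On a founders-only pedigree the G full conditional is the 1×1
    inverse-Wishart = scaled inverse chi-squared; check its moments."""
    rng = np.random.default_rng(0)
    q = 400
    a = rng.standard_normal(q) * 2.0
    Sa = float(a @ a)  # A = I for founders
    nu0, s0 = 2.0, 0.1  # dim + 1 extra df, scale 0.1
    df_post = q + nu0
    draws = stats.invwishart.rvs(df=df_post, scale=s0 + Sa, size=20_000,
                                 random_state=rng)
    oracle = stats.invgamma.rvs(a=df_post / 2, scale=(s0 + Sa) / 2, size=20_000,
                                random_state=np.random.default_rng(1))
    assert np.mean(draws) == pytest.approx(np.mean(oracle), rel=0.02)
    assert np.var(draws) == pytest.approx(np.var(oracle), rel=0.1)


def test_constrained_residual_variance_is_exactly_one(recovery_chain_rg0):
    _, chain = recovery_chain_rg0
    assert (chain.draws["sigma2_e1"] == 1.0).all()


def test_null_genetic_covariance_posterior_covers_zero(recovery_chain_rg0):
    _, chain = recovery_chain_rg0
    rg = chain.draws["rg"]
    assert abs(rg.mean()) < 2 * rg.std()
    lo, hi = np.quantile(rg, [0.025, 0.975])
    assert lo < 0 < hi


def test_independent_residuals_posterior_centered_at_zero():
    """Simulated with σ_e12 = 0: posterior of the residual covariance
    concentrates around 0."""
    cfg = SimulationConfig(
        n_generations=2, base_size=300, sires_per_line=8, dams_per_line=24,
        offspring_per_dam=5, trait_names=("WS", "BMY"),
        true_G=[[1.5, 0.6], [0.6, 1.0]], true_R=[[1.0, 0.0], [0.0, 1.0]],
        selection_trait="BMY", seed=44,
    )
    ds = simulate_population(cfg)
    chain = gibbs_run(
        ds.pedigree, ds.phenotypes, ModelSpec(trait1="WS", trait2="BMY"),
        McmcConfig(iterations=6000, burnin=2000, thin=4, seed=9),
    )
    e12 = chain.draws["sigma_e12"]
    assert abs(e12.mean()) < 3 * e12.std()


# ------------------------------------------------------- missing records


def test_handle_missing_classifies_patterns(small_bivariate_dataset):
    ds = small_bivariate_dataset
    pheno = ds.phenotypes.copy()
    pheno.loc[pheno.index[:50], "BMY"] = np.nan
    pheno.loc[pheno.index[50:80], "WS"] = None
    spec = ModelSpec(trait1="WS", trait2="BMY")
    plan = handle_missing(pheno, spec)
    assert plan.strategy == "augment"
    assert plan.n_trait1_only == 50
    assert plan.n_trait2_only == 30
    assert plan.n_both == len(pheno) - 80


def test_partially_missing_records_still_recover_truth():
    """Mask the co-trait outside the last generation (the study pattern for
    generation-6-only traits).  In an unselected population the augmented
    analysis recovers r_g without bias; records missing one trait still
    inform the liability and the pedigree links.  (Masking the selection
    criterion itself would bias any analysis, so selection is off here.)"""
    g1 = 1.5
    cfg = SimulationConfig(
        n_generations=2, base_size=300, sires_per_line=10, dams_per_line=25,
        offspring_per_dam=5, trait_names=("WS", "BMY"),
        true_G=[[g1, 0.5 * np.sqrt(g1)], [0.5 * np.sqrt(g1), 1.0]],
        true_R=[[1.0, 0.1], [0.1, 1.0]],
        selection_trait="BMY", selection_fraction=1.0,  # random parents
        measured_generations={"BMY": [2]},
        seed=77,
    )
    ds = simulate_population(cfg)
    assert ds.phenotypes["BMY"].isna().any()
    chain = gibbs_run(
        ds.pedigree, ds.phenotypes, ModelSpec(trait1="WS", trait2="BMY"),
        McmcConfig(iterations=8000, burnin=2000, thin=4, seed=10),
    )
    rg = chain.draws["rg"]
    assert abs(rg.mean() - 0.5) < 3 * rg.std()


def test_observed_liability_agrees_with_threshold_fit(small_bivariate_dataset):
    """Replacing the ordinal score by the directly observed liability gives
    the same heritability posterior within Monte-Carlo error."""
    ds = small_bivariate_dataset
    cfg = McmcConfig(iterations=8000, burnin=2000, thin=4, seed=12)
    chain_thr = gibbs_run(
        ds.pedigree, ds.phenotypes, ModelSpec(trait1="WS", trait2="BMY"), cfg
    )
    pheno_cont = ds.phenotypes.copy()
    pheno_cont["liab"] = ds.liabilities["liability"]
    chain_cont = gibbs_run(
        ds.pedigree, pheno_cont.drop(columns="WS"),
        ModelSpec(trait1="liab", trait2="BMY"), cfg,
    )
    h_thr = chain_thr.draws["h2_1"]
    h_cont = chain_cont.draws["h2_1"]
    tol = 2 * np.sqrt(h_thr.std() ** 2 + h_cont.std() ** 2)
    assert abs(h_thr.mean() - h_cont.mean()) < max(tol, 0.05)


# ------------------------------------------------------- intra-line refit


def test_line_restriction_limits_records(small_bivariate_dataset):
    ds = small_bivariate_dataset
    spec = ModelSpec(trait1="WS", trait2="BMY", line="pHu+")
    chain = gibbs_run(
        ds.pedigree, ds.phenotypes, spec,
        McmcConfig(iterations=600, burnin=100, thin=5, seed=2),
    )
    n_line = (ds.pedigree.table["line"] == "pHu+").sum()
    assert chain.n_records == n_line
    assert chain.n_pedigree == len(ds.pedigree)  # A keeps the whole pedigree
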