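"""Model encodings, the IRLS engine, X handling and dominance deviation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from nagwas.assoc import (association_for_variant, dominance_deviation_test,
                          encode_model, fit_logistic, run_association,
                          stratified_x_association)
from nagwas.io import (GenotypeProbabilityMatrix, PhenotypeTable, VariantKey)
from nagwas.simulate import (SimulationSpec, SimVariant, simulate_genotypes,
                             simulate_phenotype)


# ---------------------------------------------------------------------------
# encodings
# ---------------------------------------------------------------------------

def test_autosomal_encodings_from_soft_triple():
    trip = np.array([[0.1, 0.2, 0.7]])
    expect = {"additive": [1.6], "dominant": [0.9], "recessive": [0.7],
              "heterodominant": [0.2]}
    for model, val in expect.items():
        cols, valid = encode_model(trip, model)
        np.testing.assert_allclose(cols[0], val)
        assert valid.all()
    cols, _ = encode_model(trip, "genotypic")
    np.testing.assert_allclose(cols[0], [0.2, 0.7])


def test_hard_het_encodings():
    trip = np.array([[0.0, 1.0, 0.0]])
    vals = {m: encode_model(trip, m)[0][0, 0]
            for m in ("additive", "dominant", "recessive", "heterodominant")}
    assert vals == {"additive": 1.0, "dominant": 1.0, "recessive": 0.0,
                    "heterodominant": 1.0}


def test_x_full_inactivation_male_scale():
    trip = np.array([[0.0, 0.0, 1.0]])  # male carrier, p(B) = 1
    male = np.array([1.0])
    assert encode_model(trip, "additive", male, "X")[0][0, 0] == 2.0
    assert encode_model(trip, "recessive", male, "X")[0][0, 0] == 1.0
    assert encode_model(trip, "heterodominant", male, "X")[0][0, 0] == 0.0
    np.testing.assert_allclose(encode_model(trip, "genotypic", male, "X")[0][0],
                               [0.0, 1.0])


def test_x_missing_sex_dropped():
    trip = np.tile([0.0, 1.0, 0.0], (3, 1))
    sex = np.array([1.0, np.nan, 2.0])
    _, valid = encode_model(trip, "additive", sex, "X")
    assert valid.tolist() == [True, False, True]


# ---------------------------------------------------------------------------
# IRLS engine
# ---------------------------------------------------------------------------

def test_two_by_two_fit_matches_sample_odds_ratio():
    y = np.r_[np.ones(100), np.zeros(100)]
    x = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
    fit = fit_logistic(y, x[:, None])
    assert np.exp(fit.coef[1]) == pytest.approx(3.857, abs=5e-4)
    assert fit.converged


def test_separation_flagged_not_estimated():
    y = np.r_[np.ones(20), np.zeros(20)]
    x = y.copy()
    fit = fit_logistic(y, x[:, None])
    assert not fit.converged


def test_monomorphic_genotype_rejected():
    y = np.r_[np.ones(5), np.zeros(5)]
    with pytest.raises(ValueError, match="monomorphic"):
        fit_logistic(y, np.zeros((10, 1)))


def _neg_loglik(beta, y, design):
    eta = design @ beta
    return -np.sum(y * eta - np.logaddexp(0.0, eta))


def test_irls_matches_independent_optimizer_on_random_data(rng):
    """IRLS coefficients agree with a brute-force ML optimizer to 1e-6."""
    for _ in range(20):
        n = int(rng.integers(60, 200))
        k = int(rng.integers(1, 3))
        geno = rng.dirichlet([1, 1, 1], size=n) @ [0, 1, 2]
        covs = rng.standard_normal((n, k))
        lin = 0.4 * geno - 0.3 + covs @ rng.uniform(-0.5, 0.5, k)
        y = rng.binomial(1, 1 / (1 + np.exp(-lin))).astype(float)
        if y.sum() in (0, n):
            continue
        fit = fit_logistic(y, geno[:, None], covariates=covs)
        if not fit.converged:
            continue
        covs_std = (covs - covs.mean(0)) / covs.std(0)
        design = np.column_stack([np.ones(n), geno, covs_std])
        res = minimize(_neg_loglik, np.zeros(design.shape[1]),
                       args=(y, design), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-6)


def test_hard_call_additive_equals_integer_dosage_fit(rng):
    g = rng.binomial(2, 0.3, size=400)
    probs = np.zeros((400, 3))
    probs[np.arange(400), g] = 1.0
    y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 * g - 0.5)))).astype(float)
    cols, _ = encode_model(probs, "additive")
    f1 = fit_logistic(y, cols)
    f2 = fit_logistic(y, g.astype(float)[:, None])
    np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-12)


def test_null_wald_calibration(rng):
    """|beta| < 3 SE nearly always when status is independent of genotype."""
    n, reps, ok = 5000, 40, 0
    for _ in range(reps):
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = rng.binomial(1, 0.3, size=n).astype(float)
        fit = fit_logistic(y, g[:, None])
        if abs(fit.coef[1]) < 3 * fit.se[1]:
            ok += 1
    assert ok >= reps - 1


def test_genotypic_model_nests_single_df_models(rng):
    """The 2-column genotypic mean space nests every 1-column encoding, so
    its maximized log-likelihood can never fall below theirs."""
    for _ in range(15):
        n = 600
        g = rng.binomial(2, 0.3, size=n)
        probs = np.zeros((n, 3))
        probs[np.arange(n), g] = 1.0
        lin = -0.5 + 0.4 * (g == 1) + 0.6 * (g == 2)
        y = rng.binomial(1, 1 / (1 + np.exp(-lin))).astype(float)
        fits = {}
        for model in ("additive", "dominant", "recessive", "heterodominant",
                      "genotypic"):
            cols, _ = encode_model(probs, model)
            fits[model] = fit_logistic(y, cols)
        if not all(f.converged for f in fits.values()):
            continue
        assert fits["genotypic"].joint_p is not None
        for model in ("additive", "dominant", "recessive", "heterodominant"):
            assert fits["genotypic"].loglik >= fits[model].loglik - 1e-7


def test_or_ci_reconstruction():
    from nagwas.io import AssociationRecord
    rec = AssociationRecord(variant=VariantKey("5", 52080909, "rs77704739",
                                               "T", "C"),
                            model="recessive", beta=np.log(4.32), se=0.2401,
                            p=1.75e-8, hwe_controls_p=0.5, alt_hom_cases=10)
    or_, lo, hi = rec.odds_ratio()
    assert or_ == pytest.approx(4.32, abs=1e-6)
    assert lo == pytest.approx(2.70, abs=0.01)
    assert hi == pytest.approx(6.92, abs=0.01)


# ---------------------------------------------------------------------------
# per-variant driver
# ---------------------------------------------------------------------------

def _cohort(rng, n=2000, maf=0.3, beta=0.0, model="additive"):
    spec = SimulationSpec(n_samples=n, case_fraction=0.3,
                          variants=[SimVariant(maf=maf,
                                               model="null" if beta == 0 else model,
                                               or_=float(np.exp(beta)))],
                          seed=int(rng.integers(2**31 - 1)))
    g, sex = simulate_genotypes(spec)
    phenos = simulate_phenotype(g, spec, sex=sex)
    probs = np.zeros((n, 1, 3))
    probs[np.arange(n), 0, g[:, 0]] = 1.0
    matrix = GenotypeProbabilityMatrix([spec.variants[0].key()],
                                       phenos.samples, probs)
    return matrix, phenos


def test_run_association_attaches_metadata(rng):
    matrix, phenos = _cohort(rng)
    records = run_association(matrix, phenos, models=("additive", "recessive"))
    assert {r.model for r in records} == {"additive", "recessive"}
    for r in records:
        assert 0 <= r.p <= 1
        assert r.maf == pytest.approx(0.3, abs=0.05)
        assert r.n_cases + r.n_controls == 2000
        assert r.alt_hom_cases >= 0 and 0 <= r.hwe_controls_p <= 1


def test_run_association_drops_monomorphic(rng):
    matrix, phenos = _cohort(rng)
    matrix.probs[:, 0, :] = np.tile([1.0, 0, 0], (2000, 1))
    records = run_association(matrix, phenos, models=("additive",))
    assert records == []


# ---------------------------------------------------------------------------
# X chromosome
# ---------------------------------------------------------------------------

def _x_cohort(rng, n=20000, maf=0.25, beta_m=0.4, beta_f=0.4):
    sex = rng.integers(1, 3, size=n).astype(float)
    male = sex == 1
    g = rng.binomial(2, maf, size=n)
    g[male] = rng.binomial(1, maf, size=int(male.sum()))
    enc = np.where(male, 2.0 * g, g)  # full inactivation truth
    beta = np.where(male, beta_m, beta_f)
    y = rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + beta * enc / 2 * 2)))).astype(float)
    probs = np.zeros((n, 1, 3))
    probs[np.arange(n), 0, np.minimum(g, 2)] = 1.0
    probs[male, 0, :] = 0.0
    probs[male, 0, np.minimum(g[male], 1)] = 1.0  # hemizygous on (p0, p1)
    variants = [VariantKey("X", 50_000_000, "rsX", "A", "G")]
    matrix = GenotypeProbabilityMatrix(variants,
                                       [f"sample_{i + 1}" for i in range(n)],
                                       probs)
    df = pd.DataFrame({"status": y, "sex": sex},
                      index=[f"sample_{i + 1}" for i in range(n)])
    return matrix, PhenotypeTable(df)


def test_stratified_matches_pooled_when_effects_equal(rng):
    matrix, phenos = _x_cohort(rng, n=50000, beta_m=0.3, beta_f=0.3)
    strat = stratified_x_association(matrix, phenos, models=("additive",))
    pooled = run_association(matrix, phenos, models=("additive",),
                             apply_filter=False)
    assert strat[0].panel == "x:stratified"
    assert strat[0].beta == pytest.approx(pooled[0].beta, abs=5e-3)


def test_stratified_shared_effect_between_sex_specific(rng):
    matrix, phenos = _x_cohort(rng, n=40000, beta_m=0.5, beta_f=0.0)
    shared = stratified_x_association(matrix, phenos, models=("additive",))[0].beta
    betas = {}
    for code in (1.0, 2.0):
        keep = phenos.sex == code
        sub = GenotypeProbabilityMatrix(matrix.variants,
                                        list(np.array(matrix.samples)[keep]),
                                        matrix.probs[keep])
        subp = PhenotypeTable(phenos.df.loc[keep])
        with pytest.warns(UserWarning, match="single-sex"):
            betas[code] = stratified_x_association(sub, subp,
                                                   models=("additive",))[0].beta
    lo, hi = sorted([betas[1.0], betas[2.0]])
    assert lo - 0.02 <= shared <= hi + 0.02


def test_par_variants_excluded(rng):
    probs = np.tile([0.0, 1.0, 0.0], (100, 1)).reshape(100, 1, 3)
    variants = [VariantKey("X", 1_000_000, "rsPAR", "A", "G")]  # inside PAR1
    matrix = GenotypeProbabilityMatrix(variants,
                                       [f"sample_{i + 1}" for i in range(100)],
                                       probs)
    df = pd.DataFrame({"status": rng.binomial(1, 0.4, 100),
                       "sex": rng.integers(1, 3, 100)}, index=matrix.samples)
    with pytest.warns(UserWarning, match="pseudoautosomal"):
        records = run_association(matrix, PhenotypeTable(df))
    assert records == []


# ---------------------------------------------------------------------------
# dominance deviation
# ---------------------------------------------------------------------------

def test_dominance_deviation_null_uniform(rng):
    """Deviation p-values are uniform when the truth is purely additive."""
    pvals = []
    for _ in range(120):
        spec = SimulationSpec(n_samples=4000, case_fraction=0.3,
                              variants=[SimVariant(maf=0.3, model="additive",
                                                   or_=1.5)],
                              seed=int(rng.integers(2**31 - 1)))
        g, sex = simulate_genotypes(spec)
        phenos = simulate_phenotype(g, spec, sex=sex)
        probs = np.zeros((4000, 3))
        probs[np.arange(4000), g[:, 0]] = 1.0
        p, reason = dominance_deviation_test(probs, phenos, covariate_names=())
        assert reason is None
        pvals.append(p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.001


def test_dominance_deviation_detects_recessive(rng):
    hits = 0
    reps = 30
    for _ in range(reps):
        spec = SimulationSpec(n_samples=20000, case_fraction=0.3,
                              variants=[SimVariant(maf=0.2, model="recessive",
                                                   or_=4.0)],
                              seed=int(rng.integers(2**31 - 1)))
        g, sex = simulate_genotypes(spec)
        phenos = simulate_phenotype(g, spec, sex=sex)
        probs = np.zeros((20000, 3))
        probs[np.arange(20000), g[:, 0]] = 1.0
        p, _ = dominance_deviation_test(probs, phenos, covariate_names=())
        hits += p < 0.05
    assert hits >= 0.8 * reps


def test_dominance_deviation_requires_hets():
    probs = np.tile([1.0, 0.0, 0.0], (50, 1))
    probs[0] = [0, 0, 1]
    df = pd.DataFrame({"status": [1] * 25 + [0] * 25}, index=range(50))
    p, reason = dominance_deviation_test(probs, PhenotypeTable(df),
                                         covariate_names=())
    assert p is None and "heterozygote" in reason
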