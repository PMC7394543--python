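import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinlipid import twin_models as tm
from twinlipid.benchmarks import simulate_pairs
from twinlipid.synthetic_data import SyntheticConfig, simulate_twin_cohort


def _iid_pairs(n=50, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "zygosity": ["MZ"] * (n // 2) + ["DZ"] * (n - n // 2),
            "value1": rng.standard_normal(n),
            "value2": rng.standard_normal(n),
        }
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def test_loglik_reduces_to_independent_normals():
    """With a=c=0, e=1 and a fixed zero mean the pair likelihood equals
    the sum of univariate standard-normal log-densities."""
    pairs = _iid_pairs(seed=1)
    ll = tm.pair_loglik((0.0, 0.0, 1.0), pairs, mean=0.0)
    x = np.concatenate([pairs["value1"], pairs["value2"]])
    assert ll == pytest.approx(stats.norm.logpdf(x).sum(), rel=1e-12)


def test_loglik_singular_covariance_is_minus_inf():
    pairs = pd.DataFrame(
        {"zygosity": ["MZ"], "value1": [0.3], "value2": [0.9]}
    )
    assert tm.pair_loglik((1.0, 0.0, 0.0), pairs) == -np.inf


def test_loglik_gradient_vanishes_at_optimum(big_pairs):
    fit = tm.fit_univariate(big_pairs, "ACE")
    theta = np.array([fit.a, fit.c, fit.e])
    eps = 1e-5
    for i in range(3):
        d = np.zeros(3)
        d[i] = eps
        g = (
            tm.pair_loglik(theta + d, big_pairs)
            - tm.pair_loglik(theta - d, big_pairs)
        ) / (2 * eps)
        assert abs(g) < 0.5  # curvature ~n; relative gradient ~1e-4


# ---------------------------------------------------------------------------
# Univariate fits
# ---------------------------------------------------------------------------

def test_h2_recovery_against_falconer(big_pairs):
    fit = tm.fit_univariate(big_pairs, "ACE")
    assert fit.h2 == pytest.approx(0.5, abs=0.05)
    falc = tm.falconer_h2(
        tm.intraclass_corr(big_pairs.mz), tm.intraclass_corr(big_pairs.dz)
    )
    assert fit.h2 == pytest.approx(falc, abs=0.05)


def test_null_heritability_recovered():
    pairs = simulate_pairs(0.0, 0.3, 5000, seed=21)
    fit = tm.fit_univariate(pairs, "ACE")
    assert fit.h2 < 0.05


def test_ce_matches_ace_on_a_free_data():
    """On A-free data the CE model typically fits as well as ACE: the
    excess log-likelihood is a boundary mixture, zero half the time, so
    its median over replicates is below 0.5."""
    excess = []
    for seed in (22, 23, 24, 25, 26):
        tp = tm.TwinPairs(simulate_pairs(0.0, 0.3, 1000, seed=seed))
        ace = tm.fit_univariate(tp, "ACE")
        ce = tm.fit_univariate(tp, "CE")
        assert ace.loglik >= ce.loglik - 1e-6
        excess.append(ace.loglik - ce.loglik)
    assert np.median(excess) < 0.5


@pytest.mark.parametrize("seed", [31, 32])
def test_model_nesting_loglik_ordering(seed):
    pairs = simulate_pairs(0.4, 0.1, 500, seed=seed)
    tp = tm.TwinPairs(pairs)
    fits = {m: tm.fit_univariate(tp, m) for m in ("ACE", "AE", "CE", "E")}
    tol = 1e-6
    assert fits["ACE"].loglik >= fits["AE"].loglik - tol
    assert fits["AE"].loglik >= fits["E"].loglik - tol
    assert fits["ACE"].loglik >= fits["CE"].loglik - tol
    assert fits["CE"].loglik >= fits["E"].loglik - tol
    for fit in fits.values():
        shares = (fit.h2, fit.c2_std, fit.e2_std)
        assert sum(shares) == pytest.approx(1.0, abs=1e-8)
        assert all(0.0 <= s <= 1.0 for s in shares)


def test_unknown_model_rejected():
    with pytest.raises(ValueError, match="unknown model"):
        tm.fit_univariate(_iid_pairs(), "ADE")


# ---------------------------------------------------------------------------
# h2 significance and confidence intervals
# ---------------------------------------------------------------------------

def _fit_with_ll(model, ll, paths=(0.5, 0.3, 0.8)):
    return tm.VarianceComponentFit(
        model=model, a=paths[0], c=paths[1], e=paths[2], loglik=ll, n_params=4
    )


def test_h2_significance_edge_cases():
    assert tm.h2_significance(_fit_with_ll("ACE", -100.0),
                              _fit_with_ll("CE", -100.0)) == 1.0
    p = tm.h2_significance(_fit_with_ll("ACE", -100.0),
                           _fit_with_ll("CE", -101.92))
    assert p == pytest.approx(stats.chi2.sf(3.84, 1), rel=1e-6)
    assert p == pytest.approx(0.05, abs=0.001)


def test_h2_significance_mixture_halves_p():
    full = _fit_with_ll("ACE", -100.0)
    null = _fit_with_ll("CE", -102.0)
    assert tm.h2_significance(full, null, boundary_mixture=True) == pytest.approx(
        0.5 * tm.h2_significance(full, null)
    )


def test_h2_significance_negative_lr_raises():
    with pytest.raises(RuntimeError, match="refit"):
        tm.h2_significance(_fit_with_ll("ACE", -105.0), _fit_with_ll("CE", -100.0))


def test_profile_ci_contains_estimate_and_narrows(big_pairs):
    fit = tm.fit_univariate(big_pairs, "ACE")
    lo, hi = tm.h2_profile_ci(big_pairs, fit)
    assert lo <= fit.h2 <= hi
    assert 0.0 <= lo and hi <= 1.0
    assert hi - lo < 0.12  # Fisher-information scale at 5000 pairs/group


# ---------------------------------------------------------------------------
# Bivariate Cholesky
# ---------------------------------------------------------------------------

def test_bivariate_duplicated_trait_all_correlations_one(big_cohort):
    cohort, truth = big_cohort
    lip = truth.lipid_names[0]
    pairs = tm.pairs_from_members(cohort, cohort[lip], cohort[lip])
    fit = tm.fit_bivariate_cholesky(pairs)
    assert fit.degenerate
    assert fit.rg == 1.0 and fit.re == 1.0 and fit.rp == 1.0
    # margins coincide with the univariate fit
    uni = tm.fit_univariate(
        pd.DataFrame(
            {
                "zygosity": pairs["zygosity"],
                "value1": pairs["value1"],
                "value2": pairs["value2"],
            }
        )
    )
    assert fit.A[0, 0] == pytest.approx(uni.a2, abs=1e-3)
    assert fit.E[1, 1] == pytest.approx(uni.e2, abs=1e-3)


def _bivariate_cohort(rg_true, re_cross, seed, n=5000, a2=0.5):
    cfg = SyntheticConfig(
        n_mz_pairs=n, n_dz_pairs=n, n_lipids=2, a2=a2, c2=0.0, e2=1.0 - a2,
        rg_matrix=np.array([[1.0, rg_true], [rg_true, 1.0]]),
        re_matrix=np.array([[1.0, re_cross], [re_cross, 1.0]]),
        seed=seed,
    )
    cohort, truth = simulate_twin_cohort(cfg)
    l1, l2 = truth.lipid_names
    return cohort, truth, tm.pairs_from_members(cohort, cohort[l1], cohort[l2])


def test_bivariate_independent_genetics_with_shared_environment():
    cohort, truth, pairs = _bivariate_cohort(0.0, 0.5, seed=41)
    fit = tm.fit_bivariate_cholesky(pairs)
    assert fit.rg == pytest.approx(0.0, abs=0.1)
    assert fit.re == pytest.approx(0.5, abs=0.05)
    # latent-truth oracle: empirical correlation of the stored draws
    g = truth.genetic_latents
    emp_rg = np.corrcoef(g.iloc[:, 0], g.iloc[:, 1])[0, 1]
    assert fit.rg == pytest.approx(emp_rg, abs=0.1)


def test_bivariate_recovers_high_genetic_correlation():
    _, truth, pairs = _bivariate_cohort(0.9, 0.0, seed=42)
    fit = tm.fit_bivariate_cholesky(pairs)
    assert fit.rg == pytest.approx(0.9, abs=0.07)


def test_bivariate_absent_component_reported_as_none():
    # no shared environment simulated: rc undefined, not zero
    _, _, pairs = _bivariate_cohort(0.5, 0.0, seed=43, n=2000)
    fit = tm.fit_bivariate_cholesky(pairs)
    assert fit.rc is None or abs(fit.rc) <= 1.0  # absent when C ~ 0


# ---------------------------------------------------------------------------
# Sex heterogeneity
# ---------------------------------------------------------------------------

def _sexhet_cohort(male, female, n=2000, seed=51):
    cfg = SyntheticConfig(
        n_mz_pairs=n, n_dz_pairs=n, n_lipids=1,
        sex_params={"male": male, "female": female}, seed=seed,
    )
    cohort, truth = simulate_twin_cohort(cfg)
    return tm.pairs_from_members(cohort, cohort[truth.lipid_names[0]])


def test_sexhet_detects_planted_difference():
    male = (np.sqrt(0.1), 0.0, np.sqrt(0.9))
    female = (np.sqrt(0.6), 0.0, np.sqrt(0.4))
    fit = tm.fit_sex_heterogeneity(_sexhet_cohort(male, female))
    assert fit.p_value < 0.01
    assert fit.h2_female > fit.h2_male


def test_sexhet_fits_without_opposite_sex_pairs():
    pairs = _sexhet_cohort(
        (np.sqrt(0.4), 0.0, np.sqrt(0.6)), (np.sqrt(0.4), 0.0, np.sqrt(0.6)),
        n=300, seed=52,
    )
    same_sex = pairs[pairs["sex1"] == pairs["sex2"]]
    fit = tm.fit_sex_heterogeneity(same_sex)
    assert np.isfinite(fit.loglik_het)
    assert fit.loglik_het >= fit.loglik_hom - 1e-6


# ---------------------------------------------------------------------------
# Age moderation
# ---------------------------------------------------------------------------

def test_gxe_nests_plain_ace():
    pairs = simulate_pairs(0.4, 0.1, 400, seed=61)
    rng = np.random.default_rng(61)
    pairs["age"] = rng.uniform(69, 93, len(pairs))
    fit = tm.fit_gxe_age(pairs)
    assert fit.loglik >= fit.loglik_ace - 1e-4
    assert 0.0 <= fit.p_value <= 1.0


def test_gxe_detects_increasing_heritability():
    cfg = SyntheticConfig(
        n_mz_pairs=1500, n_dz_pairs=1500, n_lipids=1,
        age_moderation=(0.4, 0.04, 0.3, 0.0, 0.7, 0.0), seed=62,
    )
    cohort, truth = simulate_twin_cohort(cfg)
    pairs = tm.pairs_from_members(cohort, cohort[truth.lipid_names[0]])
    fit = tm.fit_gxe_age(pairs)
    assert fit.p_value < 0.01
    assert fit.h2_at(90.0) > fit.h2_at(70.0)


def test_gxe_without_age_variation_falls_back():
    pairs = simulate_pairs(0.4, 0.1, 200, seed=63)
    pairs["age"] = 75.0
    with pytest.warns(UserWarning, match="no age variation"):
        fit = tm.fit_gxe_age(pairs)
    assert fit.fallback
    assert fit.lr == 0.0 and fit.p_value == 1.0


# ---------------------------------------------------------------------------
# Falconer estimator
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "r_mz, r_dz, expected", [(0.7, 0.45, 0.5), (0.5, 0.5, 0.0), (0.9, 0.1, 1.0)]
)
def test_falconer_closed_form(r_mz, r_dz, expected):
    assert tm.falconer_h2(r_mz, r_dz) == pytest.approx(expected)


def test_falconer_rejects_out_of_range():
    with pytest.raises(ValueError):
        tm.falconer_h2(1.5, 0.2)
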