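import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinlipid import omics_association as oa


@pytest.mark.parametrize(
    "alpha, n, expected",
    [(0.05, 1, 0.05), (0.01, 100, 1e-4)],
)
def test_bonferroni_simple_cases(alpha, n, expected):
    assert oa.bonferroni_threshold(alpha, n) == pytest.approx(expected)


def test_bonferroni_rejects_bad_inputs():
    with pytest.raises(ValueError):
        oa.bonferroni_threshold(0.0, 10)
    with pytest.raises(ValueError):
        oa.bonferroni_threshold(0.05, 0)


def _clustered_data(n_pairs=100, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"S{j}" for j in range(2 * n_pairs)]
    pair_ids = pd.Series([f"P{j // 2}" for j in range(2 * n_pairs)], index=idx)
    u = np.repeat(rng.standard_normal(n_pairs), 2)
    return rng, idx, pair_ids, u


def test_mixed_model_recovers_near_perfect_probe():
    rng, idx, pair_ids, u = _clustered_data(seed=1)
    y = 0.5 * u + rng.standard_normal(200)
    probe = y + rng.normal(0.0, 0.1, 200)
    lip = pd.DataFrame({"lip": y}, index=idx)
    prb = pd.DataFrame({"prb": probe}, index=idx)
    rec = oa.mixed_model_association(lip, prb, pair_ids).iloc[0]
    # beta is per SD of the probe: corr(y, probe) * sd(y)
    expected = np.corrcoef(y, probe)[0, 1] * y.std(ddof=1)
    assert rec["beta"] == pytest.approx(expected, abs=0.05)
    assert rec["p_value"] < 1e-20
    assert rec["significant"]
    assert rec["direction"] == "positive"


def test_mixed_model_negative_effect_is_inverse():
    rng, idx, pair_ids, u = _clustered_data(seed=2)
    y = 0.5 * u + rng.standard_normal(200)
    prb = pd.DataFrame({"prb": -0.7 * y + rng.normal(0, 0.5, 200)}, index=idx)
    rec = oa.mixed_model_association(
        pd.DataFrame({"lip": y}, index=idx), prb, pair_ids
    ).iloc[0]
    assert rec["beta"] < 0
    assert rec["direction"] == "inverse"


def test_mixed_model_null_pvalues_uniform():
    """p-values under a permutation null pass a KS uniformity check."""
    rng, idx, pair_ids, u = _clustered_data(n_pairs=60, seed=3)
    y = 0.6 * u + rng.standard_normal(120)
    lip = pd.DataFrame({"lip": y}, index=idx)
    pvals = []
    for _ in range(300):
        x = rng.permutation(y) + rng.standard_normal(120)
        prb = pd.DataFrame({"prb": x}, index=idx)
        pvals.append(
            oa.mixed_model_association(lip, prb, pair_ids)["p_value"].iloc[0]
        )
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_lasso_selects_true_probes_few_false():
    rng = np.random.default_rng(4)
    n = 300
    idx = [f"S{j}" for j in range(n)]
    x_true = rng.standard_normal((n, 2))
    noise = rng.standard_normal((n, 50))
    y = x_true @ np.array([0.8, -0.6]) + 0.5 * rng.standard_normal(n)
    probes = pd.DataFrame(
        np.column_stack([x_true, noise]), index=idx,
        columns=[f"p{j}" for j in range(52)],
    )
    selected = oa.select_probes_penalized(pd.Series(y, index=idx), probes, seed=0)
    assert {"p0", "p1"} <= set(selected)
    assert len(set(selected) - {"p0", "p1"}) <= 3


def test_lasso_single_identical_candidate_selected():
    rng = np.random.default_rng(5)
    idx = [f"S{j}" for j in range(100)]
    y = pd.Series(rng.standard_normal(100), index=idx)
    probes = pd.DataFrame({"p0": y.to_numpy()}, index=idx)
    assert oa.select_probes_penalized(y, probes, seed=0) == ["p0"]


def test_lasso_duplicated_probe_keeps_at_least_one():
    rng = np.random.default_rng(6)
    idx = [f"S{j}" for j in range(200)]
    x = rng.standard_normal(200)
    y = pd.Series(0.9 * x + 0.3 * rng.standard_normal(200), index=idx)
    probes = pd.DataFrame({"a": x, "b": x.copy()}, index=idx)
    selected = oa.select_probes_penalized(y, probes, seed=0)
    assert len(set(selected) & {"a", "b"}) >= 1


def test_variance_explained_empty_selection_is_zero():
    rng, idx, pair_ids, u = _clustered_data(seed=7)
    y = pd.Series(0.5 * u + rng.standard_normal(200), index=idx, name="lip")
    rec = oa.variance_explained(y, pd.DataFrame(index=pd.Index(idx)), pair_ids)
    assert rec.mcfadden == 0.0 and rec.nagelkerke == 0.0


def test_variance_explained_matches_ols_r2():
    rng = np.random.default_rng(8)
    n = 1000
    idx = [f"S{j}" for j in range(n)]
    pair_ids = pd.Series([f"P{j // 2}" for j in range(n)], index=idx)
    x = rng.standard_normal(n)
    y = 0.7 * x + rng.normal(0.0, np.sqrt(0.51), n)
    lipid = pd.Series(y, index=idx, name="lip")
    probes = pd.DataFrame({"p0": x}, index=idx)
    rec = oa.variance_explained(lipid, probes, pair_ids)
    xc, yc = x - x.mean(), y - y.mean()
    r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
    assert rec.nagelkerke == pytest.approx(r2, abs=0.05)
    assert 0.0 <= rec.mcfadden <= rec.nagelkerke <= 1.0


def test_variance_explained_noise_probe_changes_little():
    rng = np.random.default_rng(9)
    n = 1000
    idx = [f"S{j}" for j in range(n)]
    pair_ids = pd.Series([f"P{j // 2}" for j in range(n)], index=idx)
    x = rng.standard_normal(n)
    y = pd.Series(0.7 * x + rng.normal(0, 0.71, n), index=idx, name="lip")
    base = oa.variance_explained(y, pd.DataFrame({"p0": x}, index=idx), pair_ids)
    noisy = oa.variance_explained(
        y,
        pd.DataFrame({"p0": x, "junk": rng.standard_normal(n)}, index=idx),
        pair_ids,
    )
    assert abs(noisy.nagelkerke - base.nagelkerke) < 0.02


def test_gwam_constant_matrix_and_shift():
    idx = ["S1", "S2", "S3"]
    betas = pd.DataFrame(0.5, index=idx, columns=["c1", "c2", "c3", "c4"])
    gwam = oa.compute_gwam(betas)
    assert (gwam == 0.5).all()
    shifted = betas.copy()
    shifted.loc["S2"] += 0.1
    g2 = oa.compute_gwam(shifted)
    assert g2["S2"] - g2["S1"] == pytest.approx(0.1)


def test_gwam_hand_computed_fixture_and_mask():
    betas = pd.DataFrame(
        {"c1": [0.2, 0.4], "c2": [0.6, 0.8], "c3": [0.1, 0.9]},
        index=["S1", "S2"],
    )
    gwam = oa.compute_gwam(betas)
    assert gwam["S1"] == pytest.approx(0.3)
    assert gwam["S2"] == pytest.approx(0.7)
    masked = oa.compute_gwam(betas, mask=["c1", "c2"])
    assert masked["S1"] == pytest.approx(0.4)
    with pytest.raises(ValueError, match="empty"):
        oa.compute_gwam(betas, mask=[])
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        oa.compute_gwam(betas + 1.0)


def test_gwam_association_recovers_planted_inverse_effect(small_omics):
    cfg, cohort, truth, _, methylation = small_omics
    gwam = oa.compute_gwam(methylation)
    target = truth.lipid_names[truth.gwam_lipid_idx]
    rec = oa.gwam_association(cohort[[target]], gwam)
    row = rec[rec["lipid"] == target].iloc[0]
    assert row["beta"] < 0
    assert row["p_value"] < 0.05


def test_gwam_association_location_invariant(small_omics):
    _, cohort, truth, _, methylation = small_omics
    target = truth.lipid_names[0]
    g1 = oa.compute_gwam(methylation)
    b1 = oa.gwam_association(cohort[[target]], g1)["beta"].iloc[0]
    b2 = oa.gwam_association(cohort[[target]], g1 + 0.05)["beta"].iloc[0]
    assert b1 == pytest.approx(b2, rel=1e-10)


def test_gwam_association_zero_variance_rejected():
    idx = ["S1", "S2", "S3", "S4"]
    y = pd.DataFrame({"lip": [0.1, 0.4, -0.2, 0.9]}, index=idx)
    with pytest.raises(ValueError, match="zero variance"):
        oa.gwam_association(y, pd.Series(0.5, index=idx))


def test_site_level_association_detects_and_respects_map():
    rng = np.random.default_rng(10)
    idx = [f"S{j}" for j in range(80)]
    y = rng.standard_normal(80)
    responses = pd.DataFrame({"lipA": y}, index=idx)
    cpgs = pd.DataFrame(
        {"cg1": y, "cg2": rng.standard_normal(80)}, index=idx
    )
    # empty map -> no records
    assert oa.site_level_association(responses, cpgs, {}).empty
    out = oa.site_level_association(responses, cpgs, {"lipA": ["cg1", "cg2"]})
    hit = out[out["cpg"] == "cg1"].iloc[0]
    assert hit["suggestive"] and hit["beta"] > 0
    # planted inverse effect recovers its sign
    cpgs["cg3"] = -0.8 * y + rng.normal(0, 0.5, 80)
    out = oa.site_level_association(responses, cpgs, {"lipA": ["cg3"]})
    assert out["beta"].iloc[0] < 0


def test_pseudo_r2_rank_agreement():
    """McFadden and Nagelkerke agree in rank order across effect sizes."""
    rng = np.random.default_rng(11)
    n = 400
    idx = [f"S{j}" for j in range(n)]
    pair_ids = pd.Series([f"P{j // 2}" for j in range(n)], index=idx)
    mcf, nag = [], []
    for beta in (0.1, 0.3, 0.5, 0.7, 0.9):
        x = rng.standard_normal(n)
        y = pd.Series(
            beta * x + rng.normal(0, np.sqrt(1 - beta**2), n), index=idx, name="l"
        )
        rec = oa.variance_explained(y, pd.DataFrame({"p": x}, index=idx), pair_ids)
        mcf.append(rec.mcfadden)
        nag.append(rec.nagelkerke)
    assert stats.spearmanr(mcf, nag).statistic > 0.95
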