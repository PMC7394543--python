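import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twinlipid import lipid_preprocess as lp
from twinlipid.synthetic_data import (
    DEFAULT_QC_SURVIVORS,
    SyntheticConfig,
    simulate_raw_peak_table,
)


# ---------------------------------------------------------------------------
# Nomenclature parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name, cls, n_chains, carbons, double_bonds",
    [
        ("TG(18:0/17:0/18:0)", "TG", 3, 53, 0),
        ("TG (18:0/17:0/18:0)", "TG", 3, 53, 0),
        ("Cer(d17:1/24:1)", "Cer", 2, 41, 2),
        ("LPC(18:1e)", "LPC", 1, 18, 1),
        ("TG(16_0/14_0/18_1)", "TG", 3, 48, 1),
        ("TG(18:1_17:1_22:6)", "TG", 3, 57, 8),
        ("PC(39:3)", "PC", 1, 39, 3),
        ("PE(16:0_20:4)", "PE", 2, 36, 4),
        ("SM(d18:1/16:0)", "SM", 2, 34, 1),
    ],
)
def test_parse_lipid_name_dialects(name, cls, n_chains, carbons, double_bonds):
    sp = lp.parse_lipid_name(name)
    assert sp.lipid_class == cls
    assert len(sp.chains) == n_chains
    assert sp.total_carbons == carbons
    assert sp.total_double_bonds == double_bonds


def test_parse_prefixes_captured():
    cer = lp.parse_lipid_name("Cer(d17:1/24:1)")
    assert cer.chains[0].prefix == "d"
    assert cer.chains[1].prefix == ""
    lpc = lp.parse_lipid_name("LPC(18:1e)")
    assert lpc.chains[0].prefix == "e"


@pytest.mark.parametrize(
    "bad", ["", "XX(18:1)", "TG(18:)", "TG", "TG(18:0/x:0)", "TG(18:0"]
)
def test_parse_errors_name_offending_token(bad):
    with pytest.raises(lp.LipidNameError):
        lp.parse_lipid_name(bad)


@given(
    cls=st.sampled_from(lp.LIPID_CLASSES),
    chains=st.lists(
        st.tuples(
            st.integers(10, 30), st.integers(0, 6), st.sampled_from(["", "d", "e", "p"])
        ),
        min_size=1,
        max_size=3,
    ),
    sep=st.sampled_from(["/", "_"]),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_parse_format_round_trip(cls, chains, sep):
    """parse(format(species)) recovers an identical species."""
    cdb = ":" if sep == "_" else ":"
    species = lp.LipidSpecies(
        raw_name="",
        lipid_class=cls,
        chains=tuple(lp.Chain(c, d, p) for c, d, p in chains),
        chain_separator=sep,
        cdb_separator=cdb,
    )
    rendered = lp.format_lipid_name(species)
    back = lp.parse_lipid_name(rendered)
    assert back.lipid_class == species.lipid_class
    assert back.chains == species.chains
    assert lp.format_lipid_name(back) == rendered


# ---------------------------------------------------------------------------
# Normalisation and CV
# ---------------------------------------------------------------------------

def _mini_peaks():
    return pd.DataFrame(
        {
            "lipid": ["PC(16:0/18:1)", "PC(16:0/18:1)", "TG(16:0/18:1/18:2)"],
            "sample": ["S1", "S2", "S1"],
            "batch": [1, 1, 1],
            "area": [2000.0, 0.0, 600.0],
            "is_area": [1000.0, 1000.0, 400.0],
            "rej": [0, 0, 0],
            "peak_quality": [0.9, 0.9, 0.9],
            "m_score": [6.0, 6.0, 6.0],
        }
    )


def test_normalize_by_internal_standard_ratios():
    out = lp.normalize_by_class_standard(_mini_peaks())
    assert out["normalized"].tolist() == [2.0, 0.0, 1.5]


def test_normalize_missing_standard_lists_sample_and_class():
    peaks = _mini_peaks()
    peaks.loc[0, "is_area"] = 0.0
    with pytest.raises(lp.LipidQCError, match=r"sample S1.*class PC"):
        lp.normalize_by_class_standard(peaks)


def test_compute_cv_known_values():
    assert lp.compute_cv([1.0, 1.0, 1.0]) == 0.0
    assert lp.compute_cv([2.0, 4.0]) == pytest.approx(np.sqrt(2.0) / 3.0, abs=1e-4)


def test_compute_cv_scale_invariant_and_errors():
    vals = [1.2, 3.4, 2.2, 5.1]
    assert lp.compute_cv(vals) == pytest.approx(
        lp.compute_cv([7.0 * v for v in vals])
    )
    with pytest.raises(lp.LipidQCError):
        lp.compute_cv([5.0])
    with pytest.raises(lp.LipidQCError):
        lp.compute_cv([-1.0, 1.0])


# ---------------------------------------------------------------------------
# Filtering and duplicate resolution
# ---------------------------------------------------------------------------

def test_filter_default_fixture_keeps_enumerated_survivors():
    table = simulate_raw_peak_table(SyntheticConfig(seed=0))
    table, _ = lp.resolve_duplicates(table)
    filtered, audit = lp.filter_lipids(table, lp.FilterRules(batches=[1, 2, 3, 4]))
    assert set(filtered["lipid"]) == set(DEFAULT_QC_SURVIVORS)
    rules = {a["lipid"]: a["rule"] for a in audit}
    assert rules["SM(d18:1/16:0)"] == "rej"
    assert rules["PE(16:0/20:4)"] == "peak_quality"
    assert rules["LPC(18:1)"] == "cv"
    assert rules["PI(16:0/18:1)"] == "batch presence"


def test_filter_all_pass_fixture_is_identity_and_idempotent():
    table = simulate_raw_peak_table(SyntheticConfig(seed=0), violations=False)
    filtered, audit = lp.filter_lipids(table)
    assert audit == []
    pd.testing.assert_frame_equal(
        filtered.reset_index(drop=True), table.reset_index(drop=True)
    )
    twice, _ = lp.filter_lipids(filtered)
    pd.testing.assert_frame_equal(
        twice.reset_index(drop=True), filtered.reset_index(drop=True)
    )


def _dup_table(cvs=(0.1, 0.2, 0.3), qualities=None, m_scores=None):
    qualities = qualities or [0.9] * len(cvs)
    m_scores = m_scores or [6.0] * len(cvs)
    rows = []
    for i, (cv, q, m) in enumerate(zip(cvs, qualities, m_scores)):
        mean = 1000.0
        for s, area in zip(
            ["QC1", "QC2", "QC3"], [mean - cv * mean, mean, mean + cv * mean]
        ):
            rows.append(
                dict(lipid="DG(16:0/18:1)", peak_id=f"dup{i}", sample=s, batch=1,
                     area=area, is_area=1000.0, rej=0, peak_quality=q,
                     m_score=m, is_qc=True)
            )
        rows.append(
            dict(lipid="DG(16:0/18:1)", peak_id=f"dup{i}", sample="S1", batch=1,
                 area=100.0 + i, is_area=1000.0, rej=0, peak_quality=q,
                 m_score=m, is_qc=False)
        )
    return pd.DataFrame(rows)


def test_duplicate_resolution_priority_order():
    # lowest CV wins
    out, _ = lp.resolve_duplicates(_dup_table())
    assert set(out["peak_id"]) == {"dup0"}
    # CV tie -> highest quality
    out, _ = lp.resolve_duplicates(
        _dup_table(cvs=(0.1, 0.1), qualities=[0.8, 0.9])
    )
    assert set(out["peak_id"]) == {"dup1"}
    # CV + quality tie -> highest m-score
    out, _ = lp.resolve_duplicates(
        _dup_table(cvs=(0.1, 0.1), qualities=[0.9, 0.9], m_scores=[6.0, 5.0])
    )
    assert set(out["peak_id"]) == {"dup0"}


def test_duplicate_resolution_preserves_survivor_values():
    table = _dup_table()
    before = table[(table["peak_id"] == "dup0") & (table["sample"] == "S1")][
        "area"
    ].iloc[0]
    out, _ = lp.resolve_duplicates(table)
    after = out[out["sample"] == "S1"]["area"].iloc[0]
    assert after == before


def test_duplicate_exact_tie_logged_ambiguous():
    out, audit = lp.resolve_duplicates(_dup_table(cvs=(0.1, 0.1)))
    assert set(out["peak_id"]) == {"dup0"}
    assert any(a["rule"] == "duplicate_tie" for a in audit)


# ---------------------------------------------------------------------------
# Group sums and Friedewald
# ---------------------------------------------------------------------------

def test_group_sums_class_totals_and_empty_class_absent():
    values = pd.DataFrame(
        {
            "Cer(d18:1/16:0)": [1.5, 1.0],
            "Cer(d18:1/24:1)": [2.5, 2.0],
            "TG(16:0/18:1/18:1)": [4.0, 1.0],
        },
        index=["S1", "S2"],
    )
    sums = lp.group_sums(values)
    assert sums.loc["S1", "Total Cer"] == 4.0
    assert sums.loc["S1", "Total TG"] == 4.0  # group of one equals that lipid
    assert "Total LPC" not in sums.columns
    # Cer(d18:1/16:0) has one double bond, Cer(d18:1/24:1) has two
    assert sums.loc["S1", "Total monounsaturated Cer"] == 1.5
    assert sums.loc["S1", "Total polyunsaturated Cer"] == 2.5
    assert sums.loc["S1", "Total polyunsaturated TG"] == 4.0


@pytest.mark.parametrize(
    "tc, hdl, tg, expected",
    [(5.2, 1.3, 1.1, 3.4), (0.0, 0.0, 0.0, 0.0), (4.4, 1.0, 2.2, 2.4)],
)
def test_friedewald_formula(tc, hdl, tg, expected):
    assert lp.friedewald_ldl(tc, hdl, tg) == pytest.approx(expected)


def test_friedewald_negative_flagged_not_nulled():
    with pytest.warns(UserWarning, match="negative"):
        out = lp.friedewald_ldl(1.0, 2.0, 2.2)
    assert out == pytest.approx(-2.0)


# ---------------------------------------------------------------------------
# Residualisation + INT
# ---------------------------------------------------------------------------

def _cov_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"age": rng.uniform(69, 93, n), "bmi": rng.normal(27, 4, n)},
        index=[f"S{i}" for i in range(n)],
    )


def test_residualize_orthogonal_response_is_centered():
    cov = _cov_frame(200)
    rng = np.random.default_rng(1)
    y = pd.Series(rng.standard_normal(200), index=cov.index)
    resid = lp.residualize(y, cov)
    assert abs(resid.mean()) < 1e-10


def test_residualize_exact_linear_response_vanishes():
    cov = _cov_frame(100)
    y = 2.0 * cov["age"] - 0.5 * cov["bmi"] + 3.0
    resid = lp.residualize(y, cov)
    assert np.abs(resid).max() < 1e-8


def test_residualize_removes_confounding():
    cov = _cov_frame(500, seed=2)
    rng = np.random.default_rng(3)
    y = 0.8 * cov["age"] + rng.standard_normal(500)
    resid = lp.residualize(y, cov)
    assert abs(np.corrcoef(resid, cov["age"])[0, 1]) < 1e-8


def test_residualize_rank_deficient_names_columns():
    cov = _cov_frame(50)
    cov["age2"] = cov["age"] * 2.0
    y = pd.Series(np.arange(50.0), index=cov.index)
    with pytest.raises(np.linalg.LinAlgError, match="age"):
        lp.residualize(y, cov)


def test_int_known_quantiles():
    # middle rank of odd n maps to 0
    out = lp.inverse_normal_transform([3.0, 1.0, 2.0])
    assert out[2] == pytest.approx(0.0, abs=1e-12)  # value 2.0 is the median
    # n=5, lowest rank, Blom offset
    out5 = lp.inverse_normal_transform([10.0, 20.0, 30.0, 40.0, 50.0])
    assert out5[0] == pytest.approx(stats.norm.ppf(0.625 / 5.25), abs=1e-9)
    assert out5[0] == pytest.approx(-1.1798, abs=1e-4)


def test_int_mean_zero_and_monotone():
    rng = np.random.default_rng(4)
    x = rng.exponential(2.0, size=201)
    out = lp.inverse_normal_transform(x)
    assert abs(out.mean()) < 1e-6
    assert np.array_equal(np.argsort(x), np.argsort(out))


def test_int_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        lp.inverse_normal_transform([1.0] * 10)


def test_transform_matrix_restores_normality():
    """INT after residualisation leaves near-zero skewness."""
    cov = _cov_frame(300, seed=5)
    rng = np.random.default_rng(6)
    values = pd.DataFrame(
        {
            "TG(16:0/18:1/18:1)": np.exp(
                0.02 * cov["age"] + rng.standard_normal(300)
            )
        },
        index=cov.index,
    )
    table = lp.transform_matrix(values, cov)
    col = table.data.iloc[:, 0]
    assert abs(stats.skew(col)) < 0.05
    assert abs(col.mean()) < 1e-6
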