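"""Lipid-omics association: mixed models, penalized selection, GWAM.

Associations between lipid residuals and probe-level gene expression are
tested one probe at a time with a linear mixed model carrying a random
intercept per twin pair (the only clustering in the design), with
family-wise control by Bonferroni correction over the probe count.
Variance explained by a selected probe set is summarised by the
likelihood-based McFadden and Nagelkerke pseudo-r2; probes enter the
multi-probe model through L1-penalized (lasso) selection with seeded
cross-validation, which guards against overfitting and collinearity.
Genome-wide average methylation (GWAM) is the per-sample mean of retained
CpG beta values; its association with each lipid is an ordinary
regression on the standardized GWAM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
import statsmodels.api as sm

__all__ = [
    "bonferroni_threshold",
    "mixed_model_association",
    "select_probes_penalized",
    "variance_explained",
    "VarianceExplainedRecord",
    "compute_gwam",
    "gwam_association",
    "site_level_association",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test p-value threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _mixed_fit(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """ML fit of a random-intercept model; returns (result, fell_back).

    When the random-effect variance collapses to the boundary (or the fit
    fails outright) the model degenerates to OLS, which is returned
    flagged instead.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, X, groups=groups).fit(reml=False)
            if np.isfinite(res.params).all() and float(np.asarray(res.cov_re)[0, 0]) > 1e-10:
                return res, False
        except (np.linalg.LinAlgError, ValueError):
            pass
    return sm.OLS(y, X).fit(), True


def _wald_record(res, slot: int, n: int, fell_back: bool) -> dict:
    beta = float(res.params[slot])
    se = float(res.bse[slot])
    # t reference with residual df = n - 2 (intercept + probe); documented
    # small-sample choice, conservative relative to the normal reference.
    tstat = beta / se if se > 0 else math.inf
    p = 2.0 * stats.t.sf(abs(tstat), df=max(n - 2, 1))
    return {
        "beta": beta,
        "se": se,
        "statistic": tstat,
        "p_value": float(p),
        "fallback_ols": fell_back,
    }


def mixed_model_association(
    lipids: pd.DataFrame,
    probes: pd.DataFrame,
    pair_ids: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (lipid, probe) mixed-model association with Bonferroni calls.

    Lipid residuals are the response, the standardized probe residual the
    fixed effect, and twin pair the random intercept. The significance
    threshold is alpha divided by the probe count of the supplied matrix.
    Returns one row per (lipid, probe) with beta (per SD of probe), SE,
    statistic, p_value, significant and direction.
    """
    samples = lipids.index.intersection(probes.index)
    if len(samples) < len(lipids.index) or len(samples) < len(probes.index):
        lipids = lipids.loc[samples]
        probes = probes.loc[samples]
    groups = pair_ids.reindex(samples).to_numpy()
    if pd.isna(groups).any():
        raise ValueError("pair_ids missing for some samples")
    threshold = bonferroni_threshold(alpha, probes.shape[1])
    n = len(samples)
    records = []
    for probe in probes.columns:
        x = _standardize(probes[probe].to_numpy(float))
        X = np.column_stack([np.ones(n), x])
        for lipid in lipids.columns:
            y = lipids[lipid].to_numpy(float)
            res, fell_back = _mixed_fit(y, X, groups)
            rec = _wald_record(res, 1, n, fell_back)
            rec.update(
                lipid=lipid,
                probe=probe,
                significant=rec["p_value"] <= threshold,
                direction="positive" if rec["beta"] >= 0 else "inverse",
            )
            records.append(rec)
    cols = [
        "lipid", "probe", "beta", "se", "statistic", "p_value",
        "significant", "direction", "fallback_ols",
    ]
    return pd.DataFrame(records, columns=cols)


def select_probes_penalized(
    lipid: pd.Series,
    probes: pd.DataFrame,
    seed: int = 0,
    n_folds: int = 10,
) -> list[str]:
    """L1-penalized probe selection with seeded k-fold cross-validation.

    Fits a lasso path of the lipid on the standardized candidate probes,
    chooses the penalty minimising CV error, and returns the probes with
    nonzero coefficients (possibly empty). With exactly collinear
    duplicated probes the lasso keeps at least one of the pair; which one
    survives follows scikit-learn's coordinate-descent ordering.
    """
    if probes.shape[1] < 1:
        raise ValueError("need at least one candidate probe")
    X = np.column_stack([_standardize(probes[c].to_numpy(float)) for c in probes])
    y = lipid.reindex(probes.index).to_numpy(float)
    n_folds = min(n_folds, len(y))
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(cv=cv, alphas=60, max_iter=20000, random_state=seed)
        model.fit(X, y)
    return [c for c, coef in zip(probes.columns, model.coef_) if coef != 0.0]


@dataclass
class VarianceExplainedRecord:
    """Likelihood-based pseudo-r2 of a lipid on a selected probe set."""

    lipid: str
    selected_probes: list[str]
    mcfadden: float
    nagelkerke: float
    ll_null: float
    ll_full: float
    fallback_ols: bool = False


def _pseudo_r2(ll_null: float, ll_full: float, n: int) -> tuple[float, float]:
    """McFadden 1 - ll_full/ll_null and Nagelkerke
    (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n)), both clipped to [0, 1]."""
    mcfadden = 1.0 - ll_full / ll_null if ll_null != 0 else 0.0
    ratio = math.exp(min((2.0 / n) * (ll_null - ll_full), 700.0))
    denom = 1.0 - math.exp(min((2.0 / n) * ll_null, 700.0))
    nagelkerke = (1.0 - ratio) / denom if denom > 0 else 0.0
    clip = lambda v: float(min(max(v, 0.0), 1.0))
    return clip(mcfadden), clip(nagelkerke)


def variance_explained(
    lipid: pd.Series,
    selected: pd.DataFrame,
    pair_ids: pd.Series,
) -> VarianceExplainedRecord:
    """Pseudo-r2 of the lipid on the selected probes under ML mixed fits.

    Null and full models both carry the random pair intercept and are
    fitted by ML (not REML) so their log-likelihoods are comparable.
    An empty selection yields both pseudo-r2 equal to zero.
    """
    y = lipid.to_numpy(float)
    n = len(y)
    groups = pair_ids.reindex(lipid.index).to_numpy()
    X0 = np.ones((n, 1))
    res0, fb0 = _mixed_fit(y, X0, groups)
    ll_null = float(res0.llf)
    if selected.shape[1] == 0:
        return VarianceExplainedRecord(
            lipid=str(lipid.name), selected_probes=[], mcfadden=0.0,
            nagelkerke=0.0, ll_null=ll_null, ll_full=ll_null, fallback_ols=fb0,
        )
    X1 = np.column_stack(
        [np.ones(n)]
        + [_standardize(selected[c].reindex(lipid.index).to_numpy(float))
           for c in selected.columns]
    )
    if n <= X1.shape[1] + 2:
        raise ValueError(
            f"too few samples ({n}) for {X1.shape[1]} fixed-effect parameters"
        )
    res1, fb1 = _mixed_fit(y, X1, groups)
    ll_full = float(res1.llf)
    if ll_full < ll_null - 1e-6:
        raise RuntimeError(
            "full-model likelihood below the null likelihood; refit needed "
            f"(ll_full={ll_full:.4f}, ll_null={ll_null:.4f})"
        )
    mcf, nag = _pseudo_r2(ll_null, ll_full, n)
    return VarianceExplainedRecord(
        lipid=str(lipid.name),
        selected_probes=list(selected.columns),
        mcfadden=mcf,
        nagelkerke=nag,
        ll_null=ll_null,
        ll_full=ll_full,
        fallback_ols=fb0 or fb1,
    )


def compute_gwam(betas: pd.DataFrame, mask=None) -> pd.Series:
    """Genome-wide average methylation: per-sample unweighted mean of
    retained CpG beta values.

    ``mask`` is an iterable of probe ids to retain (supporting exclusion
    of sex-chromosome, SNP-containing and cross-reactive probes); the
    default retains all probes.
    """
    vals = betas.to_numpy(float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    if mask is not None:
        mask = list(mask)
        if not mask:
            raise ValueError("probe mask is empty")
        missing = set(mask) - set(betas.columns)
        if missing:
            raise ValueError(f"mask probes absent from matrix: {sorted(missing)[:5]}")
        betas = betas[mask]
    return betas.mean(axis=1).rename("gwam")


def gwam_association(lipids: pd.DataFrame | pd.Series, gwam: pd.Series) -> pd.DataFrame:
    """Per-lipid regression of lipid residuals on standardized GWAM.

    Returns slope (per SD of GWAM), SE, t, p and McFadden pseudo-r2 from
    the OLS log-likelihoods. Adding a constant to all beta values leaves
    the standardized GWAM, hence the slope, unchanged.
    """
    if isinstance(lipids, pd.Series):
        lipids = lipids.to_frame()
    samples = lipids.index.intersection(gwam.index)
    lipids = lipids.loc[samples]
    g = gwam.loc[samples].to_numpy(float)
    if g.std(ddof=1) == 0:
        raise ValueError("GWAM has zero variance")
    X = np.column_stack([np.ones(len(samples)), _standardize(g)])
    records = []
    for lipid in lipids.columns:
        y = lipids[lipid].to_numpy(float)
        res = sm.OLS(y, X).fit()
        ll_null = float(sm.OLS(y, X[:, :1]).fit().llf)
        mcf, _ = _pseudo_r2(ll_null, float(res.llf), len(y))
        records.append(
            {
                "lipid": lipid,
                "beta": float(res.params[1]),
                "se": float(res.bse[1]),
                "t": float(res.tvalues[1]),
                "p_value": float(res.pvalues[1]),
                "mcfadden": mcf,
            }
        )
    return pd.DataFrame(records)


def site_level_association(
    responses: pd.DataFrame,
    cpgs: pd.DataFrame,
    site_map: dict[str, list[str]],
    pair_ids: pd.Series | None = None,
    suggestive_alpha: float = 0.05,
) -> pd.DataFrame:
    """Targeted CpG-site associations near lipid-associated transcripts.

    ``site_map`` restricts the tests to the CpGs near each response's
    associated transcripts (response may be a lipid or an expression
    probe). The same regression machinery as the probe associations is
    used (mixed model when pair ids are given, OLS otherwise); unadjusted
    p < ``suggestive_alpha`` is flagged "suggestive", mirroring targeted
    usage that avoids an epigenome-wide correction burden.
    """
    records = []
    if not site_map:
        return pd.DataFrame(
            columns=["response", "cpg", "beta", "se", "statistic", "p_value",
                     "suggestive"]
        )
    for response, sites in site_map.items():
        if response not in responses.columns:
            raise KeyError(f"response {response!r} absent from matrix")
        for site in sites:
            if site not in cpgs.columns:
                raise KeyError(f"CpG {site!r} absent from matrix")
            samples = responses.index.intersection(cpgs.index)
            y = responses.loc[samples, response].to_numpy(float)
            x = _standardize(cpgs.loc[samples, site].to_numpy(float))
            X = np.column_stack([np.ones(len(samples)), x])
            if pair_ids is not None:
                res, fell_back = _mixed_fit(y, X, pair_ids.reindex(samples).to_numpy())
            else:
                res, fell_back = sm.OLS(y, X).fit(), False
            rec = _wald_record(res, 1, len(samples), fell_back)
            records.append(
                {
                    "response": response,
                    "cpg": site,
                    "beta": rec["beta"],
                    "se": rec["se"],
                    "statistic": rec["statistic"],
                    "p_value": rec["p_value"],
                    "suggestive": rec["p_value"] < suggestive_alpha,
                }
            )
    return pd.DataFrame(records)
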