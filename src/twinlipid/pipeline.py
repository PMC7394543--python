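"""Stage orchestration shared by the CLI and scripted use.

Thin wrappers that run a whole stage over a trait matrix: per-lipid
heritability tables, pairwise genetic/environmental correlations, and the
expression/GWAM association stages, each returning tidy DataFrames ready
to write.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import twin_models as tm
from . import omics_association as oa
from .lipid_preprocess import parse_lipid_name, LipidNameError

__all__ = [
    "heritability_table",
    "correlation_table",
    "sexhet_table",
    "gxe_table",
    "expression_association_stage",
    "gwam_stage",
]


def _lipid_class_or_none(name: str) -> str | None:
    try:
        return parse_lipid_name(name).lipid_class
    except LipidNameError:
        return None


def heritability_table(
    residuals: pd.DataFrame,
    members: pd.DataFrame,
    alpha: float = 0.05,
    boundary_mixture: bool = False,
    with_ci: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit ACE/AE/CE/E per lipid; report all four with the AIC-best flagged.

    One row per (lipid, model) with components, standardized shares, h2
    with its profile CI (ACE row), the additive-component LRT p-value,
    log-likelihood and AIC.
    """
    rows = []
    for lipid in residuals.columns:
        pairs = tm.pairs_from_members(members, residuals[lipid])
        tp = tm.TwinPairs(pairs)
        fits = {m: tm.fit_univariate(tp, m, seed=seed) for m in
                ("ACE", "AE", "CE", "E")}
        p_h2 = tm.h2_significance(fits["ACE"], fits["CE"],
                                  boundary_mixture=boundary_mixture)
        ci = tm.h2_profile_ci(tp, fits["ACE"]) if with_ci else (np.nan, np.nan)
        best = min(fits, key=lambda m: fits[m].aic)
        for model, fit in fits.items():
            rows.append(
                {
                    "lipid": lipid,
                    "lipid_class": _lipid_class_or_none(lipid),
                    "model": model,
                    "a2": fit.a2,
                    "c2": fit.c2,
                    "e2": fit.e2,
                    "h2": fit.h2,
                    "c2_std": fit.c2_std,
                    "e2_std": fit.e2_std,
                    "ci_lo": ci[0] if model == "ACE" else np.nan,
                    "ci_hi": ci[1] if model == "ACE" else np.nan,
                    "p_h2": p_h2 if model == "ACE" else np.nan,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "aic_best": model == best,
                }
            )
    return pd.DataFrame(rows)


def correlation_table(
    residuals: pd.DataFrame,
    members: pd.DataFrame,
    lipids: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bivariate Cholesky correlations for every pair of the given lipids."""
    lipids = list(lipids or residuals.columns)
    rows = []
    for i, l1 in enumerate(lipids):
        for l2 in lipids[i + 1:]:
            pairs = tm.pairs_from_members(members, residuals[l1], residuals[l2])
            try:
                fit = tm.fit_bivariate_cholesky(pairs, seed=seed)
            except RuntimeError as err:
                warnings.warn(f"bivariate fit failed for ({l1}, {l2}): {err}")
                continue
            rows.append(
                {
                    "trait1": l1, "trait2": l2,
                    "rg": fit.rg, "rc": fit.rc, "re": fit.re, "rp": fit.rp,
                    "loglik": fit.loglik, "degenerate": fit.degenerate,
                }
            )
    return pd.DataFrame(rows)


def sexhet_table(
    residuals: pd.DataFrame, members: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Sex-heterogeneity fit per lipid: per-sex paths, h2 and the
    path-equality LRT."""
    rows = []
    for lipid in residuals.columns:
        pairs = tm.pairs_from_members(members, residuals[lipid])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = tm.fit_sex_heterogeneity(pairs, seed=seed)
        rows.append(
            {
                "lipid": lipid,
                "h2_male": fit.h2_male,
                "h2_female": fit.h2_female,
                "loglik_het": fit.loglik_het,
                "loglik_hom": fit.loglik_hom,
                "lr": fit.lr,
                "df": fit.df,
                "p_value": fit.p_value,
            }
        )
    return pd.DataFrame(rows)


def gxe_table(
    residuals: pd.DataFrame, members: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Age-moderation fit per lipid with h2 at the age extremes."""
    rows = []
    for lipid in residuals.columns:
        pairs = tm.pairs_from_members(members, residuals[lipid])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = tm.fit_gxe_age(pairs, seed=seed)
        grid = fit.h2_grid
        rows.append(
            {
                "lipid": lipid,
                "a1": fit.a1,
                "c1": fit.c1,
                "e1": fit.e1,
                "h2_youngest": grid["h2"].iloc[0] if grid is not None else np.nan,
                "h2_oldest": grid["h2"].iloc[-1] if grid is not None else np.nan,
                "lr": fit.lr,
                "df": fit.df,
                "p_value": fit.p_value,
            }
        )
    return pd.DataFrame(rows)


def expression_association_stage(
    residuals: pd.DataFrame,
    expression: pd.DataFrame,
    members: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed-model lipid-probe associations plus per-lipid variance explained.

    For each lipid with at least one Bonferroni-significant probe, the
    significant probes are reduced by penalized selection and the
    selected set's McFadden/Nagelkerke pseudo-r2 computed.
    """
    pair_ids = members["pair_id"]
    assoc = oa.mixed_model_association(residuals, expression, pair_ids, alpha=alpha)
    ve_rows = []
    for lipid, grp in assoc.groupby("lipid", sort=False):
        hits = grp.loc[grp["significant"], "probe"].tolist()
        if hits:
            selected = oa.select_probes_penalized(
                residuals[lipid], expression[hits], seed=seed
            )
        else:
            selected = []
        rec = oa.variance_explained(
            residuals[lipid], expression[selected], pair_ids
        )
        ve_rows.append(
            {
                "lipid": lipid,
                "n_significant": len(hits),
                "n_selected": len(selected),
                "selected_probes": ";".join(selected),
                "mcfadden": rec.mcfadden,
                "nagelkerke": rec.nagelkerke,
                "ll_null": rec.ll_null,
                "ll_full": rec.ll_full,
            }
        )
    return assoc, pd.DataFrame(ve_rows)


def gwam_stage(
    residuals: pd.DataFrame,
    methylation: pd.DataFrame,
    mask=None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Compute GWAM and regress every lipid on it."""
    gwam = oa.compute_gwam(methylation, mask=mask)
    return gwam, oa.gwam_association(residuals, gwam)
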