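"""Summary artifacts: stratifications, set comparisons, cohort table.

Derives the report-level views of the analysis: triglyceride saturation
and carbon-number stratifications, transcript association-count bins,
heritable versus non-heritable transcript-set comparisons with direction
tallies, the MZ/DZ cohort characteristics table, and the per-class
heritability summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .lipid_preprocess import LipidSpecies, parse_lipid_name

__all__ = [
    "classify_saturation",
    "classify_carbons",
    "count_association_bins",
    "heritable_vs_nonheritable_sets",
    "SetComparison",
    "cohort_table",
    "welch_t_from_summary",
    "chi2_from_counts",
    "heritability_summary",
    "plot_h2_by_class",
    "plot_h2_vs_variance_explained",
]

ASSOCIATION_BINS = ("1-2", "3-8", ">8")


def _as_species(species) -> LipidSpecies:
    if isinstance(species, LipidSpecies):
        return species
    return parse_lipid_name(str(species))


def classify_saturation(species) -> str:
    """saturated (0 double bonds) / monounsaturated (1) /
    polyunsaturated (>= 2), over all chains."""
    db = _as_species(species).total_double_bonds
    if db == 0:
        return "saturated"
    if db == 1:
        return "monounsaturated"
    return "polyunsaturated"


def classify_carbons(species) -> str:
    """Total-carbon class: low (< 49), medium (49-55), high (>= 56)."""
    c = _as_species(species).total_carbons
    if c < 49:
        return "low"
    if c <= 55:
        return "medium"
    return "high"


def _bin_label(count: int) -> str:
    if count <= 2:
        return "1-2"
    if count <= 8:
        return "3-8"
    return ">8"


def count_association_bins(
    associations: pd.DataFrame, stratification: Mapping[str, str]
) -> pd.DataFrame:
    """Bin transcripts by how many lipids of each stratum they hit.

    ``associations`` needs columns lipid, probe and significant;
    ``stratification`` maps lipid -> stratum (saturation or carbon
    class). Within each stratum, every transcript is counted once, binned
    by its number of distinct significantly-associated lipids in that
    stratum (1-2, 3-8, > 8).
    """
    sig = associations[associations["significant"].astype(bool)]
    rows = []
    strata = sorted(set(stratification.values()))
    for stratum in strata:
        lipids = {l for l, s in stratification.items() if s == stratum}
        sub = sig[sig["lipid"].isin(lipids)]
        counts = sub.groupby("probe")["lipid"].nunique()
        binned = {b: 0 for b in ASSOCIATION_BINS}
        for c in counts:
            binned[_bin_label(int(c))] += 1
        rows.append({"stratum": stratum, **binned})
    return pd.DataFrame(rows, columns=["stratum", *ASSOCIATION_BINS])


@dataclass
class SetComparison:
    """Transcript sets unique to / shared between two lipid groups, with
    positive vs inverse association direction tallies per set."""

    unique_heritable: set = field(default_factory=set)
    unique_nonheritable: set = field(default_factory=set)
    shared: set = field(default_factory=set)
    directions: pd.DataFrame | None = None


def heritable_vs_nonheritable_sets(
    associations: pd.DataFrame, heritable: Mapping[str, bool]
) -> SetComparison:
    """Partition significantly-associated transcripts by lipid heritability.

    Transcripts associated only with heritable lipids, only with
    non-heritable lipids, and with both; the partition is disjoint and
    covers the union. Direction tallies count associations (positive vs
    inverse) within each set.
    """
    sig = associations[associations["significant"].astype(bool)].copy()
    sig["heritable"] = sig["lipid"].map(lambda l: bool(heritable.get(l, False)))
    her = set(sig.loc[sig["heritable"], "probe"])
    non = set(sig.loc[~sig["heritable"], "probe"])
    comp = SetComparison(
        unique_heritable=her - non,
        unique_nonheritable=non - her,
        shared=her & non,
    )
    rows = []
    for name, probe_set in (
        ("unique_heritable", comp.unique_heritable),
        ("unique_nonheritable", comp.unique_nonheritable),
        ("shared", comp.shared),
    ):
        sub = sig[sig["probe"].isin(probe_set)]
        rows.append(
            {
                "set": name,
                "n_transcripts": len(probe_set),
                "positive": int((sub["direction"] == "positive").sum()),
                "inverse": int((sub["direction"] == "inverse").sum()),
            }
        )
    comp.directions = pd.DataFrame(rows)
    return comp


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch two-sample t statistic and p-value from printed summaries,
    with the Welch-Satterthwaite degrees of freedom."""
    v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi2_from_counts(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency
    table of counts."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def cohort_table(
    members: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
    group_col: str = "zygosity",
    welch: bool = True,
) -> pd.DataFrame:
    """MZ-versus-DZ characteristics table.

    Continuous variables are compared by a two-sample t test (Welch,
    unequal variances, by default; pooled by ``welch=False``) and
    reported as mean (SD); categorical variables by a Pearson chi-square
    without continuity correction, reported as n (%). Variables with a
    group of fewer than two observations are skipped with a warning row.
    """
    groups = list(pd.unique(members[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected two groups in {group_col!r}, got {groups}")
    g1, g2 = groups
    rows = []
    for var in continuous:
        sub = members[[group_col, var]].dropna()
        x1 = sub.loc[sub[group_col] == g1, var].to_numpy(float)
        x2 = sub.loc[sub[group_col] == g2, var].to_numpy(float)
        if len(x1) < 2 or len(x2) < 2:
            rows.append({"variable": var, "skipped": True})
            continue
        t, p = stats.ttest_ind(x1, x2, equal_var=not welch)
        rows.append(
            {
                "variable": var,
                f"{g1}": f"{x1.mean():.2f} ({x1.std(ddof=1):.2f})",
                f"{g2}": f"{x2.mean():.2f} ({x2.std(ddof=1):.2f})",
                "statistic": float(t),
                "p_value": float(p),
                "test": "welch_t" if welch else "pooled_t",
                "skipped": False,
            }
        )
    for var in categorical:
        sub = members[[group_col, var]].dropna()
        counts = pd.crosstab(sub[group_col], sub[var]).reindex([g1, g2])
        if counts.to_numpy().sum(axis=1).min() < 2 or counts.shape[1] < 2:
            rows.append({"variable": var, "skipped": True})
            continue
        chi2, p = chi2_from_counts(counts.to_numpy())
        pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
        fmt = lambda g: ", ".join(
            f"{counts.loc[g, c]} ({pct.loc[g, c]:.0f}%)" for c in counts.columns
        )
        rows.append(
            {
                "variable": var,
                f"{g1}": fmt(g1),
                f"{g2}": fmt(g2),
                "statistic": chi2,
                "p_value": float(p),
                "test": "chi2",
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def heritability_summary(
    fits: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Counts and percentages of significantly heritable lipids.

    ``fits`` needs columns lipid, h2 and p_h2, optionally lipid_class.
    Percentages are rounded to one decimal. Medians over empty sets are
    reported as None.
    """
    sig = fits["p_h2"] < alpha
    n_total = len(fits)
    n_sig = int(sig.sum())
    med = lambda s: (float(np.median(s)) if len(s) else None)
    out = {
        "n_total": n_total,
        "n_significant": n_sig,
        "percent_heritable": round(100.0 * n_sig / n_total, 1) if n_total else 0.0,
        "median_h2_significant": med(fits.loc[sig, "h2"]),
        "median_h2_nonsignificant": med(fits.loc[~sig, "h2"]),
    }
    if "lipid_class" in fits.columns:
        per_class = []
        for cls, grp in fits.groupby("lipid_class", sort=True):
            k = int((grp["p_h2"] < alpha).sum())
            per_class.append(
                {
                    "lipid_class": cls,
                    "n_total": len(grp),
                    "n_significant": k,
                    "percent_heritable": round(100.0 * k / len(grp), 1),
                    "median_h2_significant": med(grp.loc[grp["p_h2"] < alpha, "h2"]),
                }
            )
        out["per_class"] = per_class
    return out


def plot_h2_by_class(fits: pd.DataFrame, alpha: float = 0.05, path=None):
    """Strip/box plot of per-lipid h2 grouped by lipid class, with
    significantly heritable lipids emphasised. Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    classes = sorted(fits["lipid_class"].dropna().unique())
    rng = np.random.default_rng(0)
    data = [fits.loc[fits["lipid_class"] == c, "h2"] for c in classes]
    ax.boxplot(data, tick_labels=classes, showfliers=False)
    for i, cls in enumerate(classes, start=1):
        sub = fits[fits["lipid_class"] == cls]
        x = i + rng.uniform(-0.15, 0.15, len(sub))
        sig = sub["p_h2"] < alpha
        ax.scatter(x[~sig.to_numpy()], sub.loc[~sig, "h2"], s=12, c="0.6")
        ax.scatter(x[sig.to_numpy()], sub.loc[sig, "h2"], s=16, c="k")
    ax.set_ylabel("heritability $h^2$")
    ax.set_xlabel("lipid class")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_h2_vs_variance_explained(
    fits: pd.DataFrame, variance_explained: pd.DataFrame, path=None
):
    """Scatter of h2 against Nagelkerke pseudo-r2 per lipid, with the
    Pearson correlation annotated. Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = fits.merge(variance_explained, on="lipid")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(merged["h2"], merged["nagelkerke"], s=18, c="k")
    if len(merged) >= 3:
        r = float(np.corrcoef(merged["h2"], merged["nagelkerke"])[0, 1])
        ax.set_title(f"Pearson r = {r:.2f}")
    ax.set_xlabel("heritability $h^2$")
    ax.set_ylabel("variance explained (Nagelkerke $r^2$)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
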