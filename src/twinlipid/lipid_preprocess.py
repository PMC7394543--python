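"""Lipid nomenclature parsing, peak-table QC and trait transformations.

This module covers the steps between an integrated, identified LC-MS peak
table and the trait matrix a twin analysis consumes:

* parsing shorthand lipid names (``TG(18:0/17:0/18:0)``, ``Cer(d17:1/24:1)``,
  ``LPC(18:1e)``) into class / acyl-chain structure,
* internal-standard normalisation, coefficient-of-variation computation,
  QC filtering (rej flag, peak quality, QC-injection CV, batch presence)
  and duplicate-identification resolution,
* class and saturation-class group sums, Friedewald LDL-C,
* covariate residualisation followed by rank-based inverse normal
  transformation (INT).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LIPID_CLASSES",
    "Chain",
    "LipidSpecies",
    "LipidNameError",
    "LipidQCError",
    "FilterRules",
    "parse_lipid_name",
    "format_lipid_name",
    "normalize_by_class_standard",
    "compute_cv",
    "filter_lipids",
    "resolve_duplicates",
    "group_sums",
    "friedewald_ldl",
    "residualize",
    "inverse_normal_transform",
    "transform_matrix",
    "ResidualTable",
    "PEAK_TABLE_COLUMNS",
]

#: Lipid class vocabulary: ceramide, cholesteryl ester, diacylglycerol,
#: lysophosphatidylcholine, phosphatidylcholine, phosphatidylethanolamine,
#: phosphatidylinositol, sphingomyelin, triglyceride.
LIPID_CLASSES = ("Cer", "CE", "DG", "LPC", "PC", "PE", "PI", "SM", "TG")

#: Required columns of a long-format peak table (one row per lipid ID per
#: sample); ``peak_id`` distinguishes duplicate identifications of the same
#: annotation, ``is_qc`` flags repeated QC-standard injections.
PEAK_TABLE_COLUMNS = (
    "lipid",
    "sample",
    "batch",
    "area",
    "is_area",
    "rej",
    "peak_quality",
    "m_score",
)


class LipidNameError(ValueError):
    """Raised when a shorthand lipid name cannot be parsed."""


class LipidQCError(ValueError):
    """Raised when QC preconditions (internal standards, CV inputs) fail."""


@dataclass(frozen=True)
class Chain:
    """One acyl/sphingoid chain: carbons, double bonds and an optional
    prefix (``d`` sphingoid base, ``e`` ether, ``p`` plasmalogen)."""

    carbons: int
    double_bonds: int
    prefix: str = ""  # "", "d", "e" or "p"


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed shorthand lipid name.

    ``chain_separator`` and ``cdb_separator`` record the dialect the name
    was written in ("/" vs "_" between chains; ":" vs "_" between carbons
    and double bonds) so that formatting round-trips.
    """

    raw_name: str
    lipid_class: str
    chains: tuple[Chain, ...]
    chain_separator: str = "/"
    cdb_separator: str = ":"

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)


def _parse_chain(token: str, cdb_sep: str) -> Chain:
    tok = token.strip()
    prefix = ""
    if tok[:1] in ("d", "e", "p"):
        prefix, tok = tok[0], tok[1:]
    elif tok[-1:] in ("d", "e", "p"):
        prefix, tok = tok[-1], tok[:-1]
    parts = tok.split(cdb_sep)
    if len(parts) != 2 or not parts[0].isdigit() or not parts[1].isdigit():
        raise LipidNameError(f"malformed acyl chain token {token!r}")
    return Chain(int(parts[0]), int(parts[1]), prefix)


def parse_lipid_name(raw_name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into class and chain composition.

    Accepts both chain-separator dialects ("/" and "_") and both
    carbons/double-bond separators (":" and "_"), e.g.
    ``TG(18:0/17:0/18:0)``, ``TG(16_0/14_0/18_1)``, ``TG(18:1_17:1_22:6)``,
    ``Cer(d17:1/24:1)``, ``LPC(18:1e)`` and ``PC(39:3)`` (summed
    composition, single pseudo-chain).
    """
    if not raw_name or not raw_name.strip():
        raise LipidNameError("empty lipid name")
    name = raw_name.strip()
    # split "CLASS(inner)" or "CLASS inner" (published tables use both)
    if "(" in name:
        cls, _, rest = name.partition("(")
        if not rest.endswith(")"):
            raise LipidNameError(f"unbalanced parentheses in {raw_name!r}")
        inner = rest[:-1]
    else:
        # bare form, e.g. "TG18:1_17:1_22:6"
        for known in sorted(LIPID_CLASSES, key=len, reverse=True):
            if name.startswith(known):
                cls, inner = known, name[len(known):]
                break
        else:
            cls, inner = name, ""
    cls = cls.strip()
    if cls not in LIPID_CLASSES:
        raise LipidNameError(
            f"unknown lipid class token {cls!r} in {raw_name!r} "
            f"(expected one of {', '.join(LIPID_CLASSES)})"
        )
    inner = inner.strip()
    if not inner:
        raise LipidNameError(f"no chain specification in {raw_name!r}")

    if "/" in inner:
        chain_sep, tokens = "/", inner.split("/")
    elif "_" in inner:
        underscore_tokens = inner.split("_")
        if all(":" in t for t in underscore_tokens):
            # "18:1_17:1_22:6": underscores separate chains
            chain_sep, tokens = "_", underscore_tokens
        elif len(underscore_tokens) == 2:
            # "16_0": underscore separates carbons from double bonds
            chain_sep, tokens = "/", [inner]
        else:
            raise LipidNameError(f"ambiguous chain specification in {raw_name!r}")
    else:
        chain_sep, tokens = "/", [inner]

    cdb_sep = ":" if any(":" in t for t in tokens) else "_"
    chains = tuple(_parse_chain(t, cdb_sep) for t in tokens)
    return LipidSpecies(
        raw_name=name,
        lipid_class=cls,
        chains=chains,
        chain_separator=chain_sep,
        cdb_separator=cdb_sep,
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Render a parsed species back to shorthand in its own dialect.

    The sphingoid ``d`` prefix is written leading (``d18:1``); ether and
    plasmalogen marks trailing (``18:1e``), matching common usage.
    """
    rendered = []
    for ch in species.chains:
        core = f"{ch.carbons}{species.cdb_separator}{ch.double_bonds}"
        if ch.prefix == "d":
            rendered.append(f"d{core}")
        elif ch.prefix:
            rendered.append(f"{core}{ch.prefix}")
        else:
            rendered.append(core)
    return f"{species.lipid_class}({species.chain_separator.join(rendered)})"


# ---------------------------------------------------------------------------
# Peak-table QC
# ---------------------------------------------------------------------------

def normalize_by_class_standard(
    peaks: pd.DataFrame,
    standards: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Normalise peak areas by the class internal-standard area.

    Every peak area is divided by the internal-standard area for that
    lipid's class in the same sample. If ``standards`` maps class -> IS
    lipid name, IS areas are looked up from the standard's own rows
    (matched on sample and batch); otherwise the table's ``is_area``
    column is used directly. Returns a copy with a ``normalized`` column.

    Raises :class:`LipidQCError` listing every (sample, class) whose
    internal standard is missing or has non-positive area.
    """
    out = peaks.copy()
    if standards:
        classes = out["lipid"].map(lambda n: parse_lipid_name(n).lipid_class)
        is_rows = out[out["lipid"].isin(set(standards.values()))]
        lookup = {
            (r.sample, r.batch, r.lipid): r.area for r in is_rows.itertuples()
        }
        std_area = [
            lookup.get((s, b, standards.get(c, "")), np.nan)
            for s, b, c in zip(out["sample"], out["batch"], classes)
        ]
        out["is_area"] = std_area
    bad = out[~(out["is_area"] > 0)]
    if len(bad):
        pairs = sorted(
            {
                (str(r.sample), parse_lipid_name(r.lipid).lipid_class)
                for r in bad.itertuples()
            }
        )
        raise LipidQCError(
            "missing or non-positive internal-standard area for "
            + "; ".join(f"(sample {s}, class {c})" for s, c in pairs)
        )
    out["normalized"] = out["area"] / out["is_area"]
    return out


def compute_cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise LipidQCError("CV requires at least two values")
    mean = arr.mean()
    if mean == 0:
        raise LipidQCError("CV undefined: mean of values is zero")
    return float(arr.std(ddof=1) / mean)


@dataclass
class FilterRules:
    """QC retention rules applied per lipid identification."""

    cv_max: float = 0.4            # QC-injection CV must be < cv_max
    peak_quality_min: float = 0.75  # average peak quality must exceed this
    require_rej_zero: bool = True
    batches: Sequence | None = None  # declared batches; default: all observed


def _qc_cv_by_lipid(table: pd.DataFrame, key: str) -> dict:
    """CV of normalised abundance across QC injections (falls back to all
    samples when no ``is_qc`` flag is present)."""
    value_col = "normalized" if "normalized" in table.columns else "area"
    qc = table[table["is_qc"].astype(bool)] if "is_qc" in table.columns else table
    cvs = {}
    for lipid, grp in qc.groupby(key, sort=False):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size >= 2 and vals.mean() != 0:
            cvs[lipid] = float(vals.std(ddof=1) / vals.mean())
    return cvs


def filter_lipids(
    table: pd.DataFrame, rules: FilterRules | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the QC retention rules; return (filtered table, audit log).

    A lipid is retained when rej = 0 for all its rows, its average peak
    quality exceeds ``peak_quality_min``, its QC-injection CV is below
    ``cv_max``, and it is present in every declared batch. The audit log
    records one entry per excluded lipid with the violated rule.
    """
    rules = rules or FilterRules()
    declared = set(rules.batches) if rules.batches is not None else set(table["batch"])
    cvs = _qc_cv_by_lipid(table, "lipid")
    audit: list[dict] = []
    keep: list = []
    for lipid, grp in table.groupby("lipid", sort=False):
        if rules.require_rej_zero and (grp["rej"].astype(int) != 0).any():
            audit.append({"lipid": lipid, "rule": "rej", "detail": "rej flag set"})
            continue
        quality = float(grp["peak_quality"].mean())
        if not quality > rules.peak_quality_min:
            audit.append(
                {
                    "lipid": lipid,
                    "rule": "peak_quality",
                    "detail": f"average peak quality {quality:.3f} "
                    f"<= {rules.peak_quality_min}",
                }
            )
            continue
        cv = cvs.get(lipid)
        if cv is not None and not cv < rules.cv_max:
            audit.append(
                {
                    "lipid": lipid,
                    "rule": "cv",
                    "detail": f"QC CV {cv:.3f} >= {rules.cv_max}",
                }
            )
            continue
        present = set(grp["batch"])
        if not declared <= present:
            missing = sorted(str(b) for b in declared - present)
            audit.append(
                {
                    "lipid": lipid,
                    "rule": "batch presence",
                    "detail": f"absent from batch(es) {', '.join(missing)}",
                }
            )
            continue
        keep.append(lipid)
    return table[table["lipid"].isin(keep)].copy(), audit


def resolve_duplicates(
    table: pd.DataFrame,
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Resolve duplicate identifications of the same lipid annotation.

    Duplicates are rows sharing a lipid name but carrying distinct
    ``peak_id`` values (and, when m/z and retention-time columns are
    present, lying within ``mz_tol_ppm`` and ``rt_tol`` minutes of each
    other). One survivor per duplicate group is chosen by lowest QC CV,
    then highest average peak quality, then highest average m-score;
    residual exact ties fall back to input order and are logged as
    ambiguous. All other duplicates are dropped.
    """
    if "peak_id" not in table.columns:
        return table.copy(), []
    audit: list[dict] = []
    cvs = _qc_cv_by_lipid(table, "peak_id")
    keep_ids: list = []
    for lipid, grp in table.groupby("lipid", sort=False):
        ids = list(dict.fromkeys(grp["peak_id"]))
        if len(ids) == 1:
            keep_ids.extend(ids)
            continue
        # optional m/z + RT clustering: greedy by m/z order
        clusters: list[list] = []
        if {"mz", "rt"} <= set(table.columns):
            meta = {
                pid: (
                    float(grp[grp["peak_id"] == pid]["mz"].mean()),
                    float(grp[grp["peak_id"] == pid]["rt"].mean()),
                )
                for pid in ids
            }
            for pid in sorted(ids, key=lambda p: meta[p][0]):
                for cl in clusters:
                    mz0, rt0 = meta[cl[0]]
                    mz, rt = meta[pid]
                    if abs(mz - mz0) <= mz0 * mz_tol_ppm * 1e-6 and abs(rt - rt0) <= rt_tol:
                        cl.append(pid)
                        break
                else:
                    clusters.append([pid])
        else:
            clusters = [ids]
        for cluster in clusters:
            if len(cluster) == 1:
                keep_ids.extend(cluster)
                continue
            def sort_key(pid):
                sub = grp[grp["peak_id"] == pid]
                return (
                    cvs.get(pid, math.inf),
                    -float(sub["peak_quality"].mean()),
                    -float(sub["m_score"].mean()),
                    cluster.index(pid),
                )
            ranked = sorted(cluster, key=sort_key)
            survivor = ranked[0]
            if len(ranked) > 1 and sort_key(ranked[0])[:3] == sort_key(ranked[1])[:3]:
                audit.append(
                    {
                        "lipid": lipid,
                        "rule": "duplicate_tie",
                        "detail": f"exact tie; kept first by input order ({survivor})",
                    }
                )
            keep_ids.append(survivor)
            for pid in ranked[1:]:
                audit.append(
                    {
                        "lipid": lipid,
                        "rule": "duplicate",
                        "detail": f"dropped {pid} in favour of {survivor}",
                    }
                )
    return table[table["peak_id"].isin(keep_ids)].copy(), audit


_SATURATION_LABELS = {0: "saturated", 1: "monounsaturated"}


def _saturation_label(total_double_bonds: int) -> str:
    return _SATURATION_LABELS.get(total_double_bonds, "polyunsaturated")


def group_sums(
    values: pd.DataFrame, species: Iterable[LipidSpecies] | None = None
) -> pd.DataFrame:
    """Per-sample class and class-by-saturation totals.

    ``values`` is a sample x lipid matrix; lipid names are parsed unless
    pre-parsed species are supplied. Output columns are named
    ``Total <class>`` and ``Total <saturation> <class>``; classes with no
    member lipids are simply absent.
    """
    if species is None:
        species = [parse_lipid_name(c) for c in values.columns]
    species = list(species)
    out = {}
    by_class: dict[str, list[str]] = {}
    by_class_sat: dict[tuple[str, str], list[str]] = {}
    for col, sp in zip(values.columns, species):
        by_class.setdefault(sp.lipid_class, []).append(col)
        key = (sp.lipid_class, _saturation_label(sp.total_double_bonds))
        by_class_sat.setdefault(key, []).append(col)
    for cls, cols in by_class.items():
        out[f"Total {cls}"] = values[cols].sum(axis=1)
    for (cls, sat), cols in by_class_sat.items():
        out[f"Total {sat} {cls}"] = values[cols].sum(axis=1)
    return pd.DataFrame(out, index=values.index)


def friedewald_ldl(tc, hdl, tg):
    """Friedewald LDL-C estimate (mmol/L): TC - HDL-C - TG/2.2.

    Negative estimates are returned as computed but a warning is emitted;
    they indicate high-triglyceride samples where the formula breaks down.
    """
    ldl = np.asarray(tc, dtype=float) - np.asarray(hdl, dtype=float) - np.asarray(
        tg, dtype=float
    ) / 2.2
    if np.any(ldl < 0):
        warnings.warn(
            "Friedewald estimate negative for some samples; "
            "values returned unmodified",
            stacklevel=2,
        )
    return float(ldl) if ldl.ndim == 0 else ldl


# ---------------------------------------------------------------------------
# Residualisation + inverse normal transform
# ---------------------------------------------------------------------------

def _find_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    base_rank = np.linalg.matrix_rank(X)
    guilty = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            guilty.append(names[j])
    return guilty


def residualize(values: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of ``values`` on an intercept plus ``covariates``.

    Categorical (non-numeric) covariates are dummy-coded. Rows with any
    missing value are dropped (and absent from the result). A
    rank-deficient design raises, naming the collinear columns.
    """
    cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
    df = pd.concat([values.rename("__y__"), cov], axis=1).dropna()
    y = df["__y__"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), df.drop(columns="__y__").to_numpy(dtype=float)])
    names = ["intercept", *df.columns.drop("__y__")]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        guilty = _find_collinear(X, names)
        raise np.linalg.LinAlgError(
            f"rank-deficient covariate design; collinear columns: {guilty}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=df.index, name=values.name)


def inverse_normal_transform(values, c: float = 3.0 / 8.0):
    """Rank-based inverse normal transform.

    Maps value with rank r (average ranks for ties) among n to
    ``Phi^-1((r - c) / (n - 2c + 1))``; the default offset c = 3/8 is the
    Blom constant. Requires at least three values with some variation.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("inverse normal transform requires at least 3 values")
    if np.all(arr == arr[0]):
        raise ValueError("inverse normal transform undefined for constant input")
    ranks = stats.rankdata(arr, method="average")
    transformed = stats.norm.ppf((ranks - c) / (arr.size - 2 * c + 1))
    if isinstance(values, pd.Series):
        return pd.Series(transformed, index=values.index, name=values.name)
    return transformed


@dataclass
class ResidualTable:
    """Covariate-adjusted, inverse-normal-transformed trait matrix."""

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    dropped_samples: list = field(default_factory=list)


def transform_matrix(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
    int_offset: float = 3.0 / 8.0,
) -> ResidualTable:
    """Residualise every trait column on the covariates, then INT each.

    The order (adjust first, transform second) restores approximate
    normality of the adjusted traits and removes batch separation.
    """
    cols = {}
    kept_index = None
    for col in values.columns:
        resid = residualize(values[col], covariates)
        cols[col] = inverse_normal_transform(resid, c=int_offset)
        kept_index = resid.index if kept_index is None else kept_index
    data = pd.DataFrame(cols)
    dropped = [s for s in values.index if s not in data.index]
    return ResidualTable(
        data=data, covariates=list(covariates.columns), dropped_samples=dropped
    )
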