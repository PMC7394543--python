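"""Maximum-likelihood twin structural-equation models.

The classical twin design decomposes trait variance into additive genetic
(A), shared-environment (C) and unique-environment (E) components from the
contrast between monozygotic (MZ) pairs, who share all segregating genetic
variation, and dizygotic (DZ) pairs, who share half of it on average. A
pair's two trait values are modelled as bivariate normal with common
variance a^2 + c^2 + e^2 and within-pair covariance a^2 + c^2 (MZ) or
0.5 a^2 + c^2 (DZ). Narrow-sense heritability is
h^2 = a^2 / (a^2 + c^2 + e^2).

Implemented here:

* univariate ACE / AE / CE / E fits with profile-likelihood confidence
  intervals on h^2 and a likelihood-ratio test of the additive component,
* the bivariate Cholesky model yielding genetic (rg), shared-environment
  (rc), unique-environment (re) and phenotypic (rp) correlations,
* a sex-heterogeneity model with separate male/female path coefficients
  (opposite-sex DZ pairs covary through the cross-product of male and
  female paths),
* a gene-by-age moderation model in which each path is linear in centred
  age, giving an age-varying h^2,
* Falconer's moment estimator 2(rMZ - rDZ), kept as an independent
  cross-check of the likelihood machinery.

All likelihoods are evaluated from per-group sufficient statistics, so a
single objective evaluation is O(1) in the number of pairs (except for the
age-moderation model, whose covariance varies per pair).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinPairs",
    "VarianceComponentFit",
    "BivariateFit",
    "SexHetFit",
    "GxEFit",
    "pairs_from_members",
    "pair_loglik",
    "fit_univariate",
    "h2_significance",
    "h2_profile_ci",
    "fit_bivariate_cholesky",
    "fit_sex_heterogeneity",
    "fit_gxe_age",
    "falconer_h2",
    "intraclass_corr",
]

_LOG2PI = math.log(2.0 * math.pi)
_NEG_INF = -np.inf


def pairs_from_members(
    members: pd.DataFrame, trait: pd.Series, trait2: pd.Series | None = None
) -> pd.DataFrame:
    """Build a pair table from member-level metadata and trait values.

    ``members`` needs columns pair_id, member (1/2), zygosity and
    optionally sex and age; ``trait`` is indexed by the same sample ids.
    Pairs with a missing co-twin value are dropped listwise.
    """
    df = members.copy()
    df["_value"] = trait.reindex(df.index).to_numpy()
    if trait2 is not None:
        df["_value2"] = trait2.reindex(df.index).to_numpy()
    m1 = df[df["member"] == 1].set_index("pair_id")
    m2 = df[df["member"] == 2].set_index("pair_id")
    common = m1.index.intersection(m2.index)
    m1, m2 = m1.loc[common], m2.loc[common]
    out = pd.DataFrame(
        {
            "pair_id": common,
            "zygosity": m1["zygosity"].to_numpy(),
            "value1": m1["_value"].to_numpy(float),
            "value2": m2["_value"].to_numpy(float),
        }
    )
    keep = out["value1"].notna() & out["value2"].notna()
    if trait2 is not None:
        out["value1_b"] = m1["_value2"].to_numpy(float)
        out["value2_b"] = m2["_value2"].to_numpy(float)
        keep &= out["value1_b"].notna() & out["value2_b"].notna()
    if "sex" in df.columns:
        out["sex1"] = m1["sex"].to_numpy()
        out["sex2"] = m2["sex"].to_numpy()
    if "age" in df.columns:
        out["age"] = (m1["age"].to_numpy(float) + m2["age"].to_numpy(float)) / 2.0
    return out[keep].reset_index(drop=True)


@dataclass
class _GroupStats:
    """Sufficient statistics of one zygosity group for the exchangeable
    bivariate normal likelihood: n, sum(x1+x2), sum(x1^2+x2^2), sum(x1*x2)."""

    n: int
    s1: float
    s2: float
    p: float

    @classmethod
    def from_values(cls, x1: np.ndarray, x2: np.ndarray) -> "_GroupStats":
        return cls(
            n=len(x1),
            s1=float(np.sum(x1 + x2)),
            s2=float(np.sum(x1 * x1 + x2 * x2)),
            p=float(np.sum(x1 * x2)),
        )


class TwinPairs:
    """Validated pair data split by zygosity, with cached sufficient stats.

    Expects a DataFrame with columns zygosity ("MZ"/"DZ"), value1, value2
    and optionally sex1/sex2/age.
    """

    def __init__(self, pairs: pd.DataFrame):
        z = pairs["zygosity"].astype(str).str.upper()
        bad = set(z) - {"MZ", "DZ"}
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")
        self.frame = pairs.reset_index(drop=True)
        self._z = z.to_numpy()
        self.mz = self.frame[self._z == "MZ"]
        self.dz = self.frame[self._z == "DZ"]
        self.stats = {
            "MZ": _GroupStats.from_values(
                self.mz["value1"].to_numpy(float), self.mz["value2"].to_numpy(float)
            ),
            "DZ": _GroupStats.from_values(
                self.dz["value1"].to_numpy(float), self.dz["value2"].to_numpy(float)
            ),
        }
        self.n_mz = self.stats["MZ"].n
        self.n_dz = self.stats["DZ"].n
        all_values = np.concatenate(
            [self.frame["value1"].to_numpy(float), self.frame["value2"].to_numpy(float)]
        )
        self.grand_mean = float(all_values.mean()) if all_values.size else 0.0
        self.sd = float(all_values.std(ddof=1)) if all_values.size > 1 else 1.0


def _exchangeable_loglik(g: _GroupStats, v: float, k: float, mu: float) -> float:
    """Bivariate normal log-likelihood with covariance [[v, k], [k, v]] and
    common mean mu, from sufficient statistics."""
    det = v * v - k * k
    if det <= 0.0 or v <= 0.0:
        return _NEG_INF
    sd2 = g.s2 - 2.0 * mu * g.s1 + 2.0 * g.n * mu * mu
    sdp = g.p - mu * g.s1 + g.n * mu * mu
    return (
        -g.n * _LOG2PI
        - 0.5 * g.n * math.log(det)
        - (v * sd2 - 2.0 * k * sdp) / (2.0 * det)
    )


def _profiled_mean(pairs: TwinPairs, v: float, k_mz: float, k_dz: float) -> float:
    """ML grand mean given the covariance: pairs are weighted by
    1/(v + k), which differs between MZ and DZ."""
    w_mz = 1.0 / (v + k_mz)
    w_dz = 1.0 / (v + k_dz)
    g_mz, g_dz = pairs.stats["MZ"], pairs.stats["DZ"]
    denom = 2.0 * (g_mz.n * w_mz + g_dz.n * w_dz)
    if denom == 0.0:
        return 0.0
    return (g_mz.s1 * w_mz + g_dz.s1 * w_dz) / denom


def _ace_loglik(
    pairs: TwinPairs, a2: float, c2: float, e2: float, mu: float | None = None
) -> float:
    v = a2 + c2 + e2
    k_mz = a2 + c2
    k_dz = 0.5 * a2 + c2
    if v <= 0.0 or v * v - k_mz * k_mz <= 0.0 or v * v - k_dz * k_dz <= 0.0:
        return _NEG_INF
    if mu is None:
        mu = _profiled_mean(pairs, v, k_mz, k_dz)
    return _exchangeable_loglik(pairs.stats["MZ"], v, k_mz, mu) + _exchangeable_loglik(
        pairs.stats["DZ"], v, k_dz, mu
    )


def pair_loglik(paths, pairs, mean: float | None = None) -> float:
    """Log-likelihood of path coefficients (a, c, e) on a pair table.

    ``pairs`` is a DataFrame or :class:`TwinPairs`. When ``mean`` is None
    the grand mean is profiled out analytically. A non-positive-definite
    implied covariance returns -inf rather than raising, so optimisers can
    probe the boundary safely.
    """
    if not isinstance(pairs, TwinPairs):
        pairs = TwinPairs(pairs)
    a, c, e = (float(x) for x in paths)
    return _ace_loglik(pairs, a * a, c * c, e * e, mean)


@dataclass
class VarianceComponentFit:
    """Result of a univariate twin model fit."""

    model: str
    a: float
    c: float
    e: float
    loglik: float
    n_params: int
    converged: bool = True
    h2_ci: tuple[float, float] | None = None
    p_h2: float | None = None

    @property
    def a2(self) -> float:
        return self.a * self.a

    @property
    def c2(self) -> float:
        return self.c * self.c

    @property
    def e2(self) -> float:
        return self.e * self.e

    @property
    def total_variance(self) -> float:
        return self.a2 + self.c2 + self.e2

    @property
    def h2(self) -> float:
        return self.a2 / self.total_variance

    @property
    def c2_std(self) -> float:
        return self.c2 / self.total_variance

    @property
    def e2_std(self) -> float:
        return self.e2 / self.total_variance

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


_MODEL_FREE_PATHS = {"ACE": (0, 1, 2), "AE": (0, 2), "CE": (1, 2), "E": (2,)}


def _multistart_minimize(objective, starts, bounds, tol=1e-10):
    """Bounded quasi-Newton from several starts, each polished by a
    simplex pass (the -inf contract makes the objective cliff-edged near
    singular covariances, where gradient-based line searches can stall)."""
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol}
        )
        polish = optimize.minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-7, "fatol": 1e-7, "maxiter": 120 * len(res.x)},
        )
        if polish.fun < res.fun:
            res = polish
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_univariate(
    pairs, model: str = "ACE", n_starts: int = 5, seed: int = 0
) -> VarianceComponentFit:
    """ML fit of one of the nested twin models ACE, AE, CE or E.

    Paths are optimised directly (their squares are the variance
    components, so non-negativity is automatic) with a seeded multi-start
    bounded quasi-Newton search; the grand mean is profiled analytically.
    """
    if model not in _MODEL_FREE_PATHS:
        raise ValueError(f"unknown model {model!r}; expected ACE, AE, CE or E")
    if not isinstance(pairs, TwinPairs):
        pairs = TwinPairs(pairs)
    if "A" in model and (pairs.n_mz < 2 or pairs.n_dz < 2):
        raise ValueError(
            f"model {model} needs at least 2 MZ and 2 DZ pairs "
            f"(got {pairs.n_mz} MZ, {pairs.n_dz} DZ)"
        )
    free = _MODEL_FREE_PATHS[model]
    sd = max(pairs.sd, 1e-6)

    def objective(theta: np.ndarray) -> float:
        paths = [0.0, 0.0, 0.0]
        for slot, val in zip(free, theta):
            paths[slot] = val
        ll = _ace_loglik(pairs, paths[0] ** 2, paths[1] ** 2, paths[2] ** 2)
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    starts = [np.full(len(free), sd * f) for f in (0.6, 0.3)]
    starts += [sd * rng.uniform(0.05, 1.2, size=len(free)) for _ in range(n_starts - 2)]
    bounds = [(0.0, 10.0 * sd)] * len(free)
    res = _multistart_minimize(objective, starts, bounds)
    paths = [0.0, 0.0, 0.0]
    for slot, val in zip(free, res.x):
        paths[slot] = abs(float(val))
    fit = VarianceComponentFit(
        model=model,
        a=paths[0],
        c=paths[1],
        e=paths[2],
        loglik=-float(res.fun),
        n_params=len(free) + 1,  # + grand mean
        converged=bool(res.success),
    )
    if not np.isfinite(fit.loglik):
        raise RuntimeError(
            f"{model} fit failed to find a finite likelihood after "
            f"{len(starts)} starts (diagnostics: {res.message})"
        )
    return fit


def h2_significance(
    ace_fit: VarianceComponentFit,
    ce_fit: VarianceComponentFit,
    boundary_mixture: bool = False,
) -> float:
    """Likelihood-ratio p-value for the additive genetic component.

    Compares the ACE fit against the CE fit (a = 0). The default
    reference is chi-square with 1 df; ``boundary_mixture=True`` uses the
    50:50 mixture of a point mass at zero and chi-square(1) appropriate
    for a variance tested on its boundary.
    """
    lr = 2.0 * (ace_fit.loglik - ce_fit.loglik)
    if lr < -1e-6:
        raise RuntimeError(
            f"negative likelihood ratio ({lr:.3g}): the CE fit exceeds the "
            "ACE fit; refit with more starts"
        )
    lr = max(lr, 0.0)
    if lr == 0.0:
        return 1.0
    p = stats.chi2.sf(lr, df=1)
    return float(0.5 * p if boundary_mixture else p)


def _profile_loglik_h2(pairs: TwinPairs, h2: float, warm=None) -> float:
    """Maximum log-likelihood subject to a fixed standardized h^2,
    optimising total variance and the shared-environment share."""
    h2 = min(max(h2, 0.0), 1.0 - 1e-9)

    def objective(theta):
        v, s = theta
        a2 = h2 * v
        c2 = s * v
        e2 = (1.0 - h2 - s) * v
        ll = _ace_loglik(pairs, a2, c2, e2)
        return -ll if np.isfinite(ll) else 1e12

    sd2 = max(pairs.sd**2, 1e-8)
    starts = [(sd2, 0.05)]
    if warm is not None:
        starts.insert(0, warm)
    best = _multistart_minimize(
        objective, starts, bounds=[(1e-8, 100.0 * sd2), (0.0, max(1.0 - h2, 1e-9))]
    )
    return -float(best.fun)


def h2_profile_ci(
    pairs, ace_fit: VarianceComponentFit, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for h^2, clipped to [0, 1].

    Bounds are the h^2 values where twice the drop from the maximised
    log-likelihood equals the chi-square(1) critical value.
    """
    if not isinstance(pairs, TwinPairs):
        pairs = TwinPairs(pairs)
    crit = stats.chi2.ppf(level, df=1) / 2.0
    ll_max = ace_fit.loglik
    h2_hat = ace_fit.h2
    warm = (ace_fit.total_variance, ace_fit.c2_std)

    def deficit(h2: float) -> float:
        return ll_max - _profile_loglik_h2(pairs, h2, warm=warm) - crit

    # lower bound
    if h2_hat <= 1e-8 or deficit(0.0) <= 0.0:
        lo = 0.0
    else:
        lo = float(optimize.brentq(deficit, 0.0, h2_hat, xtol=1e-5))
    # upper bound
    hi_probe = 1.0 - 1e-6
    if deficit(hi_probe) <= 0.0:
        hi = 1.0
    else:
        hi = float(optimize.brentq(deficit, max(h2_hat, 1e-8), hi_probe, xtol=1e-5))
    return (max(lo, 0.0), min(hi, 1.0))


# ---------------------------------------------------------------------------
# Bivariate Cholesky model
# ---------------------------------------------------------------------------

@dataclass
class BivariateFit:
    """Bivariate Cholesky decomposition of two traits' twin covariance.

    rg / rc / re are the correlations between the two traits' additive
    genetic, shared-environment and unique-environment factors; rp is the
    implied phenotypic correlation. A correlation whose component variance
    is numerically zero is reported as None (absent), not 0.
    """

    rg: float | None
    rc: float | None
    re: float | None
    rp: float
    A: np.ndarray
    C: np.ndarray
    E: np.ndarray
    loglik: float
    n_params: int
    converged: bool = True
    degenerate: bool = False


def _component_corr(M: np.ndarray, tol: float = 1e-6) -> float | None:
    if M[0, 0] < tol or M[1, 1] < tol:
        return None
    return float(np.clip(M[0, 1] / math.sqrt(M[0, 0] * M[1, 1]), -1.0, 1.0))


class _QuadStats:
    """Per-group sufficient statistics for a 4-variate normal likelihood:
    n, the vector of column sums and the matrix of cross-product sums."""

    def __init__(self, X: np.ndarray):
        self.n = X.shape[0]
        self.sx = X.sum(axis=0)
        self.sxx = X.T @ X

    def loglik(self, mean: np.ndarray, cov: np.ndarray) -> float:
        if self.n == 0:
            return 0.0
        try:
            chol = np.linalg.cholesky(cov)
            s_mu = (
                self.sxx
                - np.outer(mean, self.sx)
                - np.outer(self.sx, mean)
                + self.n * np.outer(mean, mean)
            )
            half = np.linalg.solve(chol, s_mu)
            quad = float(np.trace(np.linalg.solve(chol.T, half)))
        except np.linalg.LinAlgError:
            return _NEG_INF
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        return -0.5 * (self.n * (4.0 * _LOG2PI + logdet) + quad)


def _tri(theta3) -> np.ndarray:
    """Lower-triangular 2x2 from its three free entries."""
    l11, l21, l22 = theta3
    return np.array([[l11, 0.0], [l21, l22]])


def fit_bivariate_cholesky(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> BivariateFit:
    """Fit the bivariate Cholesky ACE model to two traits on the same pairs.

    Accepts either one pair table containing both traits (columns value1,
    value2, value1_b, value2_b as built by :func:`pairs_from_members` with
    ``trait2``), or two aligned single-trait pair tables. Each pair
    contributes a 4-variate normal likelihood; A, C and E are each
    parameterised by a 2x2 lower-triangular Cholesky factor, which keeps
    the implied covariance positive semidefinite by construction.
    """
    if pairs_b is None:
        df = pairs_a
        needed = {"value1", "value2", "value1_b", "value2_b", "zygosity"}
        if not needed <= set(df.columns):
            raise ValueError(f"pair table must contain columns {sorted(needed)}")
        z = df["zygosity"].astype(str).str.upper().to_numpy()
        X = df[["value1", "value1_b", "value2", "value2_b"]].to_numpy(float)
    else:
        if len(pairs_a) != len(pairs_b):
            raise ValueError("the two traits must be measured on the same pairs")
        za = pairs_a["zygosity"].astype(str).str.upper().to_numpy()
        zb = pairs_b["zygosity"].astype(str).str.upper().to_numpy()
        if not np.array_equal(za, zb):
            raise ValueError("pair tables disagree on zygosity ordering")
        z = za
        X = np.column_stack(
            [
                pairs_a["value1"].to_numpy(float),
                pairs_b["value1"].to_numpy(float),
                pairs_a["value2"].to_numpy(float),
                pairs_b["value2"].to_numpy(float),
            ]
        )
    # member-major layout: [y1_trait1, y1_trait2, y2_trait1, y2_trait2]
    t1 = np.concatenate([X[:, 0], X[:, 2]])
    t2 = np.concatenate([X[:, 1], X[:, 3]])
    if np.max(np.abs(t1 - t2)) < 1e-10:
        # duplicated trait: the 4x4 covariance is singular and the
        # likelihood unbounded; all cross-trait correlations are 1 and the
        # margins coincide with the univariate fit.
        uni = fit_univariate(
            pd.DataFrame(
                {"zygosity": z, "value1": X[:, 0], "value2": X[:, 2]}
            )
        )
        ones = np.ones((2, 2))
        return BivariateFit(
            rg=1.0 if uni.a2 > 1e-6 else None,
            rc=1.0 if uni.c2 > 1e-6 else None,
            re=1.0,
            rp=1.0,
            A=uni.a2 * ones,
            C=uni.c2 * ones,
            E=uni.e2 * ones,
            loglik=math.inf,
            n_params=11,
            degenerate=True,
        )

    stats_mz = _QuadStats(X[z == "MZ"])
    stats_dz = _QuadStats(X[z == "DZ"])
    sd1 = float(t1.std(ddof=1)) or 1.0
    sd2 = float(t2.std(ddof=1)) or 1.0
    m1, m2 = float(t1.mean()), float(t2.mean())

    def unpack(theta):
        La, Lc, Le = _tri(theta[0:3]), _tri(theta[3:6]), _tri(theta[6:9])
        mu = np.array([theta[9], theta[10], theta[9], theta[10]])
        return La @ La.T, Lc @ Lc.T, Le @ Le.T, mu

    def objective(theta):
        A, C, E, mu = unpack(theta)
        W = A + C + E
        ll = 0.0
        for st, kappa in ((stats_mz, 1.0), (stats_dz, 0.5)):
            B = kappa * A + C
            cov = np.block([[W, B], [B, W]])
            g = st.loglik(mu, cov)
            if not np.isfinite(g):
                return 1e12
            ll += g
        return -ll

    rng = np.random.default_rng(seed)
    base = np.array(
        [0.6 * sd1, 0.0, 0.6 * sd2, 0.3 * sd1, 0.0, 0.3 * sd2,
         0.6 * sd1, 0.0, 0.6 * sd2, m1, m2]
    )
    starts = [base]
    for _ in range(n_starts - 1):
        jitter = rng.uniform(0.5, 1.5, size=11)
        jitter[[1, 4, 7]] = rng.uniform(-0.3, 0.3, size=3)
        start = base * jitter
        start[[1, 4, 7]] = jitter[[1, 4, 7]] * max(sd1, sd2)
        start[9], start[10] = m1, m2
        starts.append(start)
    smax = 10.0 * max(sd1, sd2)
    bounds = []
    for i in range(9):
        lo = -smax if i in (1, 4, 7) else 0.0  # off-diagonals may be negative
        bounds.append((lo, smax))
    bounds += [(m1 - 5 * sd1, m1 + 5 * sd1), (m2 - 5 * sd2, m2 + 5 * sd2)]
    res = _multistart_minimize(objective, starts, bounds, tol=1e-12)
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise RuntimeError("bivariate Cholesky fit did not converge")
    A, C, E, _ = unpack(res.x)
    W = A + C + E
    return BivariateFit(
        rg=_component_corr(A),
        rc=_component_corr(C),
        re=_component_corr(E),
        rp=float(np.clip(W[0, 1] / math.sqrt(W[0, 0] * W[1, 1]), -1.0, 1.0)),
        A=A,
        C=C,
        E=E,
        loglik=-float(res.fun),
        n_params=11,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Sex heterogeneity
# ---------------------------------------------------------------------------

@dataclass
class _GeneralStats:
    """Sufficient statistics for a bivariate normal with member-specific
    means/variances (needed for opposite-sex pairs)."""

    n: int
    s1a: float
    s1b: float
    s2a: float
    s2b: float
    p: float

    @classmethod
    def from_values(cls, x1, x2) -> "_GeneralStats":
        x1 = np.asarray(x1, float)
        x2 = np.asarray(x2, float)
        return cls(
            n=len(x1),
            s1a=float(x1.sum()),
            s1b=float(x2.sum()),
            s2a=float((x1 * x1).sum()),
            s2b=float((x2 * x2).sum()),
            p=float((x1 * x2).sum()),
        )

    def loglik(self, m1, m2, v1, v2, k) -> float:
        if self.n == 0:
            return 0.0
        det = v1 * v2 - k * k
        if det <= 0.0 or v1 <= 0.0 or v2 <= 0.0:
            return _NEG_INF
        d11 = self.s2a - 2.0 * m1 * self.s1a + self.n * m1 * m1
        d22 = self.s2b - 2.0 * m2 * self.s1b + self.n * m2 * m2
        d12 = self.p - m1 * self.s1b - m2 * self.s1a + self.n * m1 * m2
        quad = (v2 * d11 + v1 * d22 - 2.0 * k * d12) / det
        return -self.n * _LOG2PI - 0.5 * self.n * math.log(det) - 0.5 * quad


@dataclass
class SexHetFit:
    """Sex-heterogeneity model fit and its homogeneity LRT."""

    paths_male: tuple[float, float, float]
    paths_female: tuple[float, float, float]
    h2_male: float
    h2_female: float
    loglik_het: float
    loglik_hom: float
    lr: float
    df: int
    p_value: float
    hom_fit: tuple[float, float, float] = (0.0, 0.0, 0.0)


_MALE_TOKENS = {"M", "MALE", "1"}


def _is_male(x) -> bool:
    return str(x).strip().upper() in _MALE_TOKENS


def fit_sex_heterogeneity(pairs: pd.DataFrame, n_starts: int = 5, seed: int = 0) -> SexHetFit:
    """Fit separate male and female ACE paths and test their equality.

    Five pair groups contribute: MZ male, MZ female, DZ male-male, DZ
    female-female and DZ opposite-sex. The opposite-sex within-pair
    covariance is 0.5 a_m a_f + c_m c_f. Means are sex-specific in both
    the heterogeneity and homogeneity models, so the LRT constrains only
    the three path coefficients (df = 3).
    """
    df = pairs.copy()
    z = df["zygosity"].astype(str).str.upper()
    male1 = df["sex1"].map(_is_male)
    male2 = df["sex2"].map(_is_male)

    def grab(mask, swap=False):
        sub = df[mask]
        x1 = sub["value2" if swap else "value1"].to_numpy(float)
        x2 = sub["value1" if swap else "value2"].to_numpy(float)
        return _GeneralStats.from_values(x1, x2)

    groups = {
        "mz_m": (grab((z == "MZ") & male1 & male2), 1.0, "mm"),
        "mz_f": (grab((z == "MZ") & ~male1 & ~male2), 1.0, "ff"),
        "dz_m": (grab((z == "DZ") & male1 & male2), 0.5, "mm"),
        "dz_f": (grab((z == "DZ") & ~male1 & ~male2), 0.5, "ff"),
        # opposite-sex pairs ordered male first
        "dz_os": (
            _GeneralStats(
                **{
                    k: getattr(grab((z == "DZ") & male1 & ~male2), k)
                    + getattr(grab((z == "DZ") & ~male1 & male2, swap=True), k)
                    for k in ("n", "s1a", "s1b", "s2a", "s2b", "p")
                }
            ),
            0.5,
            "os",
        ),
    }
    n_male_pairs = groups["mz_m"][0].n + groups["dz_m"][0].n
    n_female_pairs = groups["mz_f"][0].n + groups["dz_f"][0].n
    for label, n in (("male", n_male_pairs), ("female", n_female_pairs)):
        if n < 5:
            warnings.warn(
                f"only {n} same-sex {label} pairs; {label} paths weakly identified",
                stacklevel=2,
            )

    male_vals = np.concatenate(
        [
            df.loc[male1, "value1"].to_numpy(float),
            df.loc[male2, "value2"].to_numpy(float),
        ]
    )
    female_vals = np.concatenate(
        [
            df.loc[~male1, "value1"].to_numpy(float),
            df.loc[~male2, "value2"].to_numpy(float),
        ]
    )
    mu_m0 = float(male_vals.mean()) if male_vals.size else 0.0
    mu_f0 = float(female_vals.mean()) if female_vals.size else 0.0
    sd = float(np.concatenate([male_vals, female_vals]).std(ddof=1)) or 1.0

    def group_ll(stats_k, kappa, kind, pm, pf, mu_m, mu_f):
        am, cm, em = pm
        af, cf, ef = pf
        vm = am * am + cm * cm + em * em
        vf = af * af + cf * cf + ef * ef
        if kind == "mm":
            return stats_k.loglik(mu_m, mu_m, vm, vm, kappa * am * am + cm * cm)
        if kind == "ff":
            return stats_k.loglik(mu_f, mu_f, vf, vf, kappa * af * af + cf * cf)
        return stats_k.loglik(mu_m, mu_f, vm, vf, 0.5 * am * af + cm * cf)

    def total_ll(pm, pf, mu_m, mu_f):
        ll = 0.0
        for stats_k, kappa, kind in groups.values():
            g = group_ll(stats_k, kappa, kind, pm, pf, mu_m, mu_f)
            if not np.isfinite(g):
                return _NEG_INF
            ll += g
        return ll

    rng = np.random.default_rng(seed)

    def fit(het: bool):
        npaths = 6 if het else 3

        def objective(theta):
            if het:
                pm, pf = theta[0:3], theta[3:6]
            else:
                pm = pf = theta[0:3]
            ll = total_ll(pm, pf, theta[npaths], theta[npaths + 1])
            return -ll if np.isfinite(ll) else 1e12

        base = np.concatenate(
            [np.full(npaths, 0.5 * sd), [mu_m0, mu_f0]]
        )
        starts = [base]
        for _ in range(n_starts - 1):
            s = base.copy()
            s[:npaths] = sd * rng.uniform(0.05, 1.2, size=npaths)
            starts.append(s)
        bounds = [(0.0, 10.0 * sd)] * npaths + [
            (mu_m0 - 5 * sd, mu_m0 + 5 * sd),
            (mu_f0 - 5 * sd, mu_f0 + 5 * sd),
        ]
        return _multistart_minimize(objective, starts, bounds)

    res_het = fit(het=True)
    res_hom = fit(het=False)
    ll_het = -float(res_het.fun)
    ll_hom = -float(res_hom.fun)
    if ll_hom > ll_het + 1e-6:
        # nesting violated numerically; reuse the better solution
        ll_het = ll_hom
        res_het.x = np.concatenate([res_hom.x[0:3], res_hom.x[0:3], res_hom.x[3:5]])
    pm = tuple(abs(float(x)) for x in res_het.x[0:3])
    pf = tuple(abs(float(x)) for x in res_het.x[3:6])
    lr = max(2.0 * (ll_het - ll_hom), 0.0)
    h2 = lambda p: p[0] ** 2 / max(p[0] ** 2 + p[1] ** 2 + p[2] ** 2, 1e-12)
    return SexHetFit(
        paths_male=pm,
        paths_female=pf,
        h2_male=h2(pm),
        h2_female=h2(pf),
        loglik_het=ll_het,
        loglik_hom=ll_hom,
        lr=lr,
        df=3,
        p_value=float(stats.chi2.sf(lr, df=3)),
        hom_fit=tuple(abs(float(x)) for x in res_hom.x[0:3]),
    )


# ---------------------------------------------------------------------------
# Gene-by-age moderation
# ---------------------------------------------------------------------------

@dataclass
class GxEFit:
    """Age-moderated ACE fit: each path is linear in centred age."""

    a0: float
    a1: float
    c0: float
    c1: float
    e0: float
    e1: float
    mu: float
    loglik: float
    loglik_ace: float
    lr: float
    df: int
    p_value: float
    age_center: float
    h2_grid: pd.DataFrame | None = None
    fallback: bool = False

    def h2_at(self, age) -> np.ndarray:
        t = np.asarray(age, float) - self.age_center
        a = self.a0 + self.a1 * t
        c = self.c0 + self.c1 * t
        e = self.e0 + self.e1 * t
        total = a * a + c * c + e * e
        return a * a / np.where(total > 0, total, np.nan)


def fit_gxe_age(
    pairs: pd.DataFrame, n_starts: int = 4, seed: int = 0, grid_points: int = 5
) -> GxEFit:
    """Fit the gene-by-environment (age) moderation model.

    Path coefficients are a(t) = a0 + a1 t, c(t) = c0 + c1 t and
    e(t) = e0 + e1 t in age t centred at the sample mean; age is shared
    within a pair, so each pair contributes a bivariate normal with its
    own implied covariance. The moderation LRT compares against the plain
    ACE model (a1 = c1 = e1 = 0; df = 3).
    """
    df = pairs
    ages = df["age"].to_numpy(float)
    center = float(ages.mean())
    t = ages - center
    if np.allclose(t, 0.0):
        warnings.warn("no age variation; falling back to the plain ACE model",
                      stacklevel=2)
        ace = fit_univariate(df, "ACE", seed=seed)
        return GxEFit(
            a0=ace.a, a1=0.0, c0=ace.c, c1=0.0, e0=ace.e, e1=0.0,
            mu=float(np.concatenate([df["value1"], df["value2"]]).mean()),
            loglik=ace.loglik, loglik_ace=ace.loglik, lr=0.0, df=3,
            p_value=1.0, age_center=center, fallback=True,
        )
    z = df["zygosity"].astype(str).str.upper().to_numpy()
    kappa = np.where(z == "MZ", 1.0, 0.5)
    x1 = df["value1"].to_numpy(float)
    x2 = df["value2"].to_numpy(float)
    sd = float(np.concatenate([x1, x2]).std(ddof=1)) or 1.0
    mu0 = float(np.concatenate([x1, x2]).mean())
    t_scale = float(np.abs(t).max()) or 1.0

    def neg_ll(theta):
        a0, a1, c0, c1, e0, e1, mu = theta
        a = a0 + a1 * t
        c = c0 + c1 * t
        e = e0 + e1 * t
        v = a * a + c * c + e * e
        k = kappa * a * a + c * c
        det = v * v - k * k
        if np.any(det <= 0.0) or np.any(v <= 0.0):
            return 1e12
        d1 = x1 - mu
        d2 = x2 - mu
        ll = np.sum(
            -_LOG2PI
            - 0.5 * np.log(det)
            - (v * (d1 * d1 + d2 * d2) - 2.0 * k * d1 * d2) / (2.0 * det)
        )
        return -float(ll)

    rng = np.random.default_rng(seed)
    base = np.array([0.5 * sd, 0.0, 0.3 * sd, 0.0, 0.6 * sd, 0.0, mu0])
    starts = [base]
    for _ in range(n_starts - 1):
        s = base.copy()
        s[[0, 2, 4]] = sd * rng.uniform(0.05, 1.0, size=3)
        s[[1, 3, 5]] = rng.normal(0.0, 0.05 * sd / t_scale, size=3)
        starts.append(s)
    slope_cap = 5.0 * sd / t_scale
    bounds = [
        (0.0, 10.0 * sd), (-slope_cap, slope_cap),
        (0.0, 10.0 * sd), (-slope_cap, slope_cap),
        (0.0, 10.0 * sd), (-slope_cap, slope_cap),
        (mu0 - 5 * sd, mu0 + 5 * sd),
    ]
    res = _multistart_minimize(neg_ll, starts, bounds)
    ace = fit_univariate(df, "ACE", seed=seed)
    ll_gxe = -float(res.fun)
    if ll_gxe < ace.loglik - 1e-6:
        # moderation model nests ACE; enforce nesting numerically
        theta = np.array([ace.a, 0.0, ace.c, 0.0, ace.e, 0.0, mu0])
        refined = optimize.minimize(
            neg_ll, theta, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12}
        )
        if -refined.fun > ll_gxe:
            res = refined
            ll_gxe = -float(refined.fun)
    a0, a1, c0, c1, e0, e1, mu = (float(v) for v in res.x)
    lr = max(2.0 * (ll_gxe - ace.loglik), 0.0)
    fit = GxEFit(
        a0=a0, a1=a1, c0=c0, c1=c1, e0=e0, e1=e1, mu=mu,
        loglik=ll_gxe, loglik_ace=ace.loglik, lr=lr, df=3,
        p_value=float(stats.chi2.sf(lr, df=3)), age_center=center,
    )
    grid_ages = np.linspace(ages.min(), ages.max(), grid_points)
    fit.h2_grid = pd.DataFrame({"age": grid_ages, "h2": fit.h2_at(grid_ages)})
    return fit


# ---------------------------------------------------------------------------
# Moment estimators (independent cross-checks)
# ---------------------------------------------------------------------------

def intraclass_corr(pairs: pd.DataFrame) -> float:
    """Double-entry Pearson correlation of a pair table (the twin
    intraclass correlation estimator)."""
    x1 = pairs["value1"].to_numpy(float)
    x2 = pairs["value2"].to_numpy(float)
    a = np.concatenate([x1, x2])
    b = np.concatenate([x2, x1])
    return float(np.corrcoef(a, b)[0, 1])


def falconer_h2(r_mz: float, r_dz: float) -> float:
    """Falconer's moment estimator 2 (rMZ - rDZ), clipped to [0, 1]."""
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    return float(np.clip(2.0 * (r_mz - r_dz), 0.0, 1.0))
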