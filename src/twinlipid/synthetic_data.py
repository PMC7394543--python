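"""Twin-structured synthetic data with known ground truth.

Generates every input the pipeline consumes — a twin cohort with
per-lipid trait values, a probe-level expression matrix with planted
lipid associations, a CpG beta-value matrix with a planted genome-wide
average methylation (GWAM) effect, and a raw peak table exercising each
QC rule — together with the generating parameters, so that recovery of
heritability, correlations and association effects can be tested against
truth without any external download.

The trait model is the classical twin decomposition: for each lipid with
variance fractions (a2, c2, e2) summing to one, a monozygotic pair's two
values share the additive-genetic and shared-environment draws (within-
pair covariance a2 + c2) while a dizygotic pair shares half the genetic
variance (covariance 0.5 a2 + c2). Cross-lipid genetic correlations come
from a supplied rg matrix applied to the latent genetic factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_twin_cohort",
    "simulate_expression",
    "simulate_methylation",
    "simulate_raw_peak_table",
    "write_synthetic_dataset",
    "default_lipid_names",
]

# name templates cycled to give the cohort a realistic class composition
_NAME_TEMPLATES = [
    "TG(16:0/18:1/18:{db})",
    "TG({c}:0/17:0/18:0)",
    "Cer(d18:1/{c}:1)",
    "PC({c}:0/18:1)",
    "PC(39:{db})",
    "PE(16:0/{c}:4)",
    "LPC({c}:0)",
    "LPC(18:{db}e)",
    "SM(d18:1/{c}:0)",
    "DG({c}:0/18:1)",
    "CE({c}:3)",
    "PI(16:0/{c}:1)",
]


def default_lipid_names(n: int) -> list[str]:
    """Plausible shorthand names spanning the nine lipid classes."""
    names = []
    i = 0
    while len(names) < n:
        tpl = _NAME_TEMPLATES[i % len(_NAME_TEMPLATES)]
        name = tpl.format(c=14 + (i // len(_NAME_TEMPLATES)) % 12, db=i % 3)
        if name not in names:
            names.append(name)
        i += 1
    return names[:n]


@dataclass
class SyntheticConfig:
    """Generating parameters for one synthetic study.

    Variance fractions may be scalars (broadcast to all lipids) or
    per-lipid sequences; they must sum to one per lipid. The default
    cohort matches the study design the pipeline targets: 75 MZ and 55 DZ
    pairs aged 69-93, moderately heritable lipids (a2 = 0.4), 500
    expression probes and 1000 CpG sites (full-scale array dimensions are
    reachable through configuration but are not defaults).
    """

    n_mz_pairs: int = 75
    n_dz_pairs: int = 55
    n_lipids: int = 60
    a2: float | Sequence[float] = 0.4
    c2: float | Sequence[float] = 0.1
    e2: float | Sequence[float] = 0.5
    rg_matrix: np.ndarray | None = None
    rc_matrix: np.ndarray | None = None
    re_matrix: np.ndarray | None = None
    sex_params: Mapping[str, Sequence[float]] | None = None  # paths (a, c, e)
    age_moderation: Sequence[float] | None = None  # (a0, a1, c0, c1, e0, e1)
    age_range: tuple[float, float] = (69.0, 93.0)
    p_female: float = 0.65
    p_opposite_sex: float = 0.5
    lipid_names: list[str] | None = None
    n_probes: int = 500
    probe_noise_sd: float = 1.0
    planted_assoc: list[tuple[int, int, float]] = field(default_factory=list)
    n_cpg: int = 1000
    gwam_beta: float = 0.0
    gwam_lipid_idx: int = 0
    gwam_frac: float = 0.2
    gwam_latent_shift: float = 0.5
    seed: int = 0

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a2 = np.broadcast_to(np.asarray(self.a2, float), (self.n_lipids,)).copy()
        c2 = np.broadcast_to(np.asarray(self.c2, float), (self.n_lipids,)).copy()
        e2 = np.broadcast_to(np.asarray(self.e2, float), (self.n_lipids,)).copy()
        return a2, c2, e2

    def __post_init__(self):
        a2, c2, e2 = self.components()
        total = a2 + c2 + e2
        if np.any(np.abs(total - 1.0) > 1e-12):
            bad = int(np.argmax(np.abs(total - 1.0)))
            raise ValueError(
                f"variance fractions must sum to 1 per lipid; lipid {bad} "
                f"sums to {total[bad]!r}"
            )
        if np.any(a2 < 0) or np.any(c2 < 0) or np.any(e2 < 0):
            raise ValueError("variance fractions must be non-negative")
        for name in ("rg_matrix", "rc_matrix", "re_matrix"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, float)
            setattr(self, name, m)
            if m.shape != (self.n_lipids, self.n_lipids):
                raise ValueError(f"{name} must be {self.n_lipids} x {self.n_lipids}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-10):
                raise ValueError(f"{name} must have a unit diagonal")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValueError(f"{name} must be positive semidefinite")
        if self.sex_params is not None and self.age_moderation is not None:
            raise ValueError("sex_params and age_moderation cannot be combined")
        if self.lipid_names is not None and len(self.lipid_names) != self.n_lipids:
            raise ValueError("lipid_names length must equal n_lipids")


@dataclass
class SyntheticTruth:
    """Realised generating quantities stored alongside each dataset."""

    a2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    lipid_names: list[str]
    genetic_latents: pd.DataFrame | None = None  # sample x lipid
    shared_latents: pd.DataFrame | None = None
    unique_latents: pd.DataFrame | None = None
    planted_assoc: list[tuple[int, int, float]] = field(default_factory=list)
    gwam_beta: float = 0.0
    gwam_lipid_idx: int = 0
    gwam_latent: pd.Series | None = None
    seed: int = 0

    def to_json(self) -> str:
        payload = {
            "a2": self.a2.tolist(),
            "c2": self.c2.tolist(),
            "e2": self.e2.tolist(),
            "lipid_names": self.lipid_names,
            "planted_assoc": [list(t) for t in self.planted_assoc],
            "gwam_beta": self.gwam_beta,
            "gwam_lipid_idx": self.gwam_lipid_idx,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)


def _chol_or_eye(matrix: np.ndarray | None, n: int) -> np.ndarray:
    if matrix is None:
        return np.eye(n)
    # tiny jitter makes exactly-PSD matrices factorable
    return np.linalg.cholesky(matrix + 1e-10 * np.eye(n))


def _assign_sexes(rng, config) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair member sexes; MZ co-twins always match, DZ pairs are
    opposite-sex with probability p_opposite_sex."""
    sex_mz = np.where(
        rng.random(config.n_mz_pairs) < config.p_female, "F", "M"
    )
    sexes1 = list(sex_mz)
    sexes2 = list(sex_mz)
    for _ in range(config.n_dz_pairs):
        if rng.random() < config.p_opposite_sex:
            first_female = rng.random() < 0.5
            sexes1.append("F" if first_female else "M")
            sexes2.append("M" if first_female else "F")
        else:
            s = "F" if rng.random() < config.p_female else "M"
            sexes1.append(s)
            sexes2.append(s)
    return np.array(sexes1), np.array(sexes2)


def _latent_cohort(rng, config, a2, c2, e2):
    """Latent-factor generation with optional cross-lipid correlations.

    Returns member-level trait values plus the per-member latent draws
    (genetic / shared / unique), each standard normal marginally.
    """
    L = config.n_lipids
    lg = _chol_or_eye(config.rg_matrix, L)
    lc = _chol_or_eye(config.rc_matrix, L)
    le = _chol_or_eye(config.re_matrix, L)
    n_mz, n_dz = config.n_mz_pairs, config.n_dz_pairs

    def draw(n):
        return rng.standard_normal((n, L))

    # MZ: genetic and shared latents common to the pair
    g_mz = draw(n_mz) @ lg.T
    c_mz = draw(n_mz) @ lc.T
    g1_mz, g2_mz = g_mz, g_mz
    c1_mz, c2_mz = c_mz, c_mz
    # DZ: genetic latent = sqrt(1/2) common + sqrt(1/2) unique per member
    gc = draw(n_dz) @ lg.T
    g1_dz = np.sqrt(0.5) * gc + np.sqrt(0.5) * (draw(n_dz) @ lg.T)
    g2_dz = np.sqrt(0.5) * gc + np.sqrt(0.5) * (draw(n_dz) @ lg.T)
    c_dz = draw(n_dz) @ lc.T
    c1_dz, c2_dz = c_dz, c_dz

    g1 = np.vstack([g1_mz, g1_dz])
    g2 = np.vstack([g2_mz, g2_dz])
    c1 = np.vstack([c1_mz, c1_dz])
    c2m = np.vstack([c2_mz, c2_dz])
    e1 = draw(n_mz + n_dz) @ le.T
    e2m = draw(n_mz + n_dz) @ le.T

    a, c, e = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)
    y1 = g1 * a + c1 * c + e1 * e
    y2 = g2 * a + c2m * c + e2m * e
    return y1, y2, (g1, g2), (c1, c2m), (e1, e2m)


def _pairwise_cohort(rng, config, a2, c2, e2, sexes1, sexes2, ages):
    """Direct per-pair bivariate sampling for the sex-heterogeneity and
    age-moderation generating modes (one lipid at a time; cross-lipid
    correlations are not supported in these modes)."""
    n_pairs = config.n_mz_pairs + config.n_dz_pairs
    kappa = np.concatenate(
        [np.ones(config.n_mz_pairs), np.full(config.n_dz_pairs, 0.5)]
    )
    y1 = np.empty((n_pairs, config.n_lipids))
    y2 = np.empty((n_pairs, config.n_lipids))
    t = ages - ages.mean()
    for j in range(config.n_lipids):
        for i in range(n_pairs):
            if config.sex_params is not None:
                p1 = np.asarray(
                    config.sex_params["male" if sexes1[i] == "M" else "female"], float
                )
                p2 = np.asarray(
                    config.sex_params["male" if sexes2[i] == "M" else "female"], float
                )
            elif config.age_moderation is not None:
                a0, a1m, c0, c1m, e0, e1m = config.age_moderation
                p1 = p2 = np.array(
                    [a0 + a1m * t[i], c0 + c1m * t[i], e0 + e1m * t[i]]
                )
            else:  # pragma: no cover - callers route here only for these modes
                p1 = p2 = np.array([np.sqrt(a2[j]), np.sqrt(c2[j]), np.sqrt(e2[j])])
            v1 = float(p1 @ p1)
            v2 = float(p2 @ p2)
            cov = float(kappa[i] * p1[0] * p2[0] + p1[1] * p2[1])
            sigma = np.array([[v1, cov], [cov, v2]])
            try:
                chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(2))
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    f"implied pair covariance for lipid index {j} is not "
                    f"positive semidefinite: {sigma.tolist()}"
                ) from err
            z = chol @ rng.standard_normal(2)
            y1[i, j], y2[i, j] = z
    return y1, y2


def simulate_twin_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a member-level twin cohort table and its ground truth.

    The returned table has one row per twin (index = sample id) with
    columns pair_id, member, zygosity, sex, age, covariates (education,
    bmi, smoking, apoe4, batch) and one column per lipid. Trait values
    have unit total variance by construction when the fractions sum to 1.
    """
    if config.n_mz_pairs < 2 or config.n_dz_pairs < 2:
        raise ValueError("need at least 2 MZ and 2 DZ pairs")
    rng = np.random.default_rng(config.seed)
    a2, c2, e2 = config.components()
    names = config.lipid_names or default_lipid_names(config.n_lipids)
    n_pairs = config.n_mz_pairs + config.n_dz_pairs

    ages = rng.uniform(*config.age_range, size=n_pairs)
    sexes1, sexes2 = _assign_sexes(rng, config)

    latents = (None, None, None)
    if config.sex_params is not None or config.age_moderation is not None:
        y1, y2 = _pairwise_cohort(rng, config, a2, c2, e2, sexes1, sexes2, ages)
    else:
        y1, y2, g, c, e = _latent_cohort(rng, config, a2, c2, e2)
        latents = (g, c, e)

    zygosity = np.array(["MZ"] * config.n_mz_pairs + ["DZ"] * config.n_dz_pairs)
    n_members = 2 * n_pairs
    pair_labels = np.array([f"P{i + 1:04d}" for i in range(n_pairs)])
    sample_ids = np.empty(n_members, dtype=object)
    sample_ids[0::2] = [f"{p}_1" for p in pair_labels]
    sample_ids[1::2] = [f"{p}_2" for p in pair_labels]
    sexes = np.empty(n_members, dtype=object)
    sexes[0::2], sexes[1::2] = sexes1, sexes2
    cohort = pd.DataFrame(
        {
            "pair_id": np.repeat(pair_labels, 2),
            "member": np.tile([1, 2], n_pairs),
            "zygosity": np.repeat(zygosity, 2),
            "sex": sexes,
            "age": np.repeat(np.round(ages, 2), 2),
            # covariate distributions are documented package choices
            "education": np.clip(rng.normal(11.0, 3.2, n_members), 4, 22),
            "bmi": np.clip(rng.normal(27.7, 4.8, n_members), 16, 45),
            "smoking": rng.choice(
                ["never", "former", "current"], size=n_members, p=[0.55, 0.35, 0.10]
            ),
            "lipid_med": (rng.random(n_members) < 0.4).astype(int),
            "apoe4": (rng.random(n_members) < 0.27).astype(int),
            "batch": rng.integers(1, 3, n_members),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    values = np.empty((2 * n_pairs, config.n_lipids))
    values[0::2] = y1
    values[1::2] = y2
    for j, name in enumerate(names):
        cohort[name] = values[:, j]

    def latent_frame(pair_latents):
        if pair_latents[0] is None:
            return None
        l1, l2 = pair_latents
        out = np.empty_like(values)
        out[0::2] = l1
        out[1::2] = l2
        return pd.DataFrame(out, index=cohort.index, columns=names)

    g, c, e = latents
    truth = SyntheticTruth(
        a2=a2,
        c2=c2,
        e2=e2,
        lipid_names=list(names),
        genetic_latents=latent_frame(g) if g is not None else None,
        shared_latents=latent_frame(c) if c is not None else None,
        unique_latents=latent_frame(e) if e is not None else None,
        seed=config.seed,
    )
    return cohort, truth


def simulate_expression(
    cohort: pd.DataFrame, truth: SyntheticTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Probe-level expression: Gaussian noise plus planted lipid signals.

    Each planted (lipid index, probe index, beta) adds beta times the
    lipid's trait value to that probe, so the implied lipid-probe
    correlation is beta / sqrt(beta^2 + noise_sd^2) for unit-variance
    lipids.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(cohort)
    probes = rng.normal(0.0, config.probe_noise_sd, size=(n, config.n_probes))
    names = [f"probe_{j + 1:05d}" for j in range(config.n_probes)]
    for lipid_idx, probe_idx, beta in config.planted_assoc:
        if not 0 <= lipid_idx < len(truth.lipid_names):
            raise IndexError(f"planted lipid index {lipid_idx} out of range")
        if not 0 <= probe_idx < config.n_probes:
            raise IndexError(f"planted probe index {probe_idx} out of range")
        probes[:, probe_idx] += beta * cohort[truth.lipid_names[lipid_idx]].to_numpy()
    truth.planted_assoc = list(config.planted_assoc)
    return pd.DataFrame(probes, index=cohort.index, columns=names)


def simulate_methylation(
    cohort: pd.DataFrame, truth: SyntheticTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """CpG beta values in (0, 1) via an inverse-logit of Gaussian latents.

    A per-sample global factor, correlated (strength ``gwam_beta``) with
    the chosen lipid, shifts the latents of a fraction of probes, which
    induces a GWAM-lipid association of the configured sign. The factor
    is stored in the truth object for oracle regressions.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = len(cohort)
    baseline = rng.normal(0.0, 1.5, size=config.n_cpg)  # per-probe mean level
    latents = baseline + rng.normal(0.0, 0.5, size=(n, config.n_cpg))
    if config.gwam_beta != 0.0:
        rho = float(np.clip(config.gwam_beta, -0.99, 0.99))
        lipid = cohort[truth.lipid_names[config.gwam_lipid_idx]].to_numpy()
        lipid_std = (lipid - lipid.mean()) / lipid.std()
        m = rho * lipid_std + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
        n_shift = max(int(config.gwam_frac * config.n_cpg), 1)
        latents[:, :n_shift] += config.gwam_latent_shift * m[:, None]
        truth.gwam_latent = pd.Series(m, index=cohort.index, name="gwam_factor")
    truth.gwam_beta = config.gwam_beta
    truth.gwam_lipid_idx = config.gwam_lipid_idx
    names = [f"cg{j + 1:07d}" for j in range(config.n_cpg)]
    return pd.DataFrame(expit(latents), index=cohort.index, columns=names)


# ---------------------------------------------------------------------------
# Raw peak-table fixture
# ---------------------------------------------------------------------------

#: Lipids that survive every QC rule in the default raw peak fixture,
#: enumerated by hand from its construction (kept in sync with
#: :func:`simulate_raw_peak_table`).
DEFAULT_QC_SURVIVORS = frozenset(
    {"PC(16:0/18:1)", "TG(16:0/18:1/18:2)", "Cer(d18:1/24:1)", "DG(16:0/18:1)"}
)


def simulate_raw_peak_table(
    config: SyntheticConfig | None = None, violations: bool = True
) -> pd.DataFrame:
    """Raw peak-table fixture exercising every QC rule.

    With ``violations=True`` (default) the table contains, by
    construction: a duplicate trio with QC CVs 0.1 / 0.2 / 0.3 (survivor
    the lowest-CV identification), one lipid with QC CV >= 0.4, one with
    average peak quality <= 0.75, one rejected identification, and one
    lipid absent from the last of the four batches. The clean lipids are
    :data:`DEFAULT_QC_SURVIVORS`. With ``violations=False`` every lipid
    passes and filtering is the identity.
    """
    seed = config.seed if config is not None else 0
    rng = np.random.default_rng(seed + 3)
    batches = [1, 2, 3, 4]
    samples = [f"S{i + 1:02d}" for i in range(8)]
    qc_samples = ["QC1", "QC2", "QC3"]

    def qc_areas_for_cv(cv: float, mean: float = 1000.0) -> list[float]:
        # symmetric triple {m-d, m, m+d}: sd = d, so cv = d / m
        d = cv * mean
        return [mean - d, mean, mean + d]

    lipids: list[dict] = [
        dict(lipid="PC(16:0/18:1)", rej=0, quality=0.92, m_score=6.0,
             qc_cv=0.05, batches=batches),
        dict(lipid="TG(16:0/18:1/18:2)", rej=0, quality=0.88, m_score=7.5,
             qc_cv=0.08, batches=batches),
        dict(lipid="Cer(d18:1/24:1)", rej=0, quality=0.95, m_score=6.8,
             qc_cv=0.10, batches=batches),
    ]
    if violations:
        lipids += [
            dict(lipid="LPC(18:1)", rej=0, quality=0.90, m_score=6.0,
                 qc_cv=0.60, batches=batches),           # fails CV < 0.4
            dict(lipid="PE(16:0/20:4)", rej=0, quality=0.70, m_score=6.0,
                 qc_cv=0.05, batches=batches),           # fails quality > 0.75
            dict(lipid="SM(d18:1/16:0)", rej=1, quality=0.90, m_score=6.0,
                 qc_cv=0.05, batches=batches),           # fails rej = 0
            dict(lipid="PI(16:0/18:1)", rej=0, quality=0.90, m_score=6.0,
                 qc_cv=0.05, batches=batches[:3]),       # absent from batch 4
        ]
        dup_specs = [("dup1", 0.1), ("dup2", 0.2), ("dup3", 0.3)]
    else:
        dup_specs = [("dup1", 0.1)]

    rows = []
    for entry in lipids:
        pid = entry["lipid"]
        qc_vals = qc_areas_for_cv(entry["qc_cv"])
        per_batch = {
            b: samples[2 * (b - 1): 2 * (b - 1) + 2] for b in batches
        }
        for b in entry["batches"]:
            for s in per_batch[b]:
                rows.append(
                    dict(lipid=entry["lipid"], peak_id=pid, sample=s, batch=b,
                         area=float(rng.uniform(500, 5000)), is_area=1000.0,
                         rej=entry["rej"], peak_quality=entry["quality"],
                         m_score=entry["m_score"], is_qc=False)
                )
        for s, area in zip(qc_samples, qc_vals):
            rows.append(
                dict(lipid=entry["lipid"], peak_id=pid, sample=s,
                     batch=entry["batches"][0], area=area, is_area=1000.0,
                     rej=entry["rej"], peak_quality=entry["quality"],
                     m_score=entry["m_score"], is_qc=True)
            )
    # duplicate identifications of one annotation, distinguished by peak_id
    for pid, cv in dup_specs:
        qc_vals = qc_areas_for_cv(cv)
        for b in batches:
            for s in [samples[2 * (b - 1)], samples[2 * (b - 1) + 1]]:
                rows.append(
                    dict(lipid="DG(16:0/18:1)", peak_id=pid, sample=s, batch=b,
                         area=float(rng.uniform(500, 5000)), is_area=1000.0,
                         rej=0, peak_quality=0.9, m_score=6.0, is_qc=False)
                )
        for s, area in zip(qc_samples, qc_vals):
            rows.append(
                dict(lipid="DG(16:0/18:1)", peak_id=pid, sample=s, batch=1,
                     area=area, is_area=1000.0, rej=0, peak_quality=0.9,
                     m_score=6.0, is_qc=True)
            )
    return pd.DataFrame(rows)


def write_synthetic_dataset(outdir, config: SyntheticConfig) -> dict[str, str]:
    """Generate the full dataset and write it as plain-text artifacts.

    Writes pairs.csv (member metadata), lipids.csv (sample x lipid),
    expression.tsv, methylation.tsv, raw_peaks.csv and truth.json; returns
    the mapping of artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_twin_cohort(config)
    expression = simulate_expression(cohort, truth, config)
    methylation = simulate_methylation(cohort, truth, config)
    peaks = simulate_raw_peak_table(config)

    meta_cols = [
        "pair_id", "member", "zygosity", "sex", "age",
        "education", "bmi", "smoking", "lipid_med", "apoe4", "batch",
    ]
    paths = {}
    cohort[meta_cols].to_csv(outdir / "pairs.csv")
    cohort[truth.lipid_names].to_csv(outdir / "lipids.csv")
    expression.to_csv(outdir / "expression.tsv", sep="\t")
    methylation.to_csv(outdir / "methylation.tsv", sep="\t")
    peaks.to_csv(outdir / "raw_peaks.csv", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    cfg = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in asdict(config).items()
    }
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    for name in ("pairs.csv", "lipids.csv", "expression.tsv",
                 "methylation.tsv", "raw_peaks.csv", "truth.json",
                 "config.json"):
        paths[name] = str(outdir / name)
    return paths
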