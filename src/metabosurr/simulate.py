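"""Synthetic multi-biobank generator with known ground truth.

Real multi-cohort 1H-NMR resources of the kind this package targets are
access-restricted, so every downstream stage is exercised against data from
this generator, which emulates their statistical structure:

* block-correlated metabolite classes: log-concentrations load on one latent
  Gaussian factor per biochemical class, plus idiosyncratic noise, and are
  exponentiated so raw concentrations are positive and right-skewed
  (log-normal);
* cohort batch effects: an additive per-metabolite offset on the log scale
  plus a multiplicative per-metabolite gain on the centred log signal, both
  drawn once per cohort. The gain component matters: a purely additive
  offset shifts every score in a held-out cohort by a constant and therefore
  cannot degrade within-cohort discrimination, whereas gain variation
  rotates the signal direction seen by a model trained on other cohorts;
* planted binary phenotypes: each phenotype follows an equal-variance
  binormal liability model — labels are drawn at the target prevalence and
  the liability is N(0,1) in controls and N(d,1) in cases, so the oracle AUC
  of the true liability is exactly Phi(d / sqrt(2)); the liability is then
  coupled into the metabolite matrix through a per-marker weight vector;
* per-cell artifacts (missing values, zeros, >5-SD outliers) with an exact
  injection mask, so QC filters can be checked cell-for-cell;
* family-clustered survival: exponential proportional-hazards event times
  with a shared gamma frailty per family and administrative censoring.

The planted parameters are returned in a :class:`GenerativeTruth` object that
is sufficient to recompute any planted quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import CohortDataset
from .panel import MetabolitePanel, default_panel

__all__ = [
    "PlantedPhenotype",
    "GenerativeConfig",
    "GenerativeTruth",
    "ArtifactMask",
    "generate_dataset",
    "inject_artifacts",
    "plant_survival",
    "demo_config",
    "log_uniform_sizes",
]


def oracle_auc_from_separation(d: float) -> float:
    """AUC of the true liability under the equal-variance binormal model."""
    return float(norm.cdf(d / np.sqrt(2.0)))


def separation_from_auc(auc: float) -> float:
    """Inverse of :func:`oracle_auc_from_separation`."""
    if not 0.0 < auc < 1.0:
        raise ValueError("oracle AUC must be in (0, 1)")
    return float(norm.ppf(auc) * np.sqrt(2.0))


@dataclass
class PlantedPhenotype:
    """A binary phenotype planted into the generator.

    ``liability_weights`` maps marker names to the shift (on the log
    concentration scale) that one unit of liability induces in that marker.
    ``separation`` is the standardized mean difference d of the liability
    between cases and controls; the oracle AUC is Phi(d / sqrt(2)).
    """

    name: str
    target_prevalence: float
    liability_weights: dict[str, float]
    separation: float
    sex_linked: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError(
                f"{self.name}: prevalence must be in (0,1), "
                f"got {self.target_prevalence}")
        if self.separation < 0:
            raise ValueError(f"{self.name}: separation must be >= 0")

    @property
    def oracle_auc(self) -> float:
        return oracle_auc_from_separation(self.separation)

    @classmethod
    def from_auc(cls, name: str, oracle_auc: float, target_prevalence: float,
                 liability_weights: dict[str, float],
                 sex_linked: bool = False) -> "PlantedPhenotype":
        """Build a phenotype by its oracle AUC instead of its separation."""
        if oracle_auc == 0.5:
            d = 0.0
        else:
            d = separation_from_auc(oracle_auc)
        return cls(name, target_prevalence, liability_weights, d, sex_linked)


@dataclass
class GenerativeConfig:
    """Parameters of one synthetic multi-cohort dataset.

    The seed fully determines the output: two calls with identical configs
    produce bit-identical datasets.
    """

    cohort_sizes: list[int]
    panel: MetabolitePanel = field(default_factory=default_panel)
    n_latent_factors: int | None = None  # default: one per marker class
    block_structure: dict[str, float] | None = None  # class -> loading
    noise_sd: float = 0.25
    cohort_shift_sd: float = 0.0
    cohort_gain_sd: float = 0.0
    prevalence_spread: float = 0.0  # SD of per-cohort prevalence around target
    phenotype_specs: list[PlantedPhenotype] = field(default_factory=list)
    missing_rate: float = 0.0
    zero_rate: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) == 0:
            raise ValueError("need at least one cohort")
        if any(s <= 0 for s in self.cohort_sizes):
            raise ValueError("cohort sizes must be positive")
        for rate_name in ("missing_rate", "zero_rate", "outlier_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{rate_name} must be in [0,1], got {r}")
        if self.cohort_shift_sd < 0:
            raise ValueError("cohort_shift_sd must be >= 0")
        if self.cohort_gain_sd < 0:
            raise ValueError("cohort_gain_sd must be >= 0")
        if self.prevalence_spread < 0:
            raise ValueError("prevalence_spread must be >= 0")

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_sizes)

    @property
    def n_samples(self) -> int:
        return int(sum(self.cohort_sizes))


@dataclass
class ArtifactMask:
    """Exact record of which cells were altered by artifact injection.

    Each entry is a list of ``[row, column]`` pairs indexing into the
    metabolite matrix (row = sample position, column = panel position).
    """

    missing_cells: list[list[int]] = field(default_factory=list)
    zero_cells: list[list[int]] = field(default_factory=list)
    outlier_cells: list[list[int]] = field(default_factory=list)

    def samples(self, kind: str) -> set[int]:
        cells = getattr(self, f"{kind}_cells")
        return {int(r) for r, _ in cells}


@dataclass
class GenerativeTruth:
    """Planted parameters of one synthetic dataset; JSON-serializable."""

    seed: int
    marker_names: list[str]
    loadings: list[list[float]]          # markers x factors
    baselines: list[float]               # per-marker log-scale intercepts
    noise_sd: float
    cohort_offsets: dict[str, list[float]]
    cohort_gains: dict[str, list[float]] = field(default_factory=dict)
    phenotypes: dict[str, dict] = field(default_factory=dict)
    artifact_mask: ArtifactMask | None = None
    survival: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerativeTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        mask = payload.get("artifact_mask")
        if mask is not None:
            payload["artifact_mask"] = ArtifactMask(**mask)
        return cls(**payload)

    def liability(self, phenotype: str) -> np.ndarray:
        return np.asarray(self.phenotypes[phenotype]["liability"], dtype=float)

    def labels(self, phenotype: str) -> np.ndarray:
        return np.asarray(self.phenotypes[phenotype]["labels"], dtype=int)

    def oracle_auc(self, phenotype: str) -> float:
        return float(self.phenotypes[phenotype]["oracle_auc"])


def log_uniform_sizes(n_cohorts: int, total: int, rng: np.random.Generator,
                      ratio: float = 20.0) -> list[int]:
    """Cohort sizes drawn log-uniformly with max/min ratio ~``ratio``,
    rescaled to sum to ``total`` (each at least 2)."""
    raw = np.exp(rng.uniform(0.0, np.log(ratio), size=n_cohorts))
    sizes = np.maximum(2, np.round(raw / raw.sum() * total).astype(int))
    # fix rounding drift on the largest cohort
    sizes[int(np.argmax(sizes))] += total - int(sizes.sum())
    return [int(s) for s in sizes]


_DEFAULT_BLOCK_LOADING = 0.35


def _class_loadings(panel: MetabolitePanel, block_structure: dict[str, float],
                    n_factors: int) -> np.ndarray:
    """Loading matrix (markers x factors): each marker loads on the factor
    assigned to its class (classes mapped to factors cyclically)."""
    classes = sorted({panel.class_of(m) for m in panel.names})
    factor_of = {c: i % n_factors for i, c in enumerate(classes)}
    L = np.zeros((len(panel.names), n_factors))
    for j, m in enumerate(panel.names):
        c = panel.class_of(m)
        L[j, factor_of[c]] = block_structure.get(c, _DEFAULT_BLOCK_LOADING)
    return L


def _clinical_columns(rng: np.random.Generator, n: int, sex: np.ndarray,
                      age: np.ndarray, factors: np.ndarray) -> pd.DataFrame:
    """Raw continuous clinical variables with plausible marginals, partially
    linked to the latent lipid factor so derived flags correlate with the
    metabolome."""
    f_lip = factors[:, 0]
    male = sex == 1
    out = pd.DataFrame({
        "triglycerides": np.exp(0.10 + 0.35 * f_lip
                                + 0.30 * rng.standard_normal(n)),
        "hdl_chol": np.exp(0.30 - 0.20 * f_lip + 0.20 * rng.standard_normal(n)),
        "total_chol": np.clip(5.5 + 0.5 * f_lip + 0.8 * rng.standard_normal(n),
                              2.0, None),
        "creatinine": np.exp(4.17 + 0.20 * male + 0.15 * rng.standard_normal(n)),
        "sbp": 125 + 0.25 * (age - 55) + 15 * rng.standard_normal(n),
        "bmi": np.clip(26 + 4 * rng.standard_normal(n), 16, 55),
        "hgb": np.where(male, 9.4, 8.4) + 0.7 * rng.standard_normal(n),
        "wbc": np.exp(1.8 + 0.25 * rng.standard_normal(n)),
        "hscrp": np.exp(0.2 + 0.9 * rng.standard_normal(n)),
        "current_smoking": (rng.random(n) < 0.25).astype(int),
        "alcohol_consumption": (rng.random(n) < 0.6).astype(int),
        "lipid_medication": (rng.random(n)
                             < 1 / (1 + np.exp(-(age - 65) / 8))).astype(int),
        "blood_pressure_lowering_medication":
            (rng.random(n) < 1 / (1 + np.exp(-(age - 62) / 8))).astype(int),
    })
    out["dbp"] = 78 + 0.4 * (out["sbp"] - 125) + 8 * rng.standard_normal(n)
    out["waist"] = (np.where(male, 94.0, 82.0)
                    + 2.5 * (out["bmi"] - 26) + 6 * rng.standard_normal(n))
    out["diabetes"] = (rng.random(n)
                       < 0.03 + 0.12 / (1 + np.exp(-(age - 62) / 8))
                       ).astype(int)
    out["metabolic_syndrome"] = (
        rng.random(n)
        < 0.08 + 0.3 / (1 + np.exp(-(out["bmi"] - 31) / 2))).astype(int)
    return out


def generate_dataset(config: GenerativeConfig
                     ) -> tuple[CohortDataset, GenerativeTruth]:
    """Generate one multi-cohort dataset plus its planted truth.

    Deterministic under ``config.seed``. If the config carries nonzero
    artifact rates, :func:`inject_artifacts` is applied with a seed derived
    from the config seed and the mask is recorded in the truth.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    markers = panel.names
    n, m = config.n_samples, len(markers)
    classes = sorted({panel.class_of(mk) for mk in markers})
    q = config.n_latent_factors or len(classes)
    block = config.block_structure or {c: _DEFAULT_BLOCK_LOADING
                                       for c in classes}

    cohort_names = [f"cohort_{i + 1:02d}" for i in range(config.n_cohorts)]
    cohort = np.repeat(cohort_names, config.cohort_sizes)
    sex = (rng.random(n) < 0.5).astype(int)
    age = np.clip(rng.normal(55.0, 15.0, size=n), 18.0, 95.0)

    L = _class_loadings(panel, block, q)
    factors = rng.standard_normal((n, q))
    baselines = rng.uniform(np.log(0.05), np.log(3.0), size=m)
    log_m = baselines + factors @ L.T \
        + config.noise_sd * rng.standard_normal((n, m))

    offsets = {c: rng.normal(0.0, config.cohort_shift_sd, size=m)
               if config.cohort_shift_sd > 0 else np.zeros(m)
               for c in cohort_names}
    gains = {c: rng.normal(0.0, config.cohort_gain_sd, size=m)
             if config.cohort_gain_sd > 0 else np.zeros(m)
             for c in cohort_names}

    truth = GenerativeTruth(
        seed=config.seed,
        marker_names=list(markers),
        loadings=L.tolist(),
        baselines=baselines.tolist(),
        noise_sd=config.noise_sd,
        cohort_offsets={c: o.tolist() for c, o in offsets.items()},
        cohort_gains={c: g.tolist() for c, g in gains.items()},
    )

    pheno_frame = {}
    for spec in config.phenotype_specs:
        p = spec.target_prevalence
        if config.prevalence_spread > 0:
            # per-cohort case mix (e.g. hospital vs population cohorts);
            # interacting with cohort signatures, this is what makes pooled
            # CV optimistic relative to leave-one-biobank-out
            p_cohort = {c: float(np.clip(p + config.prevalence_spread
                                         * rng.standard_normal(), 0.02, 0.98))
                        for c in cohort_names}
            base_p = np.array([p_cohort[c] for c in cohort])
        else:
            p_cohort = {c: p for c in cohort_names}
            base_p = np.full(n, p)
        if spec.sex_linked:
            delta = 0.5 * np.minimum(base_p, 1.0 - base_p)
            thresh = np.where(sex == 1, base_p + delta, base_p - delta)
        else:
            thresh = base_p
        y = (rng.random(n) < thresh).astype(int)
        liability = spec.separation * y + rng.standard_normal(n)
        w = np.array([spec.liability_weights.get(mk, 0.0) for mk in markers])
        log_m += np.outer(liability - liability.mean(), w)
        pheno_frame[spec.name] = y
        per_cohort = {c: float(y[cohort == c].mean()) for c in cohort_names}
        truth.phenotypes[spec.name] = {
            "separation": spec.separation,
            "oracle_auc": spec.oracle_auc,
            "target_prevalence": p,
            "per_cohort_target_prevalence": p_cohort,
            "realized_prevalence": float(y.mean()),
            "per_cohort_prevalence": per_cohort,
            "sex_linked": spec.sex_linked,
            "weights": {mk: wv for mk, wv in spec.liability_weights.items()},
            "liability": liability.tolist(),
            "labels": y.tolist(),
        }

    # cohort batch structure is applied after the liability coupling so the
    # gain component perturbs the signal direction seen out-of-cohort
    if config.cohort_shift_sd > 0 or config.cohort_gain_sd > 0:
        for c in cohort_names:
            rows = cohort == c
            log_m[rows] = (baselines
                           + (log_m[rows] - baselines) * (1.0 + gains[c])
                           + offsets[c])

    conc = np.exp(log_m)
    df = pd.DataFrame({
        "sample_id": [f"s{i:06d}" for i in range(n)],
        "cohort": cohort,
        "sex": sex,
        "age": age,
    })
    clin = _clinical_columns(rng, n, sex, age, factors)
    df = pd.concat([df,
                    pd.DataFrame(conc, columns=markers),
                    clin,
                    pd.DataFrame(pheno_frame)], axis=1)
    clinical_cols = list(clin.columns) + list(pheno_frame)
    ds = CohortDataset(df=df, metabolite_cols=list(markers),
                       clinical_cols=clinical_cols)

    if config.missing_rate or config.zero_rate or config.outlier_rate:
        ds, _ = inject_artifacts(ds, config.missing_rate, config.zero_rate,
                                 config.outlier_rate,
                                 seed=(config.seed + 1) % (2 ** 31),
                                 truth=truth)
    return ds, truth


def inject_artifacts(dataset: CohortDataset, missing_rate: float,
                     zero_rate: float, outlier_rate: float, seed: int,
                     truth: GenerativeTruth | None = None
                     ) -> tuple[CohortDataset, ArtifactMask]:
    """Corrupt randomly selected metabolite cells; return the exact mask.

    Rates are per-cell fractions of the metabolite matrix. The three artifact
    types are placed on disjoint *samples* so that each corrupted sample is
    attributable to exactly one downstream QC rule. Outlier cells are
    displaced upward to more than 5 SD from the column mean computed without
    the cell itself.
    """
    for nm, r in (("missing_rate", missing_rate), ("zero_rate", zero_rate),
                  ("outlier_rate", outlier_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{nm} must be in [0,1], got {r}")

    rng = np.random.default_rng(seed)
    X = dataset.metabolite_matrix().copy()
    n, m = X.shape
    n_cells = n * m
    mask = ArtifactMask()

    free = np.ones(n, dtype=bool)  # samples not yet assigned an artifact type

    def pick_cells(rate: float) -> list[tuple[int, int]]:
        k = int(round(rate * n_cells))
        if k == 0:
            return []
        rows_avail = np.flatnonzero(free)
        k = min(k, rows_avail.size * m)
        idx = rng.choice(rows_avail.size * m, size=k, replace=False)
        cells = [(int(rows_avail[i // m]), int(i % m)) for i in idx]
        for r, _ in cells:
            free[r] = False
        return cells

    for r, c in pick_cells(missing_rate):
        X[r, c] = np.nan
        mask.missing_cells.append([int(r), int(c)])
    for r, c in pick_cells(zero_rate):
        X[r, c] = 0.0
        mask.zero_cells.append([int(r), int(c)])
    for r, c in pick_cells(outlier_rate):
        col = np.delete(X[:, c], r)
        col = col[np.isfinite(col)]
        mu, sd = float(np.mean(col)), float(np.std(col, ddof=1))
        X[r, c] = mu + (7.0 + 3.0 * rng.random()) * max(sd, 1e-12)
        mask.outlier_cells.append([int(r), int(c)])

    df = dataset.df.copy()
    df[dataset.metabolite_cols] = X
    out = dataset.replace(df)
    if truth is not None:
        truth.artifact_mask = mask
    return out, mask


def plant_survival(dataset: CohortDataset, log_hr_map: dict[str, float],
                   censor_rate: float, n_families: int, seed: int,
                   frailty_variance: float = 0.5,
                   baseline_hazard: float = np.log(2) / 10.0,
                   truth: GenerativeTruth | None = None) -> CohortDataset:
    """Append family-clustered survival columns (time, event, family_id).

    Event times follow an exponential proportional-hazards model with linear
    predictor sum(log_hr * column) over ``log_hr_map``, multiplied by a
    gamma-distributed frailty (mean 1, variance ``frailty_variance``) shared
    within each family. Administrative censoring at the empirical
    (1 - censor_rate) quantile of the event times.
    """
    if censor_rate < 0 or censor_rate > 1:
        raise ValueError("censor_rate must be in [0,1]")
    missing = [k for k in log_hr_map if k not in dataset.df.columns]
    if missing:
        raise KeyError(f"log_hr_map names absent from dataset: {missing}")

    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    fam = rng.integers(0, n_families, size=n)
    if frailty_variance > 0:
        z_fam = rng.gamma(shape=1.0 / frailty_variance,
                          scale=frailty_variance, size=n_families)
    else:
        z_fam = np.ones(n_families)

    eta = np.zeros(n)
    for col, loghr in log_hr_map.items():
        eta += loghr * dataset.df[col].to_numpy(dtype=float)
    rate = baseline_hazard * z_fam[fam] * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)

    if censor_rate >= 1.0:
        c = float(t_event.min()) / 2.0
    elif censor_rate == 0.0:
        c = float("inf")
    else:
        c = float(np.quantile(t_event, 1.0 - censor_rate))
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)

    df = dataset.df.copy()
    df["family_id"] = [f"fam{f:05d}" for f in fam]
    df["time"] = time
    df["event"] = event
    out = dataset.replace(df)
    if truth is not None:
        truth.survival = {
            "log_hr_map": dict(log_hr_map),
            "frailty_variance": frailty_variance,
            "baseline_hazard": baseline_hazard,
            "censor_rate": censor_rate,
            "censor_time": None if np.isinf(c) else c,
            "n_families": n_families,
        }
    return out


# --- the canonical demo configuration --------------------------------------

#: oracle AUCs of the four planted demo phenotypes
DEMO_PLANTED_AUCS = (0.95, 0.90, 0.75, 0.50)
DEMO_PREVALENCE = 0.25


def _demo_weights(panel: MetabolitePanel, k: int, n_informative: int = 12,
                  weight: float = 0.3) -> dict[str, float]:
    """Deterministic informative-marker assignment for demo phenotype ``k``:
    markers spread across the panel, two-thirds positive effects."""
    names = panel.names
    idx = [(7 * k + 5 * j) % len(names) for j in range(n_informative)]
    return {names[i]: (weight if j % 3 else -weight)
            for j, i in enumerate(idx)}


def demo_config(seed: int = 0, n_cohorts: int = 10, cohort_size: int = 500,
                cohort_shift_sd: float = 0.15, cohort_gain_sd: float = 0.15,
                prevalence_spread: float = 0.0,
                missing_rate: float = 0.0, zero_rate: float = 0.0,
                outlier_rate: float = 0.0) -> GenerativeConfig:
    """The desk-scale demo configuration: 10 cohorts x 500 samples with four
    planted phenotypes at oracle AUCs 0.95 / 0.90 / 0.75 / 0.50 and modest
    cohort batch shifts and gains."""
    panel = default_panel()
    specs = [
        PlantedPhenotype.from_auc(f"planted_auc{int(a * 100)}", a,
                                  DEMO_PREVALENCE, _demo_weights(panel, k))
        for k, a in enumerate(DEMO_PLANTED_AUCS)
    ]
    return GenerativeConfig(
        cohort_sizes=[cohort_size] * n_cohorts,
        panel=panel,
        cohort_shift_sd=cohort_shift_sd,
        cohort_gain_sd=cohort_gain_sd,
        prevalence_spread=prevalence_spread,
        phenotype_specs=specs,
        missing_rate=missing_rate,
        zero_rate=zero_rate,
        outlier_rate=outlier_rate,
        seed=seed,
    )
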