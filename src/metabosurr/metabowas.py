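"""Metabolome-wide association studies (MetaboWAS).

One linear regression per metabolite of the rank-inverse-normal (RIN)
transformed marker on a phenotype plus covariates; the phenotype coefficient
is the reported effect. Multiplicity is handled by Bonferroni over the
*effective* number of tests k_eff — the number of principal components of the
(RIN-transformed, standardized) marker matrix needed to explain a stated
fraction (default 99%) of the variance — giving the significance threshold
0.05 / k_eff. Correlated metabolite panels make plain Bonferroni over the
marker count needlessly conservative; k_eff is recomputed for each analysis
dataset rather than fixed.

Also provided is the confounder-substitution comparison: the same MetaboWAS
run under two different adjustment sets (e.g. a measured confounder vs its
metabolic surrogate), with the paired effect estimates, their squared
correlation, and a 2x2 significance contingency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata, t as t_dist

__all__ = ["rin_transform", "effective_tests", "run_metabowas",
           "MetaboWASResult", "compare_adjustments", "ComparisonResult",
           "bonferroni_threshold"]

FAMILY_ALPHA = 0.05

#: Blom offset for the rank-based inverse normal transformation
RIN_OFFSET = 3.0 / 8.0


def bonferroni_threshold(k_eff: int, alpha: float = FAMILY_ALPHA) -> float:
    """Per-test significance threshold alpha / k_eff."""
    if k_eff < 1:
        raise ValueError("k_eff must be >= 1")
    return alpha / k_eff


def rin_transform(values, offset: float = RIN_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transformation.

    value_i -> Phi^-1((r_i - offset) / (n + 1 - 2*offset)), with average
    ranks for ties and the Blom offset 3/8 by default, so the output depends
    on the input only through its ranks. Raises on constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("rin_transform expects a 1-d array")
    if not np.isfinite(x).all():
        raise ValueError("rin_transform requires finite values")
    if np.all(x == x[0]):
        raise ValueError("constant vector has no rank order")
    n = len(x)
    r = rankdata(x)
    return ndtri((r - offset) / (n + 1.0 - 2.0 * offset))


def rin_matrix(M: np.ndarray) -> np.ndarray:
    """Column-wise RIN transform."""
    M = np.asarray(M, dtype=float)
    return np.column_stack([rin_transform(M[:, j]) for j in range(M.shape[1])])


def effective_tests(markers: np.ndarray, variance_threshold: float = 0.99,
                    pre_transformed: bool = False) -> int:
    """Effective number of tests via PCA on the correlation scale.

    k_eff is the smallest k such that the top-k principal components of the
    RIN-transformed, standardized marker matrix explain at least
    ``variance_threshold`` of the total variance. Never exceeds the matrix
    rank; at threshold 1.0 it equals the rank.
    """
    M = np.asarray(markers, dtype=float)
    if M.ndim != 2 or M.shape[0] <= 2:
        raise ValueError("need a 2-d matrix with n > 2")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    if not pre_transformed:
        M = rin_matrix(M)
    Mc = M - M.mean(axis=0)
    sd = Mc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant marker column")
    Mc = Mc / sd
    sv = np.linalg.svd(Mc, compute_uv=False)
    var = sv ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("degenerate (rank-0) matrix")
    rank_tol = var[0] * max(Mc.shape) * np.finfo(float).eps
    rank = int((var > rank_tol).sum())
    cum = np.cumsum(var[:rank]) / total
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    return min(k, rank)


@dataclass
class MetaboWASResult:
    """Per-marker association estimates with effective-tests correction."""

    table: pd.DataFrame          # marker, beta, se, t, p, significant
    k_eff: int
    threshold: float
    phenotype: str
    covariates: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self) -> dict:
        return {"phenotype": self.phenotype, "covariates": self.covariates,
                "k_eff": self.k_eff, "threshold": self.threshold,
                "n_markers": len(self.table),
                "n_significant": self.n_significant}


def run_metabowas(markers: pd.DataFrame, phenotype, covariates=None,
                  rin: bool = True, variance_threshold: float = 0.99,
                  phenotype_name: str = "phenotype") -> MetaboWASResult:
    """Marker-wise linear models ``marker ~ phenotype + covariates``.

    Each (RIN-transformed) metabolite is regressed on the phenotype plus
    covariates by ordinary least squares; the effect is the phenotype
    coefficient with its usual t-based p-value. The effect direction follows
    the convention of modelling the metabolite as the response. Significance
    uses the 0.05 / k_eff threshold with k_eff computed on the same
    (transformed) marker matrix.

    Raises on a rank-deficient design (collinear covariates) and when the
    sample size does not exceed the parameter count.
    """
    M = markers.to_numpy(dtype=float) if isinstance(markers, pd.DataFrame) \
        else np.asarray(markers, dtype=float)
    names = (list(markers.columns) if isinstance(markers, pd.DataFrame)
             else [f"m{j}" for j in range(M.shape[1])])
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if covariates is None:
        C = np.empty((n, 0))
        cov_names: list[str] = []
    else:
        C = covariates.to_numpy(dtype=float) \
            if isinstance(covariates, pd.DataFrame) \
            else np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cov_names = (list(covariates.columns)
                     if isinstance(covariates, pd.DataFrame)
                     else [f"c{j}" for j in range(C.shape[1])])

    D = np.column_stack([np.ones(n), y, C])
    p = D.shape[1]
    if n <= p:
        raise ValueError(f"n={n} does not exceed parameter count {p}")
    if np.linalg.matrix_rank(D) < p:
        raise ValueError("design matrix is rank-deficient (collinear "
                         "phenotype/covariates)")

    if rin:
        M = rin_matrix(M)
    k_eff = effective_tests(M, variance_threshold=variance_threshold,
                            pre_transformed=True)
    threshold = bonferroni_threshold(k_eff)

    # vectorized OLS across markers: solve the shared design once
    Q, R = np.linalg.qr(D)
    B = np.linalg.solve(R, Q.T @ M)               # p x n_markers
    resid = M - D @ B
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(R.T @ R)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = 2.0 * t_dist.sf(np.abs(tstat), dof)

    table = pd.DataFrame({
        "marker": names, "beta": beta, "se": se, "t": tstat, "p": pval,
        "significant": pval < threshold,
    })
    return MetaboWASResult(table=table, k_eff=k_eff, threshold=threshold,
                           phenotype=phenotype_name, covariates=cov_names)


@dataclass
class ComparisonResult:
    """Paired MetaboWAS estimates under two adjustment sets."""

    estimates: pd.DataFrame      # marker, beta_a, beta_b, sig_a, sig_b
    r_squared: float
    sign_agreement: float
    both: int
    a_only: int
    b_only: int
    neither: int
    a_only_rate: float           # a_only / n significant under A
    b_only_rate: float           # b_only / n non-significant under A

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither

    def contingency(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.both, self.a_only], [self.b_only, self.neither]],
            index=["A significant", "A not significant"],
            columns=["B significant", "B not significant"],
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["estimates"] = self.estimates.to_dict(orient="list")
        d["rate_definitions"] = {
            "a_only_rate": "A-only count / A-significant count",
            "b_only_rate": "B-only count / A-nonsignificant count",
        }
        Path(path).write_text(json.dumps(d, default=float), encoding="utf-8")


def compare_adjustments(result_a: MetaboWASResult,
                        result_b: MetaboWASResult) -> ComparisonResult:
    """Compare two MetaboWAS runs over the same marker set.

    Reports the squared Pearson correlation of the effect estimates, the
    fraction of markers on which the effect signs agree, and the 2x2
    significance contingency (both / A-only / B-only / neither), whose cells
    sum to the marker count. Discordance rates are secondary to the raw
    counts; their definitions are recorded in the output.
    """
    a, b = result_a.table, result_b.table
    if list(a["marker"]) != list(b["marker"]):
        raise ValueError("marker sets (or their order) differ between results")
    beta_a, beta_b = a["beta"].to_numpy(), b["beta"].to_numpy()
    sig_a = a["significant"].to_numpy()
    sig_b = b["significant"].to_numpy()
    r = np.corrcoef(beta_a, beta_b)[0, 1]
    both = int((sig_a & sig_b).sum())
    a_only = int((sig_a & ~sig_b).sum())
    b_only = int((~sig_a & sig_b).sum())
    neither = int((~sig_a & ~sig_b).sum())
    n_sig_a = both + a_only
    n_nonsig_a = b_only + neither
    est = pd.DataFrame({"marker": a["marker"], "beta_a": beta_a,
                        "beta_b": beta_b, "sig_a": sig_a, "sig_b": sig_b})
    return ComparisonResult(
        estimates=est,
        r_squared=float(r ** 2),
        sign_agreement=float((np.sign(beta_a) == np.sign(beta_b)).mean()),
        both=both, a_only=a_only, b_only=b_only, neither=neither,
        a_only_rate=a_only / n_sig_a if n_sig_a else float("nan"),
        b_only_rate=b_only / n_nonsig_a if n_nonsig_a else float("nan"),
    )
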