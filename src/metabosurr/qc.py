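"""Metabolomics quality control and preprocessing.

The QC pipeline mirrors standard practice for targeted 1H-NMR panels:

1. restrict the columns to the retained markers of a panel;
2. remove samples with (a) more missing metabolite measures than a ceiling
   (default 0), then (b) one or more zero concentrations, then (c) any
   concentration more than ``sd_limit`` (default 5) standard deviations from
   the column mean — the mean/SD being computed on the samples surviving the
   first two rules, so contaminated cells cannot distort them;
3. impute any residual missing cells by NIPALS principal-component
   reconstruction;
4. z-scale each marker, storing the per-marker mean/SD so new data can be
   projected onto the same scale.

Samples are removed at the *first* rule they violate, and removal counts are
returned in a :class:`QCReport`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CohortDataset
from .panel import MetabolitePanel

logger = logging.getLogger(__name__)

__all__ = ["QCReport", "select_panel", "filter_samples", "impute_nipals",
           "zscale", "apply_scaling", "run_qc"]


@dataclass
class QCReport:
    """Counts and scaling parameters of one QC run."""

    n_input: int = 0
    n_removed_missing: int = 0
    n_removed_zero: int = 0
    n_removed_outlier: int = 0
    n_kept: int = 0
    n_cells_imputed: int = 0
    imputed_fraction: float = 0.0
    removed_missing_ids: list = field(default_factory=list)
    removed_zero_ids: list = field(default_factory=list)
    removed_outlier_ids: list = field(default_factory=list)
    scaling_mean: dict[str, float] = field(default_factory=dict)
    scaling_sd: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2),
                              encoding="utf-8")


def select_panel(dataset: CohortDataset, panel: MetabolitePanel
                 ) -> CohortDataset:
    """Restrict the dataset to the panel's retained markers, in panel order.

    Raises ``KeyError`` naming any retained marker absent from the dataset
    (mirroring the exclusion of whole cohorts that fail to report a marker).
    """
    keep = panel.retained
    absent = [m for m in keep if m not in dataset.df.columns]
    if absent:
        raise KeyError(f"dataset is missing required markers: {absent}")
    drop = [m for m in dataset.metabolite_cols if m not in keep]
    df = dataset.df.drop(columns=drop)
    return dataset.replace(df, metabolite_cols=keep)


def filter_samples(dataset: CohortDataset, max_missing: int = 0,
                   zero_forbidden: bool = True, sd_limit: float = 5.0,
                   sd_basis: str = "filtered") -> tuple[CohortDataset, QCReport]:
    """Apply the three sample-level filters in order; return kept data and a
    report.

    ``sd_basis`` controls on which samples the per-column mean/SD of the
    outlier rule are computed: ``"filtered"`` (default) uses the survivors of
    the missing and zero rules, ``"input"`` uses all input samples.
    Zero-variance columns never flag outliers. Sample SD uses the n-1
    denominator.
    """
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    if sd_basis not in ("filtered", "input"):
        raise ValueError("sd_basis must be 'filtered' or 'input'")

    X = dataset.metabolite_matrix()
    ids = dataset.df["sample_id"].to_numpy()
    report = QCReport(n_input=dataset.n_samples)

    n_missing = np.isnan(X).sum(axis=1)
    rm_missing = n_missing > max_missing
    report.n_removed_missing = int(rm_missing.sum())
    report.removed_missing_ids = [str(s) for s in ids[rm_missing]]

    has_zero = np.nansum(X == 0.0, axis=1) > 0
    rm_zero = has_zero & ~rm_missing if zero_forbidden \
        else np.zeros(len(X), dtype=bool)
    report.n_removed_zero = int(rm_zero.sum())
    report.removed_zero_ids = [str(s) for s in ids[rm_zero]]

    surv = ~rm_missing & ~rm_zero
    basis = X[surv] if sd_basis == "filtered" else X
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-basis edge
        mu = np.nanmean(basis, axis=0)
        sd = np.nanstd(basis, axis=0, ddof=1)
        safe_sd = np.where(sd > 0, sd, np.inf)  # constant columns flag nothing
        z = np.abs(X - mu) / safe_sd
        rm_outlier = surv & (np.nanmax(z, axis=1) > sd_limit)
    report.n_removed_outlier = int(rm_outlier.sum())
    report.removed_outlier_ids = [str(s) for s in ids[rm_outlier]]

    keep = surv & ~rm_outlier
    report.n_kept = int(keep.sum())
    if report.n_kept == 0:
        raise ValueError("all samples removed by QC filters")
    for rule, removed in (("missing", report.removed_missing_ids),
                          ("zero", report.removed_zero_ids),
                          ("outlier", report.removed_outlier_ids)):
        if removed:
            logger.info("QC %s rule removed %d samples: %s",
                        rule, len(removed), removed)
    return dataset.subset(keep), report


def impute_nipals(X: np.ndarray, n_components: int | None = None,
                  max_missing_fraction: float = 0.05, max_iter: int = 1000,
                  tol: float = 1e-8) -> tuple[np.ndarray, int]:
    """Complete a matrix by NIPALS principal-component reconstruction.

    NIPALS (nonlinear iterative partial least squares) estimates each
    principal component by alternating regressions of the matrix on the
    scores and loadings, using only the observed cells, which makes it
    natively tolerant of missing entries. Missing cells are replaced by the
    rank-``n_components`` reconstruction (plus the observed column means);
    observed cells are returned unchanged.

    ``n_components`` defaults to the number of components explaining >= 95%
    of the variance of the complete rows, capped at 10.

    Returns ``(completed matrix, n_cells_imputed)``.
    """
    X = np.asarray(X, dtype=float)
    miss = np.isnan(X)
    n_miss = int(miss.sum())
    if n_miss == 0:
        return X.copy(), 0
    if np.any(miss.all(axis=0)):
        cols = np.flatnonzero(miss.all(axis=0))
        raise ValueError(f"columns entirely missing: {cols.tolist()}")
    frac = n_miss / X.size
    if frac > max_missing_fraction:
        raise ValueError(
            f"missing fraction {frac:.4f} exceeds ceiling "
            f"{max_missing_fraction}; NIPALS imputation is only reliable for "
            "sparse missingness")

    if n_components is None:
        n_components = _default_components(X, miss)

    obs = ~miss
    recon = _nipals_reconstruction(X, obs, n_components, max_iter, tol)
    out = X.copy()
    out[miss] = recon[miss]

    # EM-style refinement: one-pass observed-mean centring biases the
    # reconstruction when missingness shifts a column's mean, so iterate
    # fill -> recentre -> refit to a fixed point (exact for low-rank data)
    all_obs = np.ones_like(obs)
    scale = max(float(np.nanmax(np.abs(X))), 1.0)
    for _ in range(100):
        recon = _nipals_reconstruction(out, all_obs, n_components,
                                       max_iter, tol)
        delta = float(np.max(np.abs(recon[miss] - out[miss])))
        out[miss] = recon[miss]
        if delta <= 1e-9 * scale:
            break
    return out, n_miss


def _nipals_reconstruction(X: np.ndarray, obs: np.ndarray, n_components: int,
                           max_iter: int, tol: float) -> np.ndarray:
    """Rank-``n_components`` NIPALS reconstruction using observed cells only.

    Alternates score/loading regressions restricted to observed entries,
    deflating component by component.
    """
    denom = obs.sum(axis=0)
    col_mu = np.where(obs, X, 0.0).sum(axis=0) / denom
    R = np.where(obs, X - col_mu, 0.0)
    recon = np.tile(col_mu, (X.shape[0], 1))
    obs_f = obs.astype(float)

    for _ in range(n_components):
        # start from the column with the largest observed variance
        j0 = int(np.argmax((R ** 2).sum(axis=0)))
        t = R[:, j0]
        if not np.any(t):
            break
        converged = False
        for _ in range(max_iter):
            denom_p = obs_f.T @ (t * t)
            p = (R.T @ t) / np.where(denom_p > 0, denom_p, 1.0)
            nrm = np.linalg.norm(p)
            if nrm == 0:
                break
            p /= nrm
            denom_t = obs_f @ (p * p)
            t_new = (R @ p) / np.where(denom_t > 0, denom_t, 1.0)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t), 1.0):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            raise RuntimeError(
                f"NIPALS failed to converge within {max_iter} iterations "
                f"(component score norm {np.linalg.norm(t):.3g})")
        comp = np.outer(t, p)
        recon += comp
        R = np.where(obs, R - comp, 0.0)
    return recon


def _default_components(X: np.ndarray, miss: np.ndarray, cap: int = 10,
                        explained: float = 0.95) -> int:
    complete = ~miss.any(axis=1)
    if complete.sum() >= 3:
        Xc = X[complete] - X[complete].mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        var = sv ** 2
        cum = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(cum, explained) + 1)
    else:
        k = cap
    return max(1, min(k, cap, min(X.shape) - 1))


def zscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-scale columns (sample SD, n-1); returns (scaled, mean, sd).

    Raises on zero-variance columns: a constant marker carries no signal and
    would divide by zero.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("zscale requires a complete matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        cols = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance columns: {cols.tolist()}")
    return (X - mu) / sd, mu, sd


def apply_scaling(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Project new data onto a previously fitted z-scale."""
    return (np.asarray(X, dtype=float) - np.asarray(mu)) / np.asarray(sd)


def run_qc(dataset: CohortDataset, panel: MetabolitePanel,
           max_missing: int = 0, zero_forbidden: bool = True,
           sd_limit: float = 5.0, sd_basis: str = "filtered",
           n_components: int | None = None, scale: bool = True
           ) -> tuple[CohortDataset, QCReport]:
    """Full QC pass: panel restriction, sample filters, NIPALS imputation of
    residual missing cells, and (optionally) z-scaling.

    The returned dataset carries imputed, optionally z-scaled metabolite
    columns; scaling parameters live in the report.
    """
    ds = select_panel(dataset, panel)
    ds, report = filter_samples(ds, max_missing=max_missing,
                                zero_forbidden=zero_forbidden,
                                sd_limit=sd_limit, sd_basis=sd_basis)
    X = ds.metabolite_matrix()
    if np.isnan(X).any():
        X, n_imp = impute_nipals(X, n_components=n_components)
        report.n_cells_imputed = n_imp
        report.imputed_fraction = n_imp / X.size
    if scale:
        Xs, mu, sd = zscale(X)
        report.scaling_mean = dict(zip(ds.metabolite_cols, mu.tolist()))
        report.scaling_sd = dict(zip(ds.metabolite_cols, sd.tolist()))
        X = Xs
    df = ds.df.copy()
    df[ds.metabolite_cols] = X
    return ds.replace(df), report
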