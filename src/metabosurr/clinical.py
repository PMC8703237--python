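"""Derivation of dichotomous clinical variables.

Continuous risk factors are split into "normal" vs "at risk" at accepted
clinical thresholds, composite variables (LDL cholesterol via the Friedewald
equation, eGFR via the 2009 creatinine-based CKD-EPI equation, sex-specific
obesity, high blood pressure, low haemoglobin) are composed from their raw
inputs, and missingness propagates: a derived value is missing whenever any
required input is missing, never silently FALSE.

All thresholds live in a versioned YAML spec file
(``data/clinical_thresholds.yaml``), not in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = ["friedewald_ldl", "ckdepi_egfr", "BinaryPhenotypeSpec",
           "Condition", "load_threshold_specs", "derive_binary", "derive_all",
           "compose_variables"]

#: Friedewald estimation is invalid above this triglyceride level (mmol/L)
FRIEDEWALD_TG_LIMIT = 4.5


def friedewald_ldl(total_chol, hdl, triglycerides):
    """LDL cholesterol (mmol/L) by the Friedewald equation.

    LDL = TC - HDL - TG/2.2 (all in mmol/L). Returns NaN where TG exceeds
    4.5 mmol/L (the equation's validity bound) or any input is missing.
    Raises on negative inputs.
    """
    tc = np.asarray(total_chol, dtype=float)
    h = np.asarray(hdl, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    for nm, v in (("total_chol", tc), ("hdl", h), ("triglycerides", tg)):
        if np.any(v[np.isfinite(v)] < 0):
            raise ValueError(f"negative {nm} values")
    ldl = tc - h - tg / 2.2
    ldl = np.where(tg > FRIEDEWALD_TG_LIMIT, np.nan, ldl)
    return ldl if ldl.ndim else float(ldl)


def ckdepi_egfr(creatinine, age, sex, creatinine_units: str = "umol/L",
                race_black=False):
    """eGFR (mL/min/1.73 m2) by the 2009 creatinine-based CKD-EPI equation.

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
    * 1.018 [if female] (* 1.159 [if race_black]), with Scr in mg/dL,
    k = 0.7 (female) / 0.9 (male), a = -0.329 (female) / -0.411 (male).

    ``sex`` is coded 1 = male, 0 = female. Creatinine units must be declared
    explicitly ('umol/L' or 'mg/dL'); silent unit guessing is a known failure
    mode. The race coefficient defaults to off.
    """
    scr = np.asarray(creatinine, dtype=float)
    if creatinine_units == "umol/L":
        scr = scr / 88.42
    elif creatinine_units != "mg/dL":
        raise ValueError("creatinine_units must be 'umol/L' or 'mg/dL'")
    if np.any(scr[np.isfinite(scr)] <= 0):
        raise ValueError("creatinine must be positive")
    a = np.asarray(age, dtype=float)
    male = np.asarray(sex, dtype=float) == 1
    kappa = np.where(male, 0.9, 0.7)
    alpha = np.where(male, -0.411, -0.329)
    ratio = scr / kappa
    egfr = (141.0
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993 ** a
            * np.where(male, 1.0, 1.018))
    if np.any(np.asarray(race_black)):
        egfr = egfr * np.where(np.asarray(race_black, dtype=bool), 1.159, 1.0)
    return egfr if egfr.ndim else float(egfr)


@dataclass(frozen=True)
class Condition:
    source: str
    comparator: str            # ge | le | gt | lt | band | flag
    threshold: object = None   # float, {male,female} map, or {low,high} band

    def sex_specific(self) -> bool:
        return isinstance(self.threshold, dict) and "male" in self.threshold


@dataclass(frozen=True)
class BinaryPhenotypeSpec:
    """One dichotomous clinical variable: TRUE iff all conditions hold."""

    name: str
    conditions: tuple[Condition, ...]
    units: str | None = None

    def sources(self) -> list[str]:
        return [c.source for c in self.conditions]


def load_threshold_specs(path=None) -> dict[str, BinaryPhenotypeSpec]:
    """Load the phenotype spec file (shipped default: the 20-variable set)."""
    if path is None:
        text = (resources.files("metabosurr") / "data" /
                "clinical_thresholds.yaml").read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = {}
    for entry in raw["phenotypes"]:
        conds = tuple(Condition(**c) for c in entry["conditions"])
        specs[entry["name"]] = BinaryPhenotypeSpec(
            name=entry["name"], conditions=conds, units=entry.get("units"))
    return specs


def _resolve_threshold(cond: Condition, sex: np.ndarray | None):
    if not cond.sex_specific():
        return cond.threshold, None
    if sex is None:
        raise ValueError(
            f"condition on {cond.source!r} is sex-specific but no sex "
            "column was provided")
    male = np.asarray(sex, dtype=float)
    thr = np.where(male == 1, cond.threshold["male"], cond.threshold["female"])
    sex_missing = ~np.isfinite(male)
    return thr, sex_missing


def _apply_condition(values: np.ndarray, cond: Condition,
                     sex: np.ndarray | None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Returns (truth array, missing mask) for one condition."""
    x = np.asarray(values, dtype=float)
    missing = ~np.isfinite(x)
    if cond.comparator == "flag":
        return x == 1, missing
    if cond.comparator == "band":
        lo, hi = cond.threshold["low"], cond.threshold["high"]
        return (x >= lo) & (x < hi), missing
    thr, sex_missing = _resolve_threshold(cond, sex)
    if sex_missing is not None:
        missing = missing | sex_missing
    op = {"ge": np.greater_equal, "le": np.less_equal,
          "gt": np.greater, "lt": np.less}[cond.comparator]
    with np.errstate(invalid="ignore"):
        return op(x, thr), missing


def derive_binary(df: pd.DataFrame, spec: BinaryPhenotypeSpec) -> pd.Series:
    """Evaluate one phenotype spec over a frame of raw/composed variables.

    Returns a nullable-boolean Series: TRUE iff every condition holds, FALSE
    if any condition fails on complete inputs, NA whenever a required input
    (or sex, for sex-specific thresholds) is missing.
    """
    absent = [c.source for c in spec.conditions if c.source not in df.columns]
    if absent:
        raise KeyError(f"{spec.name}: required inputs absent: {absent}")
    sex = df["sex"].to_numpy(dtype=float) if "sex" in df.columns else None
    truth = np.ones(len(df), dtype=bool)
    missing = np.zeros(len(df), dtype=bool)
    for cond in spec.conditions:
        t, m = _apply_condition(df[cond.source].to_numpy(dtype=float),
                                cond, sex)
        truth &= np.where(m, False, t)
        missing |= m
    out = pd.array(truth, dtype="boolean")
    out[missing] = pd.NA
    return pd.Series(out, index=df.index, name=spec.name)


def compose_variables(df: pd.DataFrame,
                      creatinine_units: str = "umol/L") -> pd.DataFrame:
    """Add the composed inputs (``ldl_chol``, ``egfr``) where computable."""
    out = df.copy()
    if {"total_chol", "hdl_chol", "triglycerides"} <= set(df.columns) \
            and "ldl_chol" not in df.columns:
        out["ldl_chol"] = friedewald_ldl(df["total_chol"], df["hdl_chol"],
                                         df["triglycerides"])
    if {"creatinine", "age", "sex"} <= set(df.columns) \
            and "egfr" not in df.columns:
        out["egfr"] = ckdepi_egfr(df["creatinine"], df["age"], df["sex"],
                                  creatinine_units=creatinine_units)
    return out


def derive_all(df: pd.DataFrame,
               specs: dict[str, BinaryPhenotypeSpec] | None = None,
               creatinine_units: str = "umol/L") -> pd.DataFrame:
    """Derive every phenotype whose inputs are present.

    Composes ``ldl_chol``/``egfr`` first, then applies each spec; specs whose
    inputs are entirely absent are skipped.
    """
    specs = specs or load_threshold_specs()
    base = compose_variables(df, creatinine_units=creatinine_units)
    out = {}
    for name, spec in specs.items():
        if all(c.source in base.columns for c in spec.conditions):
            out[name] = derive_binary(base, spec)
    return pd.DataFrame(out, index=df.index)
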