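"""Sex/age partitioning decisions via standardized regression and SDRs.

The decision rule is the standard-deviation ratio: the between-group SD of
a factor divided by the residual SD, with a strict cutoff (default 0.4).
Between-group SDs come from a method-of-moments decomposition of the
two-way sex x age-band layout on the Box-Cox-transformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateVarianceError,
    DomainError,
    SingularDesignError,
    UnbalancedDesignError,
)
from .preprocessing import (
    DEFAULT_AGE_BANDS,
    assign_age_band,
    boxcox_transform,
    estimate_boxcox_lambda,
)

SDR_CUTOFF = 0.4


@dataclass(frozen=True)
class PartitionAnalysis:
    analyte: str
    std_coefficients: dict[str, float]
    sd_sex: float
    sd_age: float
    sd_residual: float
    sdr_sex: float
    sdr_age: float
    partition_by_sex: bool
    partition_by_age: bool
    cutoff: float = SDR_CUTOFF


def partition_decision(sdr: float, cutoff: float = SDR_CUTOFF) -> bool:
    """True iff sdr strictly exceeds the cutoff."""
    if sdr < 0:
        raise DomainError("SDR must be >= 0")
    if cutoff <= 0:
        raise DomainError("cutoff must be > 0")
    return sdr > cutoff


def _analyte_values(table: pd.DataFrame, analyte: str | None) -> pd.DataFrame:
    if analyte is not None:
        table = table[table["analyte"] == analyte]
    if table.empty:
        raise DomainError(f"no rows for analyte {analyte!r}")
    return table


def _transformed(values: np.ndarray, lam: float | None) -> np.ndarray:
    if lam is None:
        lam = estimate_boxcox_lambda(values).lam
    return np.asarray(boxcox_transform(values, lam))


def standardized_regression(
    table: pd.DataFrame, analyte: str | None = None, lam: float | None = None
) -> dict[str, float]:
    """OLS of the z-scored transformed value on z-scored sex and age.

    Returns standardized coefficients keyed by factor name.  Raises
    :class:`SingularDesignError` when a predictor is constant (e.g. a
    single-sex table).
    """
    sub = _analyte_values(table, analyte)
    y = _transformed(sub["value"].to_numpy(dtype=float), lam)
    male = (sub["sex"].to_numpy() == "M").astype(float)
    age = sub["age"].to_numpy(dtype=float)
    X = np.column_stack([male, age])
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = ["sex", "age"][int(np.flatnonzero(sd == 0)[0])]
        raise SingularDesignError(f"constant predictor: {bad}")
    if y.std(ddof=0) == 0:
        raise SingularDesignError("constant response")
    Xz = (X - X.mean(axis=0)) / sd
    yz = (y - y.mean()) / y.std(ddof=0)
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(yz), Xz]), yz, rcond=None)
    return {"sex": float(beta[1]), "age": float(beta[2])}


def variance_components(
    table: pd.DataFrame,
    analyte: str | None = None,
    lam: float | None = None,
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
) -> tuple[float, float, float]:
    """(sd_sex, sd_age, sd_residual) on the transformed scale.

    Method-of-moments on the crossed sex x age-band layout: the residual SD
    is the pooled within-cell SD; each factor's between-group variance is
    the noise-corrected dispersion of its level means,
    ``SS_factor/N - (levels-1)*MS_e/N``, truncated at zero.
    """
    sub = _analyte_values(table, analyte)
    y = _transformed(sub["value"].to_numpy(dtype=float), lam)
    sex = sub["sex"].to_numpy()
    band = assign_age_band(sub["age"].to_numpy(), age_bands)

    n_total = y.size
    sse = 0.0
    df_e = 0
    for s in ("F", "M"):
        for lo, hi in age_bands:
            label = f"{lo}-{hi - 1}"
            cell = y[(sex == s) & (band == label)]
            if cell.size == 0:
                raise UnbalancedDesignError(f"empty cell: sex={s}, age band {label}")
            sse += float(np.sum((cell - cell.mean()) ** 2))
            df_e += cell.size - 1
    if df_e == 0:
        raise DegenerateVarianceError("no residual degrees of freedom")
    ms_e = sse / df_e

    grand = y.mean()

    def between_var(labels: np.ndarray) -> float:
        levels = np.unique(labels)
        ss = sum(
            (labels == lv).sum() * (y[labels == lv].mean() - grand) ** 2 for lv in levels
        )
        var = ss / n_total - (len(levels) - 1) * ms_e / n_total
        return max(0.0, float(var))

    sd_sex = float(np.sqrt(between_var(sex)))
    sd_age = float(np.sqrt(between_var(band)))
    sd_residual = float(np.sqrt(ms_e))
    return sd_sex, sd_age, sd_residual


def analyze_partition(
    table: pd.DataFrame,
    analyte: str | None = None,
    cutoff: float = SDR_CUTOFF,
    lam: float | None = None,
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
) -> PartitionAnalysis:
    """Full partition analysis: coefficients, SDs, SDRs and the decisions."""
    sub = _analyte_values(table, analyte)
    name = analyte if analyte is not None else str(sub["analyte"].iloc[0])
    if lam is None:
        lam = estimate_boxcox_lambda(sub["value"].to_numpy(dtype=float)).lam
    coeffs = standardized_regression(sub, lam=lam)
    sd_sex, sd_age, sd_residual = variance_components(sub, lam=lam, age_bands=age_bands)
    if sd_residual == 0:
        raise DegenerateVarianceError("residual SD is zero; SDR undefined")
    sdr_sex = sd_sex / sd_residual
    sdr_age = sd_age / sd_residual
    return PartitionAnalysis(
        analyte=name,
        std_coefficients=coeffs,
        sd_sex=sd_sex,
        sd_age=sd_age,
        sd_residual=sd_residual,
        sdr_sex=sdr_sex,
        sdr_age=sdr_age,
        partition_by_sex=partition_decision(sdr_sex, cutoff),
        partition_by_age=partition_decision(sdr_age, cutoff),
        cutoff=cutoff,
    )
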