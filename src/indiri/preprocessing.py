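"""Two-step preprocessing: stratified balancing, Box-Cox transform, Tukey fences.

The pipeline balances sex and decade-of-age strata by downsampling, then
removes outliers on the Box-Cox-transformed scale within each stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger("indiri")

from .exceptions import DomainError, InsufficientDataError, UnbalanceableError

#: The four decade bands used for age stratification, as half-open [lo, hi).
DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = ((18, 30), (30, 40), (40, 50), (50, 60))

LAMBDA_BOUNDS = (-2.0, 2.0)


@dataclass(frozen=True)
class BoxCoxParam:
    """A Box-Cox exponent; ``lam == 0`` selects the log branch."""

    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam):
            raise DomainError("Box-Cox lambda must be finite")


@dataclass(frozen=True)
class TukeyResult:
    """Outcome of Tukey fencing on one subgroup.

    ``kept``/``removed`` are in the input's (original) units; ``fences`` and
    ``quartiles`` are on the scale the fences were computed on.
    """

    kept: np.ndarray
    removed: np.ndarray
    fences: tuple[float, float]
    quartiles: tuple[float, float]


def _as_positive_array(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if np.any(~np.isfinite(x)):
        raise DomainError("values must be finite")
    if np.any(x <= 0):
        raise DomainError("Box-Cox requires strictly positive values")
    return x


def _snap_lambda(lam: float | BoxCoxParam) -> float:
    """Exponents below double precision's resolution collapse to the log branch."""
    lam = lam.lam if isinstance(lam, BoxCoxParam) else float(lam)
    return 0.0 if abs(lam) < 1e-12 else lam


def boxcox_transform(values, lam: float | BoxCoxParam):
    """Apply y = (x**lam - 1)/lam (lam != 0) or ln x (lam == 0).

    Strictly increasing in x for every lambda; raises :class:`DomainError`
    on non-positive input.
    """
    lam = _snap_lambda(lam)
    scalar = np.isscalar(values)
    x = _as_positive_array(np.atleast_1d(values))
    y = special.boxcox(x, lam)  # stable near lam = 0 (expm1 formulation)
    return float(y[0]) if scalar else y


def inverse_boxcox(values, lam: float | BoxCoxParam):
    """Invert :func:`boxcox_transform`.

    For lam != 0 the inverse is (lam*y + 1)**(1/lam), defined for
    lam*y + 1 > 0.  The lam == 1 branch (x = y + 1) is defined everywhere.
    """
    lam = _snap_lambda(lam)
    scalar = np.isscalar(values)
    y = np.asarray(np.atleast_1d(values), dtype=float)
    if lam != 0.0 and np.any(lam * y + 1.0 <= 0):
        if abs(lam - 1.0) < 1e-12:
            x = y + 1.0  # the lam = 1 branch is defined on the whole line
            return float(x[0]) if scalar else x
        raise DomainError("inverse Box-Cox undefined: lam*y + 1 <= 0")
    x = special.inv_boxcox(y, lam)  # stable near lam = 0 (log1p formulation)
    return float(x[0]) if scalar else x


def estimate_boxcox_lambda(values, bounds: tuple[float, float] = LAMBDA_BOUNDS) -> BoxCoxParam:
    """Profile-likelihood Box-Cox lambda on a bounded interval.

    Maximizes the Gaussian profile log-likelihood of the transformed sample
    (``scipy.stats.boxcox_llf``) over ``bounds`` (default [-2, 2]).
    """
    x = _as_positive_array(values)
    if x.size < 20:
        raise InsufficientDataError(f"need >= 20 values to estimate lambda, got {x.size}")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-5},
    )
    return BoxCoxParam(float(res.x))


def tukey_filter(values, k: float = 1.5, lam: float | BoxCoxParam | None = None) -> TukeyResult:
    """Fence out values beyond [Q1 - k*IQR, Q3 + k*IQR].

    If ``lam`` is given the quartiles and fences are computed on the
    Box-Cox-transformed values; ``kept``/``removed`` are always reported in
    the original units.  Quartiles use linear interpolation of order
    statistics (numpy's default).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise InsufficientDataError(f"Tukey fences need >= 4 values, got {x.size}")
    t = boxcox_transform(x, lam) if lam is not None else x
    q1, q3 = np.quantile(t, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    inside = (t >= lo) & (t <= hi)
    return TukeyResult(
        kept=x[inside],
        removed=x[~inside],
        fences=(float(lo), float(hi)),
        quartiles=(float(q1), float(q3)),
    )


def assign_age_band(ages, age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS) -> np.ndarray:
    """Label each age with its half-open band, or '' if out of range."""
    ages = np.asarray(ages)
    labels = np.full(ages.shape, "", dtype=object)
    for lo, hi in age_bands:
        labels[(ages >= lo) & (ages < hi)] = f"{lo}-{hi - 1}"
    return labels


def deduplicate_last(table: pd.DataFrame, subject_col: str = "subject_id") -> pd.DataFrame:
    """Keep only the last record per (subject, analyte); no-op without ids."""
    if subject_col not in table.columns:
        return table
    return table.drop_duplicates(subset=[subject_col, "analyte"], keep="last").reset_index(drop=True)


def balance_strata(
    table: pd.DataFrame,
    target_sex_ratio: float = 0.5,
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Downsample so every sex x age-band cell has the same size.

    With ``target_sex_ratio`` 0.5 the result has an exact 1:1 sex ratio and
    equal counts in every cell (the minimum cell count).  Other ratios scale
    the male quota relative to the female quota.  Sampling is without
    replacement and deterministic under ``seed``.
    """
    if not 0 < target_sex_ratio < 1:
        raise DomainError("target_sex_ratio must be in (0, 1)")
    bands = assign_age_band(table["age"].to_numpy(), age_bands)
    cells: dict[tuple[str, str], np.ndarray] = {}
    for lo, hi in age_bands:
        label = f"{lo}-{hi - 1}"
        for sex in ("F", "M"):
            idx = np.flatnonzero((bands == label) & (table["sex"].to_numpy() == sex))
            if idx.size == 0:
                raise UnbalanceableError(f"empty cell: sex={sex}, age band {label}")
            cells[(sex, label)] = idx
    min_f = min(v.size for (s, _), v in cells.items() if s == "F")
    min_m = min(v.size for (s, _), v in cells.items() if s == "M")
    r = target_sex_ratio
    quota_m = min(min_m, int(np.floor(min_f * r / (1 - r))))
    quota_f = min(min_f, int(np.floor(quota_m * (1 - r) / r)))
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for (sex, _), idx in sorted(cells.items()):
        quota = quota_m if sex == "M" else quota_f
        keep.append(np.sort(rng.choice(idx, size=quota, replace=False)))
    kept = np.sort(np.concatenate(keep))
    return table.iloc[kept].reset_index(drop=True)


def filter_subgroups(
    table: pd.DataFrame,
    k: float = 1.5,
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
    lam: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tukey-filter each analyte within each sex x age-band subgroup.

    The transform parameter is estimated per analyte (across its subgroups)
    unless ``lam`` is supplied.  Returns (kept, removed) tables.
    """
    table = table.reset_index(drop=True)
    band_col = pd.Series(assign_age_band(table["age"].to_numpy(), age_bands), index=table.index)
    kept_parts: list[pd.DataFrame] = []
    removed_parts: list[pd.DataFrame] = []
    for analyte, sub in table.groupby("analyte", sort=True):
        lam_a = lam
        if lam_a is None:
            vals = sub["value"].to_numpy()
            lam_a = estimate_boxcox_lambda(vals).lam if vals.size >= 20 else 1.0
        for (sex, band), cell in sub.groupby([sub["sex"], band_col.loc[sub.index]]):
            vals = cell["value"].to_numpy()
            if vals.size < 4:
                kept_parts.append(cell)
                continue
            res = tukey_filter(vals, k=k, lam=lam_a)
            t = boxcox_transform(vals, lam_a)
            inside = (t >= res.fences[0]) & (t <= res.fences[1])
            kept_parts.append(cell[inside])
            removed_parts.append(cell[~inside])
            log.info(
                "tukey %s sex=%s band=%s: kept %d, removed %d",
                analyte, sex, band, int(inside.sum()), int((~inside).sum()),
            )
    kept = pd.concat(kept_parts).sort_index().reset_index(drop=True) if kept_parts else table.iloc[:0]
    removed = (
        pd.concat(removed_parts).sort_index().reset_index(drop=True)
        if removed_parts
        else table.iloc[:0]
    )
    return kept, removed
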