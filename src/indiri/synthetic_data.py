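"""Synthetic mixed-cohort generator with known ground-truth quantiles.

Each cohort is a weighted mixture of components that are Gaussian on a
Box-Cox-transformed scale: a dominant healthy component plus minority
low/high pathological contamination.  Sex and age enter as additive effects
on the transformed scale, so the healthy reference interval of any spec is
available in closed form and serves as the recovery target for every
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DomainError
from .preprocessing import inverse_boxcox

HEALTHY = "healthy"
PATHO_LOW = "patho_low"
PATHO_HIGH = "patho_high"

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component, Gaussian on the Box-Cox(lam) scale."""

    weight: float
    lam: float
    mu: float
    sigma: float
    label: str

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DomainError("component sigma must be >= 0")
        if not 0 <= self.weight <= 1:
            raise DomainError("component weight must lie in [0, 1]")
        if self.label not in (HEALTHY, PATHO_LOW, PATHO_HIGH):
            raise DomainError(f"unknown component label {self.label!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Mixture + covariate description of one analyte's cohort."""

    analyte: str
    components: tuple[ComponentSpec, ...]
    sex_shift: float = 0.0
    age_slope: float = 0.0
    n: int = 1000
    sex_ratio: float = 0.5
    age_range: tuple[int, int] = (18, 59)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.n < 1:
            raise DomainError("n must be >= 1")
        lo, hi = self.age_range
        if not (18 <= lo <= hi < 60):
            raise DomainError("age_range must lie within [18, 60)")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise DomainError(f"component weights sum to {total}, not 1")
        healthy = self.healthy_component
        if any(c.weight > healthy.weight for c in self.components if c.label != HEALTHY):
            raise DomainError("healthy component must carry the largest weight")

    @property
    def healthy_component(self) -> ComponentSpec:
        for c in self.components:
            if c.label == HEALTHY:
                return c
        raise DomainError("spec has no healthy component")

    @property
    def age_midpoint(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw ``spec.n`` rows of (analyte, value, sex, age, truth_label).

    Each row samples a component by weight, draws Gaussian(mu + covariate
    effects, sigma) on the transformed scale, and back-transforms.  Draws
    for which the inverse transform is undefined (or non-positive) are
    redrawn; a rejection rate above 10% is an error.
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    lo, hi = spec.age_range
    sex = np.where(rng.random(n) < spec.sex_ratio, "M", "F")
    age = rng.integers(lo, hi + 1, size=n)
    weights = np.array([c.weight for c in spec.components])
    comp = rng.choice(len(spec.components), size=n, p=weights)

    mus = np.array([c.mu for c in spec.components])[comp]
    sigmas = np.array([c.sigma for c in spec.components])[comp]
    lams = np.array([c.lam for c in spec.components])[comp]
    mean = mus + spec.sex_shift * (sex == "M") + spec.age_slope * (age - spec.age_midpoint)

    values = np.empty(n)
    pending = np.arange(n)
    rejected = 0
    for _ in range(100):
        y = mean[pending] + sigmas[pending] * rng.standard_normal(pending.size)
        lam_p = lams[pending]
        base = np.where(lam_p == 0.0, 1.0, lam_p * y + 1.0)
        ok = base > 0
        x = np.full(pending.size, np.nan)
        lam_ok, y_ok, base_ok = lam_p[ok], y[ok], base[ok]
        logx = np.empty(lam_ok.size)
        zero = lam_ok == 0.0
        logx[zero] = y_ok[zero]
        logx[~zero] = np.log(base_ok[~zero]) / lam_ok[~zero]
        x[ok] = np.exp(logx)
        ok &= x > 0
        values[pending[ok]] = x[ok]
        rejected += int((~ok).sum())
        pending = pending[~ok]
        if pending.size == 0:
            break
        if rejected / (n + rejected) > 0.10:
            raise DomainError(
                f"rejection rate {rejected / (n + rejected):.1%} exceeds 10%; "
                "spec puts too much mass outside the Box-Cox domain"
            )
    else:  # pragma: no cover - bounded by the rate check above
        raise DomainError("could not complete sampling within 100 redraw rounds")

    labels = np.array([c.label for c in spec.components], dtype=object)[comp]
    return pd.DataFrame(
        {
            "analyte": spec.analyte,
            "value": values,
            "sex": sex,
            "age": age,
            "truth_label": labels,
        }
    )


def ground_truth_ri(spec: CohortSpec, sex: str | None = None) -> tuple[float, float]:
    """Closed-form healthy 2.5/97.5 percentiles on the measurement scale.

    With a single sex (or no sex effect) and no age slope this is the
    inverse transform of mu +/- 1.96*sigma.  Otherwise the healthy marginal
    (mixed over sexes and uniform integer ages) is inverted numerically.
    """
    h = spec.healthy_component
    if h.sigma == 0:
        x = inverse_boxcox(h.mu, h.lam)
        return (x, x)
    shifts = _healthy_shifts(spec, sex)
    if len(shifts) == 1:
        mu = h.mu + shifts[0]
        return (
            inverse_boxcox(mu - Z95 * h.sigma, h.lam),
            inverse_boxcox(mu + Z95 * h.sigma, h.lam),
        )
    return tuple(
        inverse_boxcox(_mixture_quantile(h.mu + np.asarray(shifts), h.sigma, p), h.lam)
        for p in (0.025, 0.975)
    )


def _healthy_shifts(spec: CohortSpec, sex: str | None) -> list[float]:
    """Enumerate the additive transformed-scale offsets of the healthy marginal."""
    sex_offsets: Iterable[float]
    if sex == "M":
        sex_offsets = [spec.sex_shift]
    elif sex == "F":
        sex_offsets = [0.0]
    elif spec.sex_shift == 0.0:
        sex_offsets = [0.0]
    else:
        sex_offsets = [0.0, spec.sex_shift]  # sex_ratio-weighted below
    lo, hi = spec.age_range
    if spec.age_slope == 0.0:
        ages = [0.0]
    else:
        ages = list(spec.age_slope * (np.arange(lo, hi + 1) - spec.age_midpoint))
    shifts = [s + a for s in sex_offsets for a in ages]
    if len(shifts) == 1:
        return shifts
    return shifts


def _mixture_quantile(mus: np.ndarray, sigma: float, p: float) -> float:
    """Quantile of an equal-weight Gaussian location mixture via brentq."""
    mus = np.asarray(mus, dtype=float)

    def cdf(t: float) -> float:
        return float(np.mean(stats.norm.cdf((t - mus) / sigma))) - p

    lo = mus.min() - 10 * sigma
    hi = mus.max() + 10 * sigma
    return float(optimize.brentq(cdf, lo, hi, xtol=1e-10))


def _mixture_spec(
    analyte: str,
    lam: float,
    mu: float,
    sigma: float,
    n: int,
    sex_shift: float = 0.0,
    low_weight: float = 0.05,
    high_weight: float = 0.05,
    low_shift_sd: float = 4.0,
    high_shift_sd: float = 4.0,
) -> CohortSpec:
    healthy_w = round(1.0 - low_weight - high_weight, 12)
    components = [ComponentSpec(healthy_w, lam, mu, sigma, HEALTHY)]
    if low_weight > 0:
        components.append(ComponentSpec(low_weight, lam, mu - low_shift_sd * sigma, sigma, PATHO_LOW))
    if high_weight > 0:
        components.append(
            ComponentSpec(high_weight, lam, mu + high_shift_sd * sigma, sigma, PATHO_HIGH)
        )
    return CohortSpec(analyte=analyte, components=tuple(components), sex_shift=sex_shift, n=n)


def thyroid_panel_spec(n: int, contamination: float = 0.10) -> dict[str, CohortSpec]:
    """Default five-analyte panel of cohort specs.

    TSH is strongly right-skewed (log-normal healthy core); the other four
    are near-Gaussian.  FT3 and FT4 carry a sex shift large enough to
    trigger sex partitioning.  ``contamination`` is split evenly between a
    low and a high pathological component.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if not 0 <= contamination < 0.5:
        raise DomainError("contamination must lie in [0, 0.5)")
    w = contamination / 2.0
    # healthy cores chosen so the closed-form RIs resemble adult thyroid panels
    tsh_mu = 0.5 * (np.log(0.8) + np.log(4.2))
    tsh_sigma = (np.log(4.2) - np.log(0.8)) / (2 * Z95)
    return {
        "TSH": _mixture_spec("TSH", 0.0, tsh_mu, tsh_sigma, n, low_weight=w, high_weight=w),
        "FT3": _mixture_spec("FT3", 1.0, 2.00, 0.25, n, sex_shift=0.35, low_weight=w, high_weight=w),
        "FT4": _mixture_spec("FT4", 1.0, 0.20, 0.12, n, sex_shift=0.12, low_weight=w, high_weight=w),
        "TT3": _mixture_spec("TT3", 1.0, 0.10, 0.15, n, low_weight=w, high_weight=w),
        "TT4": _mixture_spec("TT4", 1.0, 6.75, 1.17, n, low_weight=w, high_weight=w),
    }


def write_measurements(table: pd.DataFrame, path) -> None:
    """CSV with header analyte,value,sex,age,truth_label."""
    cols = [c for c in ("analyte", "value", "sex", "age", "truth_label") if c in table.columns]
    table.to_csv(path, index=False, columns=cols)
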