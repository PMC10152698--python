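"""Gold-standard reference interval: transformed parametric method.

Transform toward normality (Box-Cox, or fixed log), take m +/- 1.96 s on
the transformed scale, back-transform, and attach percentile-bootstrap 90%
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import DegenerateVarianceError, DomainError, InsufficientDataError, UnstableEstimatorError
from .preprocessing import boxcox_transform, estimate_boxcox_lambda, inverse_boxcox

Z95 = 1.959963984540054

CIPair = tuple[float, float]


@dataclass(frozen=True)
class ReferenceInterval:
    """Lower/upper limits with 90% CIs on the measurement scale.

    CIs default to zero-width intervals at the point estimates; when set,
    each CI is widened (if needed) to contain its limit.
    """

    ll: float
    ul: float
    ci_ll: CIPair | None = None
    ci_ul: CIPair | None = None
    method: str = ""
    subgroup: str = "T"

    def __post_init__(self) -> None:
        if not self.ll < self.ul:
            raise DomainError(f"require ll < ul, got ({self.ll}, {self.ul})")
        object.__setattr__(self, "ci_ll", _contain(self.ci_ll, self.ll))
        object.__setattr__(self, "ci_ul", _contain(self.ci_ul, self.ul))

    @property
    def width(self) -> float:
        return self.ul - self.ll


def _contain(ci: CIPair | None, point: float) -> CIPair:
    if ci is None:
        return (point, point)
    lo, hi = float(min(ci)), float(max(ci))
    return (min(lo, point), max(hi, point))


def transformed_parametric_ri(
    values,
    lam: float | str = 0.0,
    min_n: int = 120,
    method: str = "transformed_parametric",
    subgroup: str = "T",
) -> ReferenceInterval:
    """Box-Cox parametric RI: back-transformed m +/- 1.96 s.

    ``lam`` may be a number or ``"auto"`` (profile-likelihood estimate); the
    default is the log branch.  The SD is the maximum-likelihood (ddof=0)
    estimate, matching a one-component Gaussian fit.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} values, got {x.size}")
    if np.any(x <= 0):
        raise DomainError("transformed parametric RI requires positive values")
    lam_val = estimate_boxcox_lambda(x).lam if lam == "auto" else float(lam)
    y = np.asarray(boxcox_transform(x, lam_val))
    m = y.mean()
    s = y.std(ddof=0)
    if s == 0:
        raise DegenerateVarianceError("constant sample: zero variance on transformed scale")
    return ReferenceInterval(
        ll=float(inverse_boxcox(m - Z95 * s, lam_val)),
        ul=float(inverse_boxcox(m + Z95 * s, lam_val)),
        method=method,
        subgroup=subgroup,
    )


def bootstrap_ci(
    values,
    estimator: Callable[[np.ndarray], "ReferenceInterval | tuple[float, float]"],
    B: int = 100,
    level: float = 0.90,
    seed: int = 0,
    max_failure_rate: float = 0.20,
) -> tuple[CIPair, CIPair]:
    """Percentile-bootstrap CIs of (LL, UL) over B resamples.

    The estimator is re-run in full on each resample; replicate failures are
    tolerated up to ``max_failure_rate``.  Each CI is widened (if needed) to
    contain the full-sample point estimate, so CIs contain their limits by
    construction.  Deterministic under ``seed``.
    """
    if B < 2:
        raise DomainError("B must be >= 2")
    if not 0 < level < 1:
        raise DomainError("level must lie in (0, 1)")
    x = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    point = _limits(estimator(x))
    lls, uls = [], []
    failures = 0
    for _ in range(B):
        resample = x[rng.integers(0, x.size, size=x.size)]
        try:
            ll, ul = _limits(estimator(resample))
        except Exception:
            failures += 1
            continue
        lls.append(ll)
        uls.append(ul)
    if failures > max_failure_rate * B:
        raise UnstableEstimatorError(f"estimator failed on {failures}/{B} bootstrap resamples")
    alpha = (1.0 - level) / 2.0
    ci_ll = tuple(np.quantile(lls, [alpha, 1 - alpha]))
    ci_ul = tuple(np.quantile(uls, [alpha, 1 - alpha]))
    return _contain(ci_ll, point[0]), _contain(ci_ul, point[1])


def _limits(ri) -> tuple[float, float]:
    if isinstance(ri, ReferenceInterval):
        return (ri.ll, ri.ul)
    ll, ul = ri
    return (float(ll), float(ul))


def ci_width_ok(ri: ReferenceInterval, fraction: float = 0.2) -> bool:
    """True iff both CI widths are strictly below fraction * RI width."""
    limit = fraction * ri.width
    w_ll = ri.ci_ll[1] - ri.ci_ll[0]
    w_ul = ri.ci_ul[1] - ri.ci_ul[0]
    return w_ll < limit and w_ul < limit


def with_cis(ri: ReferenceInterval, ci_ll: CIPair, ci_ul: CIPair) -> ReferenceInterval:
    """Copy of ``ri`` carrying the given CIs (widened to contain the limits)."""
    return ReferenceInterval(
        ll=ri.ll, ul=ri.ul, ci_ll=ci_ll, ci_ul=ci_ul, method=ri.method, subgroup=ri.subgroup
    )
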