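"""Bias-ratio (BR) scoring of candidate RIs against a standard RI.

BR_LL = |LL - LL0| / SD_RI, BR_UL = |UL - UL0| / SD_RI with
SD_RI = (UL0 - LL0) / 3.92; BR above the threshold (default 0.375) flags a
clinically meaningful discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .direct_ri import ReferenceInterval
from .exceptions import InvalidReferenceError

BR_THRESHOLD = 0.375

Key = tuple[str, str, str]  # (method, analyte, subgroup)


@dataclass(frozen=True)
class BRResult:
    br_ll: float
    br_ul: float
    sd_ri: float
    flag_ll: bool
    flag_ul: bool
    threshold: float = BR_THRESHOLD


@dataclass(frozen=True)
class BRMatrix:
    entries: Mapping[Key, BRResult]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": m,
                "analyte": a,
                "subgroup": s,
                "BR_LL": r.br_ll,
                "BR_UL": r.br_ul,
                "SD_RI": r.sd_ri,
                "flag_LL": r.flag_ll,
                "flag_UL": r.flag_ul,
            }
            for (m, a, s), r in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


def _limits(ri) -> tuple[float, float]:
    if isinstance(ri, ReferenceInterval):
        return ri.ll, ri.ul
    ll, ul = ri
    return float(ll), float(ul)


def bias_ratio(test, standard, threshold: float = BR_THRESHOLD, decimals: int | None = None) -> BRResult:
    """Score a candidate RI against the standard RI.

    ``test`` and ``standard`` may be :class:`ReferenceInterval` objects or
    (ll, ul) pairs.  ``decimals`` optionally rounds all four limits before
    the arithmetic, to reproduce values derived from report-rounded tables.
    """
    ll, ul = _limits(test)
    ll0, ul0 = _limits(standard)
    if decimals is not None:
        ll, ul, ll0, ul0 = (round(v, decimals) for v in (ll, ul, ll0, ul0))
    if not ul0 > ll0:
        raise InvalidReferenceError(f"standard RI must have ll < ul, got ({ll0}, {ul0})")
    sd_ri = (ul0 - ll0) / 3.92
    br_ll = abs(ll - ll0) / sd_ri
    br_ul = abs(ul - ul0) / sd_ri
    return BRResult(
        br_ll=br_ll,
        br_ul=br_ul,
        sd_ri=sd_ri,
        flag_ll=br_ll > threshold,
        flag_ul=br_ul > threshold,
        threshold=threshold,
    )


def br_matrix(
    estimates: Mapping[Key, "ReferenceInterval | tuple[float, float]"],
    standards: Mapping[tuple[str, str], "ReferenceInterval | tuple[float, float]"],
    threshold: float = BR_THRESHOLD,
) -> BRMatrix:
    """One BRResult per estimate, each scored against its (analyte, subgroup) standard."""
    entries: dict[Key, BRResult] = {}
    for (method, analyte, subgroup), ri in estimates.items():
        key = (analyte, subgroup)
        if key not in standards:
            raise KeyError(f"no standard RI for (analyte={analyte!r}, subgroup={subgroup!r})")
        entries[(method, analyte, subgroup)] = bias_ratio(ri, standards[key], threshold)
    return BRMatrix(entries=entries)
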