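"""Group comparisons, correlation and dose-response regression.

Thin, validated wrappers over scipy.stats matching the reporting style used
for instability-index comparisons: two-tailed unpaired t-tests (Student's
equal-variance by default, Welch behind a flag), Pearson correlation with
R^2, and an ordinary least-squares dose-response line with a
significant-positive-slope flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "GroupSummary",
    "TTestResult",
    "PearsonResult",
    "DoseResponse",
    "summarize_groups",
    "two_sample_t",
    "pearson_r2",
    "dose_response_fit",
    "format_p",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float | None  # None when n == 1 (SD undefined)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    equal_var: bool


@dataclass(frozen=True)
class PearsonResult:
    r: float
    r2: float
    p: float
    n: int


@dataclass(frozen=True)
class DoseResponse:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    significant_increase: bool  # slope > 0 and p < 0.05


def summarize_groups(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    out = []
    for label, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if x.size < 1:
            raise ValueError(f"group {label!r} is empty")
        sd = float(x.std(ddof=1)) if x.size > 1 else None
        out.append(GroupSummary(label=str(label), n=int(x.size), mean=float(x.mean()), sd=sd))
    return out


def two_sample_t(x: Sequence[float], y: Sequence[float], equal_var: bool = True) -> TTestResult:
    """Two-tailed unpaired t-test (Student's pooled-variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    res = _st.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = x.size + y.size - 2
    else:
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue),
                       equal_var=equal_var)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson product-moment correlation with R^2 and t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = _st.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonResult(r=r, r2=r * r, p=float(res.pvalue), n=int(x.size))


def dose_response_fit(points: Sequence[tuple[float, float]]) -> DoseResponse:
    """Ordinary least-squares line through (dose, response) points.

    Flags a significant dose-dependent increase when the slope is positive
    with two-sided p < 0.05.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (dose, response) points")
    dose, resp = pts[:, 0], pts[:, 1]
    if np.unique(dose).size < 2:
        raise ValueError("need >= 2 distinct doses")
    fit = _st.linregress(dose, resp)
    r2 = float(fit.rvalue ** 2)
    return DoseResponse(
        slope=float(fit.slope), intercept=float(fit.intercept), r2=r2,
        p=float(fit.pvalue), n=int(pts.shape[0]),
        significant_increase=bool(fit.slope > 0 and fit.pvalue < 0.05),
    )


def format_p(p: float, floor: float = 1e-4) -> str:
    """Human-readable p-value: 4 significant figures, floored as '<0.0001'."""
    if p < floor:
        return f"<{floor:.4f}".rstrip("0")
    return f"{p:.4g}"
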