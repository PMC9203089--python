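"""Agreement statistics between predicted and serum bilirubin.

Conventions: the paired difference is **prediction − TSB** (a negative bias
means the device under-predicts); limits of agreement use the 1.96 multiplier
(95% LOA) on the sample (n−1) standard deviation; the skin-group comparison
is Welch's unequal-variance two-sided t-test on absolute errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError, InvalidParameterError

LOA_MULTIPLIER = 1.96


def r_squared(pred, tsb) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value."""
    pred = np.asarray(pred, dtype=float)
    tsb = np.asarray(tsb, dtype=float)
    if pred.size != tsb.size or pred.size < 3:
        raise InsufficientDataError("r_squared needs matched vectors of length >= 3")
    if np.std(pred) == 0 or np.std(tsb) == 0:
        raise InvalidParameterError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(pred, tsb)
    return float(r**2), float(p)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_upper: float
    loa_lower: float
    loa_span: float
    sd: float


def bland_altman(pred, tsb) -> BlandAltman:
    """Bias and 95% limits of agreement of prediction − TSB (mg/dL)."""
    pred = np.asarray(pred, dtype=float)
    tsb = np.asarray(tsb, dtype=float)
    if pred.size != tsb.size or pred.size < 2:
        raise InsufficientDataError("bland_altman needs matched vectors of length >= 2")
    d = pred - tsb
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    upper = bias + LOA_MULTIPLIER * sd
    lower = bias - LOA_MULTIPLIER * sd
    return BlandAltman(bias=bias, loa_upper=upper, loa_lower=lower,
                       loa_span=upper - lower, sd=sd)


def rmse_by_range(pred, tsb, edges) -> dict[str, float]:
    """Root-mean-square error per TSB bin ``(lo, hi]``; empty bins omitted."""
    pred = np.asarray(pred, dtype=float)
    tsb = np.asarray(tsb, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise InvalidParameterError("edges must be strictly increasing")
    out: dict[str, float] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (tsb > lo) & (tsb <= hi)
        if sel.any():
            out[f"{lo:g}-{hi:g}"] = float(
                np.sqrt(np.mean((pred[sel] - tsb[sel]) ** 2))
            )
    return out


def rmse_by_group(
    pred, tsb, groups, compare: tuple[str, str] | None = None
) -> tuple[dict[str, float], float]:
    """Per-group RMSE plus Welch's two-sided t-test p on absolute errors.

    ``compare`` names the two groups to test (default: the two largest);
    groups with fewer than 2 members are excluded from the test with a
    warning.
    """
    pred = np.asarray(pred, dtype=float)
    tsb = np.asarray(tsb, dtype=float)
    groups = np.asarray(groups)
    err = pred - tsb
    rmse: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for g in pd_unique(groups):
        sel = groups == g
        rmse[str(g)] = float(np.sqrt(np.mean(err[sel] ** 2)))
        sizes[str(g)] = int(sel.sum())
    eligible = [g for g, n in sizes.items() if n >= 2]
    if compare is None:
        ranked = sorted(eligible, key=lambda g: -sizes[g])
        compare = tuple(ranked[:2]) if len(ranked) >= 2 else None
    if compare is None or any(sizes.get(g, 0) < 2 for g in compare):
        import warnings

        warnings.warn("fewer than two groups with >= 2 members; t-test skipped",
                      stacklevel=2)
        return rmse, float("nan")
    a = np.abs(err[groups == compare[0]])
    b = np.abs(err[groups == compare[1]])
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        _t, p = sps.ttest_ind(a, b, equal_var=False)
    return rmse, float(p)


def pd_unique(values: np.ndarray) -> list:
    """Unique values in first-appearance order."""
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


@dataclass
class AgreementReport:
    """Full evaluation of median predictions against serum TSB."""

    r_squared: float
    p_value: float
    bias: float
    loa_upper: float
    loa_lower: float
    loa_span: float
    rmse_by_range: dict[str, float]
    rmse_by_group: dict[str, float]
    group_test_p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "bias_mg_dl": self.bias,
            "loa_upper_mg_dl": self.loa_upper,
            "loa_lower_mg_dl": self.loa_lower,
            "loa_span_mg_dl": self.loa_span,
            "rmse_by_range_mg_dl": self.rmse_by_range,
            "rmse_by_group_mg_dl": self.rmse_by_group,
            "group_test_p": self.group_test_p,
            "n": self.n,
        }


def agreement_report(
    pred,
    tsb,
    groups=None,
    range_edges=(0.0, 10.0, 25.0),
    compare_groups: tuple[str, str] | None = None,
) -> AgreementReport:
    """Compute the full agreement panel for a cohort of median predictions."""
    pred = np.asarray(pred, dtype=float)
    tsb = np.asarray(tsb, dtype=float)
    r2, p = r_squared(pred, tsb)
    ba = bland_altman(pred, tsb)
    by_range = rmse_by_range(pred, tsb, range_edges)
    if groups is not None:
        by_group, group_p = rmse_by_group(pred, tsb, groups, compare=compare_groups)
    else:
        by_group, group_p = {}, float("nan")
    return AgreementReport(
        r_squared=r2,
        p_value=p,
        bias=ba.bias,
        loa_upper=ba.loa_upper,
        loa_lower=ba.loa_lower,
        loa_span=ba.loa_span,
        rmse_by_range=by_range,
        rmse_by_group=by_group,
        group_test_p=group_p,
        n=int(pred.size),
    )
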