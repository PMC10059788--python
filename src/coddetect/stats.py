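"""Validity and reproducibility statistics for device-vs-criterion counts.

Device validity against a criterion measure (video-coded counts) is
expressed as percentage mean difference and pooled-SD Cohen's d with a
magnitude label; precision as the coefficient of variation; and
between-device reproducibility as the CV across devices and the
intraclass correlation ICC(2,k) (two-way random effects, average
measures, absolute agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "EffectSize",
    "percent_diff",
    "cohens_d",
    "classify_effect",
    "cv_pct",
    "between_device_cv",
    "icc_2k",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation and size of one group of COD counts."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"group size must be at least 2, got {self.n}")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(mean=float(values.mean()), sd=float(values.std(ddof=1)), n=len(values))


#: |d| cut-points and labels for effect-size magnitude classes.
_EFFECT_CUTS = ((0.2, "trivial"), (0.6, "small"), (1.2, "medium"), (2.0, "long"))


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with a normal-approximation 95% CI and magnitude label."""

    d: float
    ci_low: float
    ci_high: float
    label: str


def percent_diff(device: GroupSummary, reference: GroupSummary) -> float:
    """Percentage mean difference of a device relative to the criterion.

    ``100 * (device.mean - reference.mean) / reference.mean``; full
    precision (round to integer only for table rendering).
    """
    if reference.mean == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (device.mean - reference.mean) / reference.mean


def cohens_d(a: GroupSummary, b: GroupSummary, alpha: float = 0.05) -> EffectSize:
    """Pooled-SD Cohen's d of group ``a`` relative to group ``b``.

    ``d = (mean_a - mean_b) / s_p`` with the (n-1)-weighted pooled SD; for
    equal group sizes the denominator reduces to
    ``sqrt((sd_a^2 + sd_b^2) / 2)``. The CI uses the large-sample normal
    approximation ``SE = sqrt((n_a+n_b)/(n_a*n_b) + d^2/(2(n_a+n_b)))``
    and is informative output rather than a finely calibrated interval.
    """
    na, nb = a.n, b.n
    pooled_var = ((na - 1) * a.sd**2 + (nb - 1) * b.sd**2) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero")
    d = (a.mean - b.mean) / np.sqrt(pooled_var)
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb)))
    z = sps.norm.ppf(1 - alpha / 2)
    return EffectSize(
        d=float(d),
        ci_low=float(d - z * se),
        ci_high=float(d + z * se),
        label=classify_effect(d),
    )


def classify_effect(d: float) -> str:
    """Magnitude label for |d|: trivial/small/medium/long/very long.

    Cut-points 0.2, 0.6, 1.2, 2.0 (everything from 2.0 up is "very long").
    """
    if not np.isfinite(d):
        raise ValueError(f"effect size must be finite, got {d}")
    mag = abs(d)
    for cut, label in _EFFECT_CUTS:
        if mag < cut:
            return label
    return "very long"


def cv_pct(s: GroupSummary) -> float:
    """Coefficient of variation of a group, percent: ``100 * sd / |mean|``."""
    if s.mean == 0:
        raise ValueError("mean must be non-zero for a CV")
    return 100.0 * s.sd / abs(s.mean)


def between_device_cv(device_means) -> float:
    """CV (%) of per-device mean counts: sample SD across devices / mean.

    Quantifies reproducibility between units worn simultaneously. When
    configurations are grouped (by speed, smoothing or threshold), average
    the per-configuration CVs rather than pooling the counts.
    """
    means = np.asarray(device_means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least two devices")
    m = means.mean()
    if m == 0:
        raise ValueError("mean across devices must be non-zero")
    return float(100.0 * means.std(ddof=1) / abs(m))


def icc_2k(matrix, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``matrix`` is subjects x raters with no missing cells. Returns
    ``(icc, ci_low, ci_high)`` with the 95% CI from the McGraw & Wong
    F-based formulas. A matrix with zero total variance is perfect
    agreement by convention: ``(1.0, 1.0, 1.0)``.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("matrix must be at least 2 subjects x 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains missing or non-finite cells")
    n, k = x.shape
    if np.allclose(x, x.flat[0]):
        return 1.0, 1.0, 1.0

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (msc - mse) / n)

    # CI: single-measures ICC(A,1) bounds, then the Spearman-Brown step-up
    if mse <= 0:
        return float(icc), float(icc), float(icc)
    r1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * r1 / (n * (1 - r1))
    b = 1 + k * r1 * (n - 1) / (n * (1 - r1))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_upper = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = sps.f.ppf(1 - alpha / 2, v, n - 1)
    low1 = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    up1 = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )

    def step_up(r: float) -> float:
        return k * r / (1 + (k - 1) * r)

    return float(icc), float(step_up(low1)), float(step_up(up1))
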