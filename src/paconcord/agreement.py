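"""Agreement statistics battery for method comparison.

For a paired sample of weekly estimates (instrument x on accelerometer y):

* Spearman rank correlation with midrank ties and a two-sided p from the
  t-approximation ``t = rho sqrt((n-2)/(1-rho^2))``, with Holm's sequential
  (step-down) Bonferroni adjustment across a family of tests;
* Lin's concordance correlation coefficient (CCC)

  .. math:: \\hat\\rho_c = \\frac{2 s_{xy}}{s_x^2 + s_y^2 + (\\bar x - \\bar y)^2}

  with biased (1/n) moment estimators, its decomposition into precision
  (Pearson r) and accuracy (bias correction factor C_b = rho_c / r), and a
  95% CI built on the atanh (Fisher z) scale using Lin's asymptotic variance;
* Bland-Altman limits of agreement on log(x + offset) transformed values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PairedSample:
    """Complete-case paired vectors (no missing values inside)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-d vectors of equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("paired sample must not contain missing/non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    lcc: float
    lcc_ci_low: float
    lcc_ci_high: float
    pearson_r: float
    pearson_p: float
    bcf: float


@dataclass(frozen=True)
class AgreementResult:
    """One instrument-vs-device cell of the validity battery."""

    n: int
    spearman_rho: float
    spearman_p: float
    holm_significant: Optional[bool]
    pearson_r: float
    lcc: float
    lcc_ci_low: float
    lcc_ci_high: float
    bcf: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 1.96-SD limits of agreement on the log scale."""

    n: int
    mean_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def _require_n(sample: PairedSample, stat: str, n_min: int = 3) -> None:
    if sample.n < n_min:
        raise ValueError(f"{stat} needs n >= {n_min}, got n = {sample.n}")


def spearman(sample: PairedSample) -> tuple[float, float]:
    """Spearman rho with midranks for ties and a two-sided t-approximate p.

    Constant input leaves the coefficient undefined: returns (nan, nan) with
    a warning.
    """
    _require_n(sample, "spearman")
    if np.ptp(sample.x) == 0 or np.ptp(sample.y) == 0:
        warnings.warn("spearman undefined for a constant vector; returning NaN")
        return (math.nan, math.nan)
    res = stats.spearmanr(sample.x, sample.y)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejection flags, in the original order.

    Sort ascending and reject p_(i) while p_(i) <= alpha / (m - i + 1),
    stopping at the first failure.  NaN entries are never rejected and do not
    count toward the family size m.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], alpha=alpha, method="holm")[0]
    return out


def _moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Means and biased (1/n) variances/covariance, the Lin 1989 convention."""
    mx, my = float(np.mean(x)), float(np.mean(y))
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    return mx, my, sx2, sy2, sxy


def lin_ccc(
    sample: PairedSample,
    ci_level: float = 0.95,
    log_transform: bool = False,
    log_offset: float = 1.0,
) -> Optional[ConcordanceResult]:
    """Lin's concordance correlation with precision/accuracy decomposition.

    The CI is constructed on the atanh scale (z = atanh(rho_c),
    z +/- z_{alpha/2} sigma_z, back-transformed) with Lin's asymptotic
    variance for the transformed estimate.  With ``log_transform`` the
    coefficient itself is computed on log(value + log_offset) data, a
    variant sometimes preferred for right-skewed minutes.

    Returns None (with a warning) when either vector has zero variance.
    """
    _require_n(sample, "lin_ccc")
    x, y = sample.x, sample.y
    if log_transform:
        if (x < 0).any() or (y < 0).any():
            raise ValueError("log transform requires non-negative values")
        x, y = np.log(x + log_offset), np.log(y + log_offset)
    mx, my, sx2, sy2, sxy = _moments(x, y)
    if sx2 == 0 or sy2 == 0:
        warnings.warn("lin_ccc undefined for a constant vector; returning None")
        return None
    n = sample.n
    lcc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r, r_p = stats.pearsonr(x, y)
    r, r_p = float(r), float(r_p)
    bcf = lcc / r if r != 0 else math.nan
    if r == 0:
        warnings.warn("bias correction factor undefined when r = 0")

    # Lin's asymptotic variance of z = atanh(rho_c)
    u2 = (mx - my) ** 2 / math.sqrt(sx2 * sy2)
    rc, rc2 = lcc, lcc * lcc
    if r == 0 or abs(lcc) >= 1:
        # degenerate: perfect concordance (sd 0) or no precision; collapse CI
        lo = hi = lcc
    else:
        var_z = (1.0 / (n - 2)) * (
            (1 - r * r) * rc2 / ((1 - rc2) * r * r)
            + 4 * rc ** 3 * (1 - rc) * u2 / (r * (1 - rc2) ** 2)
            - 2 * rc ** 4 * u2 * u2 / (r * r * (1 - rc2) ** 2)
        )
        var_z = max(var_z, 0.0)
        zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
        z = math.atanh(lcc)
        lo = math.tanh(z - zcrit * math.sqrt(var_z))
        hi = math.tanh(z + zcrit * math.sqrt(var_z))
    return ConcordanceResult(n=n, lcc=lcc, lcc_ci_low=lo, lcc_ci_high=hi,
                             pearson_r=r, pearson_p=r_p, bcf=bcf)


def bias_correction_factor(sample: PairedSample) -> float:
    """C_b = 2 / (v + 1/v + u^2) with v = s_x/s_y and u = (x̄-ȳ)/sqrt(s_x s_y).

    Algebraically identical to lcc / r; exposed separately so the two forms
    can be cross-checked.
    """
    _require_n(sample, "bias_correction_factor")
    mx, my, sx2, sy2, sxy = _moments(sample.x, sample.y)
    if sx2 == 0 or sy2 == 0:
        return math.nan
    v = math.sqrt(sx2 / sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    return 2.0 / (v + 1.0 / v + u * u)


def bland_altman_log(
    sample: PairedSample,
    offset: float = 1.0,
    loa_sd_multiplier: float = 1.96,
) -> BlandAltmanResult:
    """Bland-Altman summary of log(value + offset) transformed pairs.

    The offset keeps zero minutes finite on the log scale (several weekly
    estimates, notably accelerometer vigorous minutes, are legitimately 0).
    Differences are x - y; limits of agreement are mean +/- 1.96 x sample SD.
    """
    _require_n(sample, "bland_altman_log")
    if (sample.x < 0).any() or (sample.y < 0).any():
        raise ValueError("bland_altman_log requires non-negative values")
    if offset < 0 or (offset == 0 and ((sample.x == 0).any() or (sample.y == 0).any())):
        raise ValueError("offset must be positive when zeros are present")
    lx, ly = np.log(sample.x + offset), np.log(sample.y + offset)
    diffs = lx - ly
    means = (lx + ly) / 2.0
    mean_diff = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        n=sample.n,
        mean_diff=mean_diff,
        loa_low=mean_diff - loa_sd_multiplier * sd,
        loa_high=mean_diff + loa_sd_multiplier * sd,
        means=means,
        diffs=diffs,
    )
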