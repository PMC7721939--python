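"""Method-comparison statistics for paired dose estimates and dose maps.

Agreement between two dosimetry methods is assessed the way method-
comparison studies do:

* Bland-Altman: per-pair differences x - y, their mean (bias) and
  sample SD, with limits of agreement at bias +/- 2 SD and the
  percentage of points falling beyond the limits.  A parametric 95%
  confidence interval of the bias is also reported, separately labeled,
  since "limits of agreement" and "CI of the bias" are often conflated.
* Lin's concordance correlation coefficient (CCC), which penalizes both
  imprecision and location/scale shift:
      rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)
  with population (1/n) moments.
* Normalized mean square error between two dose maps over a VOI,
      NMSE(%) = 100 * sum((test - ref)^2) / sum(ref^2),
  conventionally with the local-deposition map as the reference.
* Signed voxel difference maps: the positive parts of a - b and b - a,
  for visualizing where each method dominates.

Pearson/Spearman correlations and paired t / Wilcoxon tests are
delegated to scipy.stats rather than re-derived.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .voxel import DoseMap

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "bland_altman",
    "lin_ccc",
    "nmse",
    "dose_difference_map",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired per-patient or per-tumor dose estimates from two methods."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] = ()
    name_x: str = "method_A"
    name_y: str = "method_B"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1D arrays of equal length")
        if x.size < 2:
            raise ValueError("paired comparison needs at least two pairs")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("paired values must be finite")
        if self.labels and len(self.labels) != x.size:
            raise ValueError("labels length does not match data")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary plus correlation/concordance coefficients."""

    bias_Gy: float
    sd_of_differences_Gy: float
    lower_limit_Gy: float
    upper_limit_Gy: float
    bias_ci95_Gy: tuple[float, float]
    percent_beyond_limits: float
    pearson_r: float
    lin_ccc: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias_Gy": self.bias_Gy,
            "sd_of_differences_Gy": self.sd_of_differences_Gy,
            "limits_of_agreement_Gy": [self.lower_limit_Gy, self.upper_limit_Gy],
            "bias_ci95_Gy": list(self.bias_ci95_Gy),
            "percent_beyond_limits": self.percent_beyond_limits,
            "pearson_r": self.pearson_r,
            "lin_ccc": self.lin_ccc,
        }


def bland_altman(pairs: PairedSeries) -> AgreementReport:
    """Bland-Altman agreement of two paired series, limits at +/- 2 SD.

    Differences are x - y.  The limits use exactly 2 (not 1.96) sample
    standard deviations around the bias; the separate 95% CI of the
    bias uses the t distribution.
    """
    d = pairs.x - pairs.y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = bias - 2.0 * sd, bias + 2.0 * sd
    beyond = 100.0 * float(np.count_nonzero((d < lower) | (d > upper))) / pairs.n
    sem = sd / np.sqrt(pairs.n)
    t_crit = float(stats.t.ppf(0.975, pairs.n - 1))
    ci = (bias - t_crit * sem, bias + t_crit * sem)
    if np.all(pairs.x == pairs.x[0]) or np.all(pairs.y == pairs.y[0]):
        r = 1.0 if np.array_equal(pairs.x, pairs.y) else float("nan")
    else:
        r = float(stats.pearsonr(pairs.x, pairs.y).statistic)
    return AgreementReport(
        bias_Gy=bias,
        sd_of_differences_Gy=sd,
        lower_limit_Gy=lower,
        upper_limit_Gy=upper,
        bias_ci95_Gy=ci,
        percent_beyond_limits=beyond,
        pearson_r=r,
        lin_ccc=lin_ccc(pairs),
        n=pairs.n,
    )


def lin_ccc(pairs: PairedSeries) -> float:
    """Lin's concordance correlation coefficient with 1/n moments."""
    x, y = pairs.x, pairs.y
    sx2 = float(x.var())  # population variance
    sy2 = float(y.var())
    dmean2 = float((x.mean() - y.mean()) ** 2)
    denom = sx2 + sy2 + dmean2
    if denom == 0.0:
        # both series constant with equal means: perfect concordance
        return 1.0
    sxy = float(((x - x.mean()) * (y - y.mean())).mean())
    return 2.0 * sxy / denom


def nmse(reference: DoseMap, test: DoseMap, voi: np.ndarray) -> float:
    """Normalized mean square error between dose maps over a VOI, percent.

    The reference is conventionally the local-deposition (LDM) map.
    """
    if reference.geometry.shape != test.geometry.shape:
        raise ValueError("dose maps have different geometries")
    voi = np.asarray(voi, dtype=bool)
    if voi.shape != reference.geometry.shape:
        raise ValueError("VOI mask shape does not match dose maps")
    ref = reference.values[voi]
    tst = test.values[voi]
    denom = float((ref**2).sum())
    if denom == 0.0:
        raise ValueError("reference dose is zero over the VOI; NMSE undefined")
    return 100.0 * float(((tst - ref) ** 2).sum()) / denom


def dose_difference_map(a: DoseMap, b: DoseMap) -> tuple[DoseMap, DoseMap]:
    """Signed voxel differences as two non-negative maps.

    Returns (positive part of a - b, positive part of b - a); their sum
    is |a - b| elementwise.
    """
    if a.geometry.shape != b.geometry.shape:
        raise ValueError("dose maps have different geometries")
    diff = a.values - b.values
    return (
        DoseMap(geometry=a.geometry, values=np.maximum(diff, 0.0)),
        DoseMap(geometry=b.geometry, values=np.maximum(-diff, 0.0)),
    )


def comparison_table_csv(path, rows: list[tuple[str, AgreementReport]]) -> None:
    """Write pairwise comparisons as CSV: one row per method pair."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "pair",
                "n",
                "bias_Gy",
                "sd_Gy",
                "lower_limit_Gy",
                "upper_limit_Gy",
                "percent_beyond_limits",
                "pearson_r",
                "lin_ccc",
            ]
        )
        for name, rep in rows:
            writer.writerow(
                [
                    name,
                    rep.n,
                    rep.bias_Gy,
                    rep.sd_of_differences_Gy,
                    rep.lower_limit_Gy,
                    rep.upper_limit_Gy,
                    rep.percent_beyond_limits,
                    rep.pearson_r,
                    rep.lin_ccc,
                ]
            )
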