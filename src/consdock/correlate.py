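"""Agreement between score/consensus vectors and experimental potency.

Rank agreement (Spearman, i.e. Pearson on average-tie ranks) and linear
agreement (Pearson, OLS with a 95% confidence band for the conditional
mean) between any per-ligand quantity — a raw score, an ECR value, an
aggregated rank — and measured pIC50.  Pairing is by strict key
intersection; ligands lacking either value are dropped and recorded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = ["CorrelationReport", "rank_correlation", "ols_summary"]


@dataclass
class CorrelationReport:
    n: int
    spearman_rho: float
    pearson_r: float
    ols_slope: float
    ols_intercept: float
    grid: np.ndarray | None = None
    fit: np.ndarray | None = None
    ci95_lower: np.ndarray | None = None
    ci95_upper: np.ndarray | None = None
    dropped_ligands: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "n": self.n,
            "spearman_rho": self.spearman_rho,
            "pearson_r": self.pearson_r,
            "ols_slope": self.ols_slope,
            "ols_intercept": self.ols_intercept,
            "dropped_ligands": self.dropped_ligands,
        }
        return json.dumps(d, indent=2)


def _paired(
    x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    common = sorted(k for k in x if k in y
                    and not math.isnan(float(x[k])) and not math.isnan(float(y[k])))
    dropped = sorted((set(x) | set(y)) - set(common))
    if len(common) < 3:
        raise ValueError(f"need >= 3 common ligands, got {len(common)}")
    xv = np.array([float(x[k]) for k in common])
    yv = np.array([float(y[k]) for k in common])
    return xv, yv, dropped


def rank_correlation(
    x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[float, float]:
    """Spearman rho and Pearson r over the key intersection of two
    ligand -> value mappings.  Zero variance in either vector is an error
    (the correlation would be undefined)."""
    xv, yv, _ = _paired(x, y)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in one of the vectors")
    rho = float(stats.spearmanr(xv, yv).statistic)
    r = float(stats.pearsonr(xv, yv).statistic)
    return rho, r


def ols_summary(
    x: Mapping[str, float], y: Mapping[str, float], grid_points: int = 100
) -> CorrelationReport:
    """Least-squares fit of y on x with a 95% confidence band for the mean
    response (t-distribution, n-2 df) evaluated on a uniform x grid."""
    xv, yv, dropped = _paired(x, y)
    if np.ptp(xv) == 0:
        raise ValueError("zero variance in x")
    X = sm.add_constant(xv)
    fit = sm.OLS(yv, X).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    grid = np.linspace(xv.min(), xv.max(), grid_points)
    pred = fit.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(alpha=0.05)
    if np.ptp(yv) == 0:
        rho, r = (0.0, 0.0)
    else:
        rho = float(stats.spearmanr(xv, yv).statistic)
        r = float(stats.pearsonr(xv, yv).statistic)
    return CorrelationReport(
        n=len(xv),
        spearman_rho=rho,
        pearson_r=r,
        ols_slope=slope,
        ols_intercept=intercept,
        grid=grid,
        fit=pred.predicted_mean,
        ci95_lower=band[:, 0],
        ci95_upper=band[:, 1],
        dropped_ligands=dropped,
    )
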