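"""Interaction sampling completeness (Chao2) and effort correlation.

Distinct (bee, plant) links are treated as "species" and sampling days as
incidence units.  The bias-corrected Chao2 estimator of true link richness

    S_est = S_obs + ((m - 1) / m) * Q1 * (Q1 - 1) / (2 * (Q2 + 1))

uses the counts of links seen on exactly one (Q1) and exactly two (Q2)
days out of m; completeness is S_obs / S_est.  The classic form
Q1^2 / (2 Q2) is available when Q2 > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .network_builder import DailyNetwork

__all__ = [
    "CompletenessResult",
    "chao2_completeness",
    "effort_completeness_correlation",
    "completeness_table",
]


@dataclass(frozen=True)
class CompletenessResult:
    year: int
    S_obs: int
    Q1: int
    Q2: int
    m: int
    S_est: float
    completeness: float


def chao2_completeness(
    day_networks: list[DailyNetwork], bias_corrected: bool = True
) -> CompletenessResult:
    """Chao2 link-richness estimate for one year of daily networks."""
    m = len(day_networks)
    if m < 2:
        raise ValueError("Chao2 needs at least 2 sampling days")
    incidence: dict[tuple[str, str], int] = {}
    for net in day_networks:
        for link in net.links():
            incidence[link] = incidence.get(link, 0) + 1
    S_obs = len(incidence)
    Q1 = sum(1 for v in incidence.values() if v == 1)
    Q2 = sum(1 for v in incidence.values() if v == 2)
    if bias_corrected:
        S_est = S_obs + (m - 1) / m * Q1 * (Q1 - 1) / (2 * (Q2 + 1))
    else:
        if Q2 == 0:
            raise ZeroDivisionError("classic Chao2 undefined when Q2 == 0")
        S_est = S_obs + Q1**2 / (2 * Q2)
    return CompletenessResult(
        year=day_networks[0].year,
        S_obs=S_obs,
        Q1=Q1,
        Q2=Q2,
        m=m,
        S_est=float(S_est),
        completeness=float(S_obs / S_est),
    )


def effort_completeness_correlation(
    results: list[CompletenessResult], efforts: dict[int, int]
) -> tuple[float, float]:
    """Spearman correlation of per-year sampling effort vs completeness.

    ``efforts`` maps year -> number of transects walked that year.
    Returns (rho, two-sided p).
    """
    if len(results) < 3:
        raise ValueError("need at least 3 years")
    comp = [r.completeness for r in sorted(results, key=lambda r: r.year)]
    eff = [efforts[r.year] for r in sorted(results, key=lambda r: r.year)]
    if len(set(comp)) == 1 or len(set(eff)) == 1:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = stats.spearmanr(eff, comp)
    return float(rho), float(p)


def completeness_table(results: list[CompletenessResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in sorted(results, key=lambda r: r.year)])
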