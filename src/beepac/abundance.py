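"""Effective relative abundances from interaction frequencies (mass action).

Under the mass-action principle the visitation frequency between bee i and
plant j factorizes as F_ij = x_i * x_j * c_ij, the product of the partners'
relative abundances and a pairwise preference term.  Raw capture counts
cannot serve as the abundance covariate of the competition models because
abundance *is* the row total of the same interaction matrix; instead we
invert the mass-action factorization.

Estimator: on the observed (nonzero) links, least-squares fit of the
additive decomposition

    log F_ij = mu + r_i + s_j + eps_ij,   sum_i r_i = sum_j s_j = 0

then x_i ~ exp(r_i) and x_j ~ exp(s_j), each side normalized to sum 1, and
c_ij = F_ij / (x_i x_j) on observed links (the free overall scale s is
absorbed into c).  Zeros are treated as unobserved links, not log(0).  A
disconnected bipartite graph is fit per connected component, with a
warning, because relative scaling across components is not identified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .network_builder import DailyNetwork

__all__ = ["AbundanceEstimate", "estimate_abundances", "abundance_table"]


@dataclass
class AbundanceEstimate:
    """Per-day relative abundances (sum 1 per side) and link preferences."""

    date: Date
    bee_abundances: dict[str, float]
    plant_abundances: dict[str, float]
    preferences: pd.DataFrame = field(repr=False)  # bee, plant, c


def _fit_component(F: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares for log F = mu + r_i + s_j over observed links.

    ``rows``/``cols`` index the component's bees/plants in F.  Returns the
    (centered) r and s effect vectors.
    """
    sub = F[np.ix_(rows, cols)]
    ii, jj = np.nonzero(sub)
    y = np.log(sub[ii, jj])
    nb, npl = len(rows), len(cols)
    # design: intercept + bee dummies + plant dummies (full-rank via drop-first,
    # then re-center the reconstructed effects to sum-to-zero)
    X = np.zeros((len(y), 1 + (nb - 1) + (npl - 1)))
    X[:, 0] = 1.0
    for k, i in enumerate(ii):
        if i > 0:
            X[k, i] = 1.0  # columns 1..nb-1 are bee dummies for i>=1
    for k, j in enumerate(jj):
        if j > 0:
            X[k, nb - 1 + j] = 1.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = np.concatenate([[0.0], beta[1:nb]])
    s = np.concatenate([[0.0], beta[nb : nb + npl - 1]])
    return r - r.mean(), s - s.mean()


def estimate_abundances(network: DailyNetwork) -> AbundanceEstimate:
    """Mass-action abundance decomposition of one daily network."""
    F = network.counts.astype(float)
    nb, npl = F.shape
    adj = coo_matrix(
        (np.ones(np.count_nonzero(F)), np.nonzero(F)), shape=(nb, npl)
    )
    # bipartite connectivity on the (bees + plants) union graph
    from scipy.sparse import bmat

    big = bmat([[None, adj], [adj.T, None]])
    n_comp, labels = connected_components(big, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"{network.date}: bipartite graph has {n_comp} connected components; "
            "abundance scaling across components is arbitrary",
            stacklevel=2,
        )
    r_full = np.zeros(nb)
    s_full = np.zeros(npl)
    for comp in range(n_comp):
        rows = np.nonzero(labels[:nb] == comp)[0]
        cols = np.nonzero(labels[nb:] == comp)[0]
        if len(rows) == 0 or len(cols) == 0:
            continue
        if len(rows) == 1 and len(cols) == 1:
            continue  # single link: effects are zero by centering
        r, s = _fit_component(F, rows, cols)
        r_full[rows] = r
        s_full[cols] = s
    x_bee = np.exp(r_full)
    x_bee /= x_bee.sum()
    x_plant = np.exp(s_full)
    x_plant /= x_plant.sum()
    ii, jj = np.nonzero(F)
    prefs = pd.DataFrame(
        {
            "bee": [network.bee_labels[i] for i in ii],
            "plant": [network.plant_labels[j] for j in jj],
            "c": F[ii, jj] / (x_bee[ii] * x_plant[jj]),
        }
    )
    return AbundanceEstimate(
        date=network.date,
        bee_abundances=dict(zip(network.bee_labels, x_bee)),
        plant_abundances=dict(zip(network.plant_labels, x_plant)),
        preferences=prefs,
    )


def abundance_table(
    networks: list[DailyNetwork], estimates: list[AbundanceEstimate]
) -> pd.DataFrame:
    """Join per-day bee abundance estimates: ``date,species,abundance_est``.

    A species absent on a date has no row (absence, not zero).  Raises if
    any network date lacks an estimate.
    """
    by_date = {e.date: e for e in estimates}
    rows = []
    for net in networks:
        if net.date not in by_date:
            raise KeyError(f"no abundance estimate for network date {net.date}")
        est = by_date[net.date]
        for sp in net.bee_labels:
            rows.append(
                {"date": net.date, "species": sp, "abundance_est": est.bee_abundances[sp]}
            )
    return pd.DataFrame(rows)
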