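"""Mueller's potential apparent competition (PAC) index.

For a daily bee x plant visitation matrix ``a`` the pairwise index is

    d_ij = sum_k (a_ik / sum_l a_il) * (a_jk / sum_m a_mk)

the potential influence of acting bee species j on target bee species i
through the plants they share: the fraction of i's visits that go to each
plant k, weighted by j's share of all bee visits that plant k receives.
Rows (targets) sum to 1, so d is a row-stochastic overlap/dominance matrix.
The diagonal d_ii measures how much a species monopolizes its own plants
(potential intraspecific competition); column means excluding the diagonal
give each acting species' average effect on the rest of the community
(potential interspecific competition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

from .network_builder import DailyNetwork

__all__ = [
    "PACMatrix",
    "pac_matrix",
    "interspecific_index",
    "intraspecific_index",
    "competition_indices",
]


@dataclass
class PACMatrix:
    """Square PAC matrix for one day; d[i, j] = effect of j on i."""

    date: Date
    bee_labels: list[str]
    d: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.bee_labels, columns=self.bee_labels)


def pac_matrix(network: DailyNetwork) -> PACMatrix:
    """Compute the PAC matrix of a daily network.

    Requires a pruned network (no zero rows/columns); double precision,
    no smoothing.
    """
    a = network.counts.astype(float)
    if a.size == 0:
        raise ValueError("empty network")
    row = a.sum(axis=1)
    col = a.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("network has a zero row or column total")
    # d = P Q^T with P row-normalized and Q column-normalized
    d = (a / row[:, None]) @ (a / col[None, :]).T
    return PACMatrix(date=network.date, bee_labels=list(network.bee_labels), d=d)


def interspecific_index(pac: PACMatrix) -> dict[str, float]:
    """Column means of d excluding the diagonal, per acting species.

    The mean effect the acting species exerts on every other species in
    the network; empty for a single-species network.
    """
    n = len(pac.bee_labels)
    if n < 2:
        return {}
    d = pac.d
    col_sums = d.sum(axis=0) - np.diag(d)
    return {sp: float(col_sums[j] / (n - 1)) for j, sp in enumerate(pac.bee_labels)}


def intraspecific_index(pac: PACMatrix) -> dict[str, float]:
    """Diagonal of d: each species' dominance of its own plants."""
    return {sp: float(pac.d[i, i]) for i, sp in enumerate(pac.bee_labels)}


def competition_indices(networks: list[DailyNetwork]) -> pd.DataFrame:
    """Long table ``date,species,inter_acting,intra`` over daily networks.

    ``inter_acting`` is NaN for species in single-species networks (the
    interspecific index is undefined there).
    """
    rows = []
    for net in networks:
        pac = pac_matrix(net)
        inter = interspecific_index(pac)
        intra = intraspecific_index(pac)
        for sp in pac.bee_labels:
            rows.append(
                {
                    "date": net.date,
                    "year": net.year,
                    "species": sp,
                    "inter_acting": inter.get(sp, np.nan),
                    "intra": intra[sp],
                }
            )
    return pd.DataFrame(rows)
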