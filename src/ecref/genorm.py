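"""geNorm expression-stability ranking, implemented from first principles.

For candidate reference genes j and k the pairwise variation V_jk is the
standard deviation (n-1 denominator) across samples of the log2
expression ratio of the two genes.  Because log2 expression is ``-Cq``,
the log-ratio equals the per-sample Cq difference ``Cq_k - Cq_j`` and all
computation is done directly on Cq values — no exponentiation round
trips.  A gene's stability measure M is the arithmetic mean of its
pairwise variations against every other candidate; lower M means more
stable.

Ranking proceeds by stepwise elimination: the gene with the highest M is
removed and M recomputed on the remainder, until two genes remain.  The
final pair cannot be separated (each is the other's only partner, so
their M values are identical) and shares the top rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq import CollapsedCqMatrix
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeNormResult:
    """Output of the stepwise geNorm ranking.

    ``ranking`` is most-stable first, with the surviving pair (tied at
    rank 1) listed in input order; ``elimination_order`` is
    first-removed first; ``M_at_elimination`` holds each gene's M in the
    round it was removed (for the final pair, their shared two-gene M).
    """

    genes: list[str]
    pairwise_V: pd.DataFrame
    full_set_M: pd.Series
    elimination_order: list[str]
    ranking: list[str]
    M_at_elimination: pd.Series


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, CollapsedCqMatrix):
        return matrix.values
    return pd.DataFrame(matrix)


def pairwise_variation(matrix, j: str, k: str) -> float:
    """V_jk: SD across samples of the log2 ratio of genes j and k."""
    data = _as_frame(matrix)
    if j == k:
        raise DataError("pairwise variation requires two distinct genes")
    if data.shape[1] < 2:
        raise DataError("pairwise variation requires >= 2 samples")
    diff = data.loc[k].to_numpy(dtype=float) - data.loc[j].to_numpy(dtype=float)
    return float(np.std(diff, ddof=1))


def pairwise_variation_matrix(matrix, genes: list[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of V_jk over all gene pairs (V_jj = 0)."""
    data = _as_frame(matrix)
    if genes is not None:
        data = data.loc[genes]
    if data.shape[1] < 2:
        raise DataError("pairwise variation requires >= 2 samples")
    arr = data.to_numpy(dtype=float)
    g = arr.shape[0]
    V = np.zeros((g, g))
    for a in range(g):
        diffs = arr - arr[a]  # each row: Cq_k - Cq_j across samples
        V[a] = np.std(diffs, axis=1, ddof=1)
    V = (V + V.T) / 2.0  # symmetric up to float noise; enforce exactly
    np.fill_diagonal(V, 0.0)
    return pd.DataFrame(V, index=data.index, columns=data.index)


def stability_M(matrix, gene_subset: list[str] | None = None) -> pd.Series:
    """M_j = mean of V_jk over all other genes k in the subset."""
    data = _as_frame(matrix)
    genes = list(gene_subset) if gene_subset is not None else list(data.index)
    if len(genes) < 2:
        raise DataError("stability M requires >= 2 genes")
    V = pairwise_variation_matrix(data, genes)
    g = len(genes)
    M = (V.sum(axis=1)) / (g - 1)
    return M


def rank_stepwise(matrix, genes: list[str] | None = None) -> GeNormResult:
    """Full geNorm ranking by stepwise elimination of the least stable gene.

    Requires >= 3 genes.  Ties in the maximal M are broken by input
    order (first occurrence removed) and logged.
    """
    data = _as_frame(matrix)
    if genes is not None:
        data = data.loc[genes]
    gene_list = [str(g) for g in data.index]
    if len(gene_list) < 3:
        raise DataError("stepwise geNorm ranking requires >= 3 genes")
    V_full = pairwise_variation_matrix(data)
    M_full = stability_M(data)

    remaining = list(gene_list)
    elimination: list[str] = []
    M_at_elim: dict[str, float] = {}
    while len(remaining) > 2:
        M = stability_M(data, remaining)
        worst_val = M.max()
        ties = [g for g in remaining if M[g] == worst_val]
        if len(ties) > 1:
            log.info("geNorm tie at M=%.6g between %s; removing %s (input order)",
                     worst_val, ties, ties[0])
        worst = ties[0]
        M_at_elim[worst] = float(M[worst])
        elimination.append(worst)
        remaining.remove(worst)
    M_pair = stability_M(data, remaining)
    for g in remaining:
        M_at_elim[g] = float(M_pair[g])
    ranking = list(remaining) + list(reversed(elimination))
    return GeNormResult(
        genes=gene_list,
        pairwise_V=V_full,
        full_set_M=M_full,
        elimination_order=elimination,
        ranking=ranking,
        M_at_elimination=pd.Series(M_at_elim).loc[ranking],
    )


def result_to_frame(res: GeNormResult) -> pd.DataFrame:
    """TSV-ready table: rank, gene, M_full_set, M_at_elimination, round."""
    n = len(res.ranking)
    n_rounds = n - 2
    rounds = {g: i + 1 for i, g in enumerate(res.elimination_order)}
    rows = []
    for i, g in enumerate(res.ranking):
        rows.append({
            "rank": 1 if i < 2 else i + 1,  # final pair shares rank 1
            "gene": g,
            "M_full_set": float(res.full_set_M[g]),
            "M_at_elimination": float(res.M_at_elimination[g]),
            "round_eliminated": rounds.get(g, 0),  # 0 = never eliminated
        })
    return pd.DataFrame(rows)
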