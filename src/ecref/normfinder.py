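"""Model-based reference-gene stability (NormFinder-style), from scratch.

The model: log2 expression of gene i in sample j of group g decomposes
additively as

    y_igj = alpha_ig + beta_gj + eps_igj,   Var(eps_igj) = sigma2_ig

where ``beta_gj`` is a sample-specific loading common to all genes (the
quantity normalization is meant to remove) and ``alpha_ig`` carries the
gene's group-specific level.  A good reference gene has both a small
intra-group variance sigma2_ig and a small inter-group difference d_ig
(its alpha deviates little between groups).

Estimation proceeds by double-centering within each group to strip gene
and sample main effects, unbiased moment estimation of sigma2_ig, a
moment estimate gamma2 of the variance of the group differences across
genes, and shrinkage of each raw difference d_ig toward zero by the
factor gamma2 / (gamma2 + sigma2_ig/n_g).  The stability value of gene i
averages, over groups, the absolute shrunk difference plus the standard
error of that shrunk difference:

    rho_i = (1/G) sum_g [ |d~_ig| + sqrt(v_ig) ],
    v_ig  = (sigma2_ig/n_g) * gamma2 / (gamma2 + sigma2_ig/n_g)

Lower rho means more stable.  A two-gene normalizer (the log of the
geometric mean of the pair's expression) has differences and variances
that average, so the pair stability is

    (1/G) sum_g [ |(d~_ig + d~_i'g)/2| + sqrt((v_ig + v_i'g)/4) ]

and the best pair is searched over the top-m single genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq import CollapsedCqMatrix, to_log2_expression
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormFinderResult:
    genes: list[str]
    groups: list[str]
    n_per_group: dict[str, int]
    intra_group_var: pd.DataFrame   # gene x group, sigma2 estimates
    group_diff: pd.DataFrame        # gene x group, raw d_ig
    shrunk_diff: pd.DataFrame       # gene x group, shrunk d~_ig
    diff_variance: float            # gamma2
    stability: pd.Series            # rho per gene
    ranking: list[str]              # ascending rho
    best_gene: str
    best_pair: tuple[str, str] | None
    pair_stability: float | None


def _check_layout(y: pd.DataFrame, groups: pd.Series) -> tuple[list[str], dict[str, list]]:
    if list(groups.index) != list(y.columns):
        raise DataError("group vector not aligned to sample columns")
    k = y.shape[0]
    if k < 3:
        raise DataError("intra-group variance not identifiable with fewer than 3 genes")
    labels = list(dict.fromkeys(groups))  # preserve first-appearance order
    if len(labels) < 2:
        raise DataError("need >= 2 groups")
    members = {g: list(groups.index[groups == g]) for g in labels}
    for g, ids in members.items():
        if len(ids) < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
    return labels, members


def within_group_residuals(y: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Double-centred residuals per group.

    r_igj = y_igj - rowmean_ig - colmean_gj + grandmean_g; gene main
    effects and sample loadings are both absorbed, leaving pure
    measurement/biological noise under the additive model.
    """
    labels, members = _check_layout(y, groups)
    out = {}
    for g in labels:
        block = y[members[g]].to_numpy(dtype=float)
        r = (block - block.mean(axis=1, keepdims=True)
             - block.mean(axis=0, keepdims=True) + block.mean())
        out[g] = pd.DataFrame(r, index=y.index, columns=members[g])
    return out


def intra_group_variance(residuals: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Unbiased moment estimates sigma2_ig from double-centred residuals.

    With k genes and n_g samples, u_ig = sum_j r_igj^2 / (n_g - 1)
    satisfies E[u_ig] = (1 - 2/k) sigma2_ig + S_g / k^2 with
    S_g = sum_i sigma2_ig, so S_g is estimated by
    (k/(k-1)) sum_i u_ig and sigma2_ig by
    (u_ig - S_g_hat/k^2) * k/(k-2), truncated at 0 (logged; relevant at
    small n_g).
    """
    out = {}
    for g, r in residuals.items():
        k, n_g = r.shape
        if k < 3:
            raise DataError("intra-group variance not identifiable with fewer than 3 genes")
        u = (r.to_numpy(dtype=float) ** 2).sum(axis=1) / (n_g - 1)
        S_hat = (k / (k - 1)) * u.sum()
        sigma2 = (u - S_hat / k**2) * (k / (k - 2))
        n_neg = int((sigma2 < 0).sum())
        if n_neg:
            log.info("intra_group_variance: truncated %d negative estimate(s) in group %s",
                     n_neg, g)
        out[g] = np.maximum(sigma2, 0.0)
    frame = pd.DataFrame(out)
    frame.index = next(iter(residuals.values())).index
    return frame


def group_differences(y: pd.DataFrame, groups: pd.Series,
                      sigma2: pd.DataFrame) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Raw and shrunk inter-group differences plus their variance gamma2.

    d_ig is the gene's group-mean deviation, centred over genes within
    each group and over groups within each gene (equal group weights), so
    rows and columns of d both sum to zero.  gamma2 is a moment estimate
    of Var(d) across genes, max(0, mean square of d on (k-1)(G-1) df
    minus the average sampling variance sigma2_ig/n_g); each d_ig is
    shrunk by gamma2 / (gamma2 + sigma2_ig/n_g) (0 when gamma2 = 0).
    """
    labels, members = _check_layout(y, groups)
    k = y.shape[0]
    G = len(labels)
    n_g = {g: len(members[g]) for g in labels}
    a = pd.DataFrame({g: y[members[g]].mean(axis=1) - y[members[g]].to_numpy().mean()
                      for g in labels})
    d = a.sub(a.mean(axis=1), axis=0)
    samp_var = pd.DataFrame({g: sigma2[g] / n_g[g] for g in labels})
    gamma2 = (d.to_numpy() ** 2).sum() / ((k - 1) * (G - 1)) - samp_var.to_numpy().mean()
    gamma2 = max(0.0, float(gamma2))
    if gamma2 == 0.0:
        shrunk = d * 0.0
    else:
        shrunk = d * (gamma2 / (gamma2 + samp_var))
    return d, gamma2, shrunk


def stability_values(shrunk: pd.DataFrame, sigma2: pd.DataFrame, gamma2: float,
                     n_g: dict[str, int]) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene stability rho and the shrunk-difference variance terms v_ig."""
    samp_var = pd.DataFrame({g: sigma2[g] / n for g, n in n_g.items()})
    if gamma2 == 0.0:
        v = samp_var * 0.0
    else:
        v = samp_var * (gamma2 / (gamma2 + samp_var))
    rho = (shrunk.abs() + np.sqrt(v)).mean(axis=1)
    return rho, v


def shrunk_variance(res: "NormFinderResult") -> pd.DataFrame:
    """Recover the per-gene per-group variance terms v_ig from a result."""
    samp_var = pd.DataFrame({g: res.intra_group_var[g] / n
                             for g, n in res.n_per_group.items()})
    if res.diff_variance == 0.0:
        return samp_var * 0.0
    return samp_var * (res.diff_variance / (res.diff_variance + samp_var))


def pair_stability(shrunk: pd.DataFrame, v: pd.DataFrame, i: str, j: str) -> float:
    """Stability of the two-gene normalizer averaging genes i and j."""
    if i == j:
        raise DataError("a reference pair requires two distinct genes")
    d_pair = (shrunk.loc[i] + shrunk.loc[j]) / 2.0
    v_pair = (v.loc[i] + v.loc[j]) / 4.0
    return float((d_pair.abs() + np.sqrt(v_pair)).mean())


def best_pair(shrunk: pd.DataFrame, v: pd.DataFrame, ranking: list[str],
              top_m: int | None = None) -> tuple[tuple[str, str], float]:
    """Minimum-stability pair among the top-m ranked single genes."""
    pool = ranking if top_m is None else ranking[:max(2, top_m)]
    if len(pool) < 2:
        raise DataError("pair search requires >= 2 candidate genes")
    best, best_val = None, np.inf
    for i, j in itertools.combinations(pool, 2):
        val = pair_stability(shrunk, v, i, j)
        if val < best_val:
            best, best_val = (i, j), val
    return best, best_val


def run_normfinder(matrix, groups: pd.Series | None = None,
                   top_m: int | None = None) -> NormFinderResult:
    """Full stability analysis of a card's candidate genes.

    ``matrix`` is a :class:`CollapsedCqMatrix` (Cq values; converted to
    log2 expression internally) or a genes x samples log2-expression
    DataFrame with an explicit ``groups`` vector.  The best pair is
    reported only when its stability does not exceed the best single
    gene's, mirroring the rule that a pair is preferred only when it is
    at least as stable.
    """
    if isinstance(matrix, CollapsedCqMatrix):
        y = to_log2_expression(matrix)
        groups = matrix.groups
    else:
        y = pd.DataFrame(matrix)
        if groups is None:
            raise DataError("groups vector required for raw input")
    labels, members = _check_layout(y, groups)
    n_g = {g: len(members[g]) for g in labels}
    resid = within_group_residuals(y, groups)
    sigma2 = intra_group_variance(resid)
    d, gamma2, shrunk = group_differences(y, groups, sigma2)
    rho, v = stability_values(shrunk, sigma2, gamma2, n_g)
    ranking = list(rho.sort_values(kind="stable").index)
    best = ranking[0]
    pair, pair_val = (None, None)
    if len(ranking) >= 2:
        cand_pair, cand_val = best_pair(shrunk, v, ranking, top_m)
        if cand_val <= float(rho[best]):
            pair, pair_val = cand_pair, cand_val
        else:
            log.info("best pair %s (%.4g) less stable than best single %s (%.4g); "
                     "pair not reported", cand_pair, cand_val, best, rho[best])
    return NormFinderResult(
        genes=[str(g) for g in y.index],
        groups=labels,
        n_per_group=n_g,
        intra_group_var=sigma2,
        group_diff=d,
        shrunk_diff=shrunk,
        diff_variance=gamma2,
        stability=rho,
        ranking=ranking,
        best_gene=best,
        best_pair=pair,
        pair_stability=pair_val,
    )


def result_to_frame(res: NormFinderResult) -> pd.DataFrame:
    """TSV-ready ranking table with per-group variance components."""
    rows = []
    for rank, g in enumerate(res.ranking, start=1):
        row = {"rank": rank, "gene": g, "stability": float(res.stability[g])}
        for grp in res.groups:
            row[f"intra_var_{grp}"] = float(res.intra_group_var.loc[g, grp])
            row[f"shrunk_diff_{grp}"] = float(res.shrunk_diff.loc[g, grp])
        rows.append(row)
    return pd.DataFrame(rows)
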