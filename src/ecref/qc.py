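"""Technical-replicate quality control for TLDA cards.

Two questions are asked of every control assay replicated on the cards:

1. How tight are replicate wells within a card (per-sample SD and range,
   averaged over samples)?
2. Do replicate wells differ systematically between cards (one-way
   fixed-effects ANOVA across replicate instances)?

The ANOVA treats each physical well position — a (card, well) pair — as a
factor level and the per-sample Cq values of that well as the level's
observations (``factor_mode="replicate_instance"``).  With
``factor_mode="card"`` wells are pooled within card, which for two cards
is equivalent to a pooled two-sample t-test (F = t^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cq import CqTable
from .errors import DataError

log = logging.getLogger(__name__)

FACTOR_MODES = ("replicate_instance", "card")


@dataclass(frozen=True)
class ReplicateQcResult:
    """One-way ANOVA of a gene's replicate wells across cards."""

    gene: str
    factor_mode: str
    n_levels: int
    anova_F: float
    anova_df: tuple[int, int]
    anova_p: float


def intra_card_stats(table: CqTable) -> pd.DataFrame:
    """Per-gene per-card replicate spread.

    For every (gene, card) with >= 2 replicate wells, computes the SD
    (n-1 denominator) and range of the replicate Cq values within each
    sample, then averages these across samples.  Genes with a single well
    on a card are skipped with a warning.

    Returns a DataFrame with columns ``assay_id, card, n_wells,
    mean_intra_sd, mean_intra_range``.
    """
    rows = []
    for (gene, card), sub in table.wells.groupby(["assay_id", "card"], sort=True):
        n_wells = sub["well"].nunique()
        if n_wells < 2:
            log.debug("intra_card_stats: %s on card %s has <2 replicates, skipped", gene, card)
            continue
        per_sample = sub.groupby("sample_id")["cq"]
        sd = per_sample.std(ddof=1)
        rng = per_sample.max() - per_sample.min()
        rows.append({
            "assay_id": gene,
            "card": card,
            "n_wells": n_wells,
            "mean_intra_sd": float(sd.mean()),
            "mean_intra_range": float(rng.mean()),
        })
    return pd.DataFrame(rows, columns=["assay_id", "card", "n_wells",
                                       "mean_intra_sd", "mean_intra_range"])


def _anova_levels(table: CqTable, gene: str, factor_mode: str) -> list[np.ndarray]:
    sub = table.wells[table.wells["assay_id"] == gene]
    return _levels_from_frame(sub, gene, factor_mode)


def _levels_from_frame(sub: pd.DataFrame, gene: str, factor_mode: str) -> list[np.ndarray]:
    if sub.empty:
        raise DataError(f"gene {gene!r} not present")
    if sub["card"].nunique() < 2:
        raise DataError(f"gene {gene!r}: no inter-card contrast (wells on a single card)")
    if sub["sample_id"].nunique() < 2:
        raise DataError(f"gene {gene!r}: fewer than 2 samples")
    if factor_mode == "replicate_instance":
        keys = ["card", "well"]
    elif factor_mode == "card":
        keys = ["card"]
    else:
        raise DataError(f"unknown factor_mode {factor_mode!r}")
    levels = [grp.sort_values("sample_id")["cq"].to_numpy(dtype=float)
              for _, grp in sub.groupby(keys, sort=True)]
    if len(levels) < 2:
        raise DataError(f"gene {gene!r}: no inter-card contrast")
    return levels


def oneway_anova(levels: list[np.ndarray]) -> tuple[float, tuple[int, int], float]:
    """Classical one-way fixed-effects ANOVA (pooled within-level variance).

    Degenerate case: if every observation is identical, F = 0 and p = 1
    (no evidence of any level effect).
    """
    obs = np.concatenate(levels)
    if np.ptp(obs) == 0:
        df = (len(levels) - 1, obs.size - len(levels))
        return 0.0, df, 1.0
    F, p = stats.f_oneway(*levels)
    df = (len(levels) - 1, obs.size - len(levels))
    if np.isnan(F):  # zero within-level variance but distinct level means
        return float("inf"), df, 0.0
    return float(F), df, float(p)


def inter_card_anova(table: CqTable, gene: str,
                     factor_mode: str = "replicate_instance") -> ReplicateQcResult:
    """Test inter-card variation of a gene's technical replicates.

    One-way ANOVA where the observations are the gene's Cq values across
    samples and the factor is either the replicate instance (each well on
    each card a level; default) or the card.
    """
    levels = _anova_levels(table, gene, factor_mode)
    F, df, p = oneway_anova(levels)
    return ReplicateQcResult(gene=gene, factor_mode=factor_mode,
                             n_levels=len(levels), anova_F=F, anova_df=df, anova_p=p)


def inter_card_anova_all(table: CqTable,
                         factor_mode: str = "replicate_instance") -> pd.DataFrame:
    """Replicate ANOVA for every gene with wells on >= 2 cards.

    Returns a DataFrame ``assay_id, n_levels, F, df1, df2, p, flag``
    (flag marks p < 0.05).  Genes on a single card are skipped.
    """
    counts = table.wells.groupby("assay_id")["card"].nunique()
    eligible = set(counts.index[counts >= 2])
    rows = []
    for gene, sub in table.wells.groupby("assay_id", sort=True):
        if gene not in eligible:
            continue
        levels = _levels_from_frame(sub, gene, factor_mode)
        F, df, p = oneway_anova(levels)
        rows.append({"assay_id": gene, "n_levels": len(levels),
                     "F": F, "df1": df[0], "df2": df[1], "p": p, "flag": p < 0.05})
    return pd.DataFrame(rows, columns=["assay_id", "n_levels", "F", "df1", "df2", "p", "flag"])
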