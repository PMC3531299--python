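"""Candidate endogenous-control statistics and the three-criterion filter.

A usable reference gene must be (1) moderately-to-highly expressed
(mean Cq <= 25), (2) not differentially expressed between the case and
control groups (two-sample t-test p < 0.05 combined with |fold change|
>= 1.5 marks a gene as differential), and (3) uniformly expressed across
all samples (coefficient of variation of Cq < 10%).

Genes passing all three hard criteria but showing |FC| >= 1.5 without
statistical significance are given ``warn`` status: they are kept for
stability ranking but flagged as not ideal for a final recommendation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cq import CollapsedCqMatrix
from .errors import DataError

log = logging.getLogger(__name__)

#: default thresholds of the three-criterion filter
MEAN_CQ_MAX = 25.0
ALPHA = 0.05
FC_THRESHOLD = 1.5
CV_MAX = 10.0

CRITERION_EXPRESSION = "mean_cq_above_max"
CRITERION_DIFFERENTIAL = "differentially_expressed"
CRITERION_CV = "cv_at_or_above_max"


@dataclass(frozen=True)
class CandidateStats:
    """Per-gene summary statistics plus (after filtering) a status."""

    gene: str
    card: str
    mean_cq: float
    min_cq: float
    max_cq: float
    cv_percent: float
    group_mean_cq: dict[str, float]
    t_stat: float
    df: float
    p_value: float
    fold_change: float
    status: str | None = None
    fail_reasons: tuple[str, ...] = ()
    colocated_with: tuple[str, ...] = ()


def welch_two_sample_t(case: np.ndarray, control: np.ndarray) -> tuple[float, float, float]:
    """Welch unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with t = (mean(case) - mean(control)) / SE.
    Degenerate inputs follow a stated convention: two constant, equal
    groups give ``(0, df, 1)``; two constant, unequal groups give
    ``(+/-inf, df, 0)`` (logged).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise DataError("each group needs n >= 2 for the t-test")
    if np.var(case) == 0 and np.var(control) == 0:
        df = float(case.size + control.size - 2)
        if case.mean() == control.mean():
            return 0.0, df, 1.0
        log.warning("welch_two_sample_t: both groups constant but unequal; p set to 0")
        t = np.inf if case.mean() > control.mean() else -np.inf
        return float(t), df, 0.0
    res = stats.ttest_ind(case, control, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fold_change_from_cq(case_mean_cq: float, control_mean_cq: float) -> float:
    """Signed expression fold change between group-mean Cq values.

    Expression is proportional to ``2**-Cq``, so the case/control ratio is
    ``r = 2**(control_mean_cq - case_mean_cq)``.  Ratios below one are
    reported as negative reciprocals (e.g. r = 0.5 -> -2.0), so
    |fold change| >= 1 always.
    """
    r = 2.0 ** (control_mean_cq - case_mean_cq)
    return float(r) if r >= 1.0 else float(-1.0 / r)


def candidate_stats(matrix: CollapsedCqMatrix,
                    case_label: str = "case",
                    control_label: str = "control") -> list[CandidateStats]:
    """Summary statistics for every gene on a card (no filter status yet).

    Mean/min/max and CV are computed over all samples on the Cq scale
    (CV = sample SD / mean x 100, n-1 denominator); the t-test and the
    signed fold change compare the case group against the control group.
    """
    groups = matrix.groups
    case_ids = groups.index[groups == case_label]
    control_ids = groups.index[groups == control_label]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise DataError("each group needs >= 2 samples for candidate statistics")
    out = []
    for gene, row in matrix.values.iterrows():
        vals = row.to_numpy(dtype=float)
        case = row[case_ids].to_numpy(dtype=float)
        control = row[control_ids].to_numpy(dtype=float)
        t, df, p = welch_two_sample_t(case, control)
        mean = float(vals.mean())
        out.append(CandidateStats(
            gene=str(gene),
            card=matrix.card,
            mean_cq=mean,
            min_cq=float(vals.min()),
            max_cq=float(vals.max()),
            cv_percent=float(np.std(vals, ddof=1) / mean * 100.0),
            group_mean_cq={case_label: float(case.mean()),
                           control_label: float(control.mean())},
            t_stat=t,
            df=df,
            p_value=p,
            fold_change=fold_change_from_cq(case.mean(), control.mean()),
        ))
    return out


def apply_ec_filter(stats_list: list[CandidateStats],
                    mean_cq_max: float = MEAN_CQ_MAX,
                    alpha: float = ALPHA,
                    fc_threshold: float = FC_THRESHOLD,
                    cv_max: float = CV_MAX) -> list[CandidateStats]:
    """Apply the three-criterion filter; returns new objects with status.

    fail if mean Cq > ``mean_cq_max`` (criterion 1), if p < ``alpha`` and
    |FC| >= ``fc_threshold`` (criterion 2, differential expression), or if
    CV >= ``cv_max`` (criterion 3).  Genes passing all three but with
    |FC| >= ``fc_threshold`` get ``warn`` (ranked, not recommended).
    Boundary semantics are as printed: mean Cq exactly at the maximum
    passes (<=); CV exactly at the maximum fails (<); |FC| exactly at the
    threshold counts as exceeding it (>=).
    """
    out = []
    for s in stats_list:
        reasons = []
        if s.mean_cq > mean_cq_max:
            reasons.append(CRITERION_EXPRESSION)
        if s.p_value < alpha and abs(s.fold_change) >= fc_threshold:
            reasons.append(CRITERION_DIFFERENTIAL)
        if s.cv_percent >= cv_max:
            reasons.append(CRITERION_CV)
        if reasons:
            status = "fail"
        elif abs(s.fold_change) >= fc_threshold:
            status = "warn"
        else:
            status = "pass"
        out.append(replace(s, status=status, fail_reasons=tuple(reasons)))
    return out


def _cytobands(location: str) -> set[str]:
    return {part.strip() for part in str(location).split("/") if part.strip()}


def flag_colocated(candidates: list[CandidateStats],
                   assays: pd.DataFrame) -> list[tuple[str, str]]:
    """Flag surviving candidate pairs that share a cytoband.

    Clustered miRNA genes transcribed as one polycistron are co-regulated,
    which would bias a stability ranking toward the cluster; pairs of
    non-failing candidates sharing any cytoband (multi-valued locations
    are slash-separated) are therefore flagged — not removed — and each
    gene's ``colocated_with`` list is filled in place of the input
    objects (returned as a new list of pairs).

    Genes without an annotation row are skipped with a warning.
    """
    loc_of = (assays.drop_duplicates("assay_id")
              .set_index("assay_id")["chrom_location"].to_dict())
    surviving = [s for s in candidates if s.status in (None, "pass", "warn")]
    bands: dict[str, set[str]] = {}
    for s in surviving:
        if s.gene not in loc_of or not str(loc_of[s.gene]).strip():
            log.warning("flag_colocated: no chromosomal location for %s, skipped", s.gene)
            continue
        bands[s.gene] = _cytobands(loc_of[s.gene])
    pairs = []
    genes = sorted(bands)
    for i, g in enumerate(genes):
        for h in genes[i + 1:]:
            if bands[g] & bands[h]:
                pairs.append((g, h))
    partners: dict[str, list[str]] = {}
    for g, h in pairs:
        partners.setdefault(g, []).append(h)
        partners.setdefault(h, []).append(g)
    for i, s in enumerate(candidates):
        if s.gene in partners:
            candidates[i] = replace(s, colocated_with=tuple(sorted(partners[s.gene])))
    return pairs


def stats_to_frame(stats_list: list[CandidateStats]) -> pd.DataFrame:
    """Tabular (Table-1-like) view of candidate statistics."""
    rows = []
    for s in stats_list:
        rows.append({
            "gene": s.gene, "card": s.card, "mean_cq": s.mean_cq,
            "min_cq": s.min_cq, "max_cq": s.max_cq, "cv_percent": s.cv_percent,
            "t_stat": s.t_stat, "p_value": s.p_value, "fold_change": s.fold_change,
            "status": s.status,
            "fail_reasons": ";".join(s.fail_reasons),
            "colocated_with": ";".join(s.colocated_with),
        })
    return pd.DataFrame(rows)
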