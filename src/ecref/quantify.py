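"""Relative quantification against chosen endogenous controls.

Normalized expression uses the 2^-dCq method: for target gene t and
control set E, dCq = Cq_t - Cq_E per sample, relative expression
2^-dCq, and log2 relative expression -dCq.  A multi-gene control set is
summarized by the arithmetic mean of the member Cq values, which equals
the geometric mean of their expression values.

Group-level log2 fold change is the case mean minus the control mean of
log2 relative expression.  The control mean can be taken over samples
directly or per cell line first (average within line, then across
lines), matching designs where the control group pools sorted
populations from a small number of lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cq import CollapsedCqMatrix
from .errors import DataError

log = logging.getLogger(__name__)

POOLING_MODES = ("per_sample", "per_line_average")


@dataclass(frozen=True)
class NormalizationResult:
    """Per-sample normalized expression of one target against one control set."""

    target: str
    normalizers: tuple[str, ...]
    delta_cq: pd.Series
    rel_expr: pd.Series      # 2^-dCq, > 0
    log2_rel: pd.Series      # -dCq

    @property
    def label(self) -> str:
        return "+".join(self.normalizers)


def delta_cq_normalize(matrix: CollapsedCqMatrix, target: str,
                       normalizers: list[str] | tuple[str, ...] | str) -> NormalizationResult:
    """Normalize one target gene against one or more control genes."""
    if isinstance(normalizers, str):
        normalizers = (normalizers,)
    normalizers = tuple(normalizers)
    if not normalizers:
        raise DataError("empty normalizer set")
    if target in normalizers:
        raise DataError(f"self-normalization: {target!r} is in the normalizer set")
    for g in (target, *normalizers):
        if g not in matrix.values.index:
            raise DataError(f"gene {g!r} not on card {matrix.card}")
    cq_ec = matrix.values.loc[list(normalizers)].mean(axis=0)
    delta = matrix.values.loc[target] - cq_ec
    return NormalizationResult(
        target=target,
        normalizers=normalizers,
        delta_cq=delta,
        rel_expr=2.0 ** (-delta),
        log2_rel=-delta,
    )


def _control_mean(log2_rel: pd.Series, control_ids, subgroups: pd.Series | None,
                  control_pooling: str) -> float:
    vals = log2_rel[control_ids]
    if control_pooling == "per_sample":
        return float(vals.mean())
    if control_pooling == "per_line_average":
        if subgroups is None:
            raise DataError("per_line_average pooling requires subgroup (line) labels")
        lines = subgroups[control_ids]
        return float(vals.groupby(lines).mean().mean())
    raise DataError(f"unknown control_pooling {control_pooling!r}")


def group_log2_fc(result: NormalizationResult, groups: pd.Series,
                  subgroups: pd.Series | None = None,
                  case_label: str = "case", control_label: str = "control",
                  control_pooling: str = "per_line_average") -> float:
    """Case-vs-control log2 fold change of normalized expression.

    With ``control_pooling="per_line_average"`` the control mean is the
    unweighted mean of per-line means, so unequal per-line sample counts
    do not tilt the pooled control value.
    """
    case_ids = groups.index[groups == case_label]
    control_ids = groups.index[groups == control_label]
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise DataError("both groups must be non-empty")
    case_mean = float(result.log2_rel[case_ids].mean())
    control_mean = _control_mean(result.log2_rel, control_ids, subgroups, control_pooling)
    return case_mean - control_mean


def _direction(log2_fc: float) -> str:
    if log2_fc > 0:
        return "up"
    if log2_fc < 0:
        return "down"
    return "flat"


def normalizer_impact_table(matrix: CollapsedCqMatrix, targets: list[str],
                            normalizer_sets: list[list[str] | tuple[str, ...]],
                            control_pooling: str = "per_line_average",
                            case_label: str = "case",
                            control_label: str = "control") -> pd.DataFrame:
    """Log2 fold change of every target under every normalizer set.

    Returns one row per (target, normalizer set) with columns ``target,
    normalizer_set, log2_fc, direction, sign_flip``; ``sign_flip`` is
    True for every row of a target whose direction is not the same under
    all normalizer sets — the hallmark of an unsuitable, differentially
    expressed control.
    """
    rows = []
    for target in targets:
        for norm in normalizer_sets:
            res = delta_cq_normalize(matrix, target, norm)
            fc = group_log2_fc(res, matrix.groups, matrix.subgroups,
                               case_label=case_label, control_label=control_label,
                               control_pooling=control_pooling)
            rows.append({"target": target, "normalizer_set": res.label,
                         "log2_fc": fc, "direction": _direction(fc)})
    table = pd.DataFrame(rows, columns=["target", "normalizer_set", "log2_fc", "direction"])
    if table.empty:
        table["sign_flip"] = pd.Series(dtype=bool)
        return table
    flip = table.groupby("target")["direction"].transform(lambda s: s.nunique() > 1)
    table["sign_flip"] = flip
    return table
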