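"""End-to-end reference-gene selection pipeline and report writer.

Stages: read (or simulate) -> ceiling imputation -> replicate QC ->
replicate collapse per card -> three-criterion filter -> geNorm and
NormFinder ranking of surviving candidates -> recommended control pair
per card -> optional normalizer-impact quantification.  All outputs are
TSV plus a JSON run record; reruns with identical config and inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cq import collapse_replicates, impute_cq_ceiling, read_cq_table
from .errors import ConfigError, DataError


class EmptyCandidateSet(DataError):
    """No card yielded a surviving candidate; outputs are kept for inspection."""
from .filtering import (ALPHA, CV_MAX, FC_THRESHOLD, MEAN_CQ_MAX, apply_ec_filter,
                        candidate_stats, flag_colocated, stats_to_frame)
from .genorm import rank_stepwise
from .genorm import result_to_frame as genorm_frame
from .normfinder import best_pair, run_normfinder, shrunk_variance
from .normfinder import result_to_frame as normfinder_frame
from .qc import inter_card_anova_all, intra_card_stats
from .quantify import normalizer_impact_table
from .simulate import paper_like_preset

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and options of a pipeline run.

    Either the three input paths or ``preset`` must be given.  All
    threshold defaults are the study's printed values.
    """

    cq_path: str | None = None
    sample_path: str | None = None
    assay_path: str | None = None
    preset: str | None = None
    seed: int = 0
    out_dir: str = "ecref_out"
    ceiling: float = 32.0
    mean_cq_max: float = MEAN_CQ_MAX
    alpha: float = ALPHA
    fc_threshold: float = FC_THRESHOLD
    cv_max: float = CV_MAX
    factor_mode: str = "replicate_instance"
    ranking: str = "stepwise"
    top_m: int | None = None
    control_pooling: str = "per_line_average"
    targets: tuple[str, ...] = ()
    normalizer_sets: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        for name in ("ceiling", "mean_cq_max", "alpha", "fc_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        if self.cv_max < 0:
            raise ConfigError("cv_max must be >= 0")
        if self.preset is None and not (self.cq_path and self.sample_path and self.assay_path):
            raise ConfigError("either preset or all three input paths are required")
        if self.preset is not None and self.preset != "paper-like":
            raise ConfigError(f"unknown preset {self.preset!r}")


def _write_tsv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    written.append(path)


def _load_inputs(config: PipelineConfig, out: Path, written: list[Path]):
    if config.preset == "paper-like":
        table, truth = paper_like_preset(config.seed)
        truth_path = out / "truth.json"
        truth_path.write_text(truth.to_json())
        written.append(truth_path)
        return table
    return read_cq_table(config.cq_path, config.sample_path, config.assay_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written as JSON).

    Any stage error aborts the run and removes files written so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except EmptyCandidateSet:
        raise  # report bundle (header-only rankings) is left in place
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> dict:
    table = _load_inputs(config, out, written)
    table = impute_cq_ceiling(table, ceiling=config.ceiling)

    # replicate QC: intra-card spread and inter-card ANOVA where possible
    intra = intra_card_stats(table)
    anova = inter_card_anova_all(table, factor_mode=config.factor_mode)
    qc_table = intra.merge(anova, on="assay_id", how="left")
    _write_tsv(qc_table, out / "qc.tsv", written)

    matrices = collapse_replicates(table)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {"ceiling": config.ceiling, "mean_cq_max": config.mean_cq_max,
                       "alpha": config.alpha, "fc_threshold": config.fc_threshold,
                       "cv_max": config.cv_max},
        "options": {"factor_mode": config.factor_mode, "ranking": config.ranking,
                    "control_pooling": config.control_pooling,
                    "top_m": config.top_m, "preset": config.preset},
        "cards": {},
    }
    summary_lines = [f"ecref {__version__} reference-gene selection report",
                     f"thresholds: mean Cq <= {config.mean_cq_max:g}, "
                     f"p < {config.alpha:g} & |FC| >= {config.fc_threshold:g} "
                     f"(differential), CV < {config.cv_max:g}"]
    any_candidates = False

    for card, matrix in sorted(matrices.items()):
        stats = candidate_stats(matrix)
        stats = apply_ec_filter(stats, mean_cq_max=config.mean_cq_max, alpha=config.alpha,
                                fc_threshold=config.fc_threshold, cv_max=config.cv_max)
        coloc_pairs = flag_colocated(stats, table.assays)
        frame = stats_to_frame(stats)
        _write_tsv(frame, out / f"candidates_{card}.tsv", written)
        _write_tsv(frame[["gene", "mean_cq", "min_cq", "max_cq", "cv_percent"]],
                   out / f"summary_stats_{card}.tsv", written)

        passing = [s.gene for s in stats if s.status == "pass"]
        warned = [s.gene for s in stats if s.status == "warn"]
        ranked_genes = passing + warned
        card_report = {"n_genes": len(stats), "n_pass": len(passing),
                       "n_warn": len(warned), "warn_genes": warned,
                       "colocated_pairs": coloc_pairs,
                       "recommended_pair": None, "recommended_pair_stability": None,
                       "genorm_top_pair": None}
        summary_lines.append(f"card {card}: {len(stats)} genes, {len(passing)} pass, "
                             f"{len(warned)} warn, "
                             f"{len(stats) - len(passing) - len(warned)} fail")
        if ranked_genes:
            any_candidates = True

        if len(ranked_genes) < 3:
            _write_tsv(pd.DataFrame(columns=["rank", "gene", "M_full_set",
                                             "M_at_elimination", "round_eliminated"]),
                       out / f"genorm_{card}.tsv", written)
            _write_tsv(pd.DataFrame(columns=["rank", "gene", "stability"]),
                       out / f"normfinder_{card}.tsv", written)
            summary_lines.append(f"card {card}: ranking skipped — fewer than 3 surviving "
                                 f"candidates ({len(ranked_genes)})")
            report["cards"][card] = card_report
            continue

        sub = matrix.subset(sorted(ranked_genes))
        gn = rank_stepwise(sub)
        _write_tsv(genorm_frame(gn), out / f"genorm_{card}.tsv", written)
        card_report["genorm_top_pair"] = gn.ranking[:2]

        nf = run_normfinder(sub, top_m=config.top_m)
        _write_tsv(normfinder_frame(nf), out / f"normfinder_{card}.tsv", written)
        card_report["normfinder_best_gene"] = nf.best_gene
        card_report["normfinder_best_pair"] = list(nf.best_pair) if nf.best_pair else None

        # recommendation: most stable NormFinder pair among pass-status genes
        pass_ranked = [g for g in nf.ranking if g in passing]
        if len(pass_ranked) >= 2:
            pair, pair_val = best_pair(nf.shrunk_diff, shrunk_variance(nf), pass_ranked)
            card_report["recommended_pair"] = list(pair)
            card_report["recommended_pair_stability"] = pair_val
            summary_lines.append(f"card {card}: recommended control pair "
                                 f"{pair[0]} + {pair[1]} (stability {pair_val:.4f})")
        else:
            summary_lines.append(f"card {card}: no control pair recommended — fewer than "
                                 "2 pass-status genes")
        report["cards"][card] = card_report
        for g in warned:
            if g in nf.ranking[:4] or g in gn.ranking[:4]:
                summary_lines.append(f"card {card}: {g} is ranked in the top candidates "
                                     "but carries warn status (differential fold change) — "
                                     "ranked but not recommended")

    if config.targets and config.normalizer_sets:
        impact_frames = []
        for card, matrix in sorted(matrices.items()):
            present = [t for t in config.targets if t in matrix.values.index]
            sets_here = [s for s in config.normalizer_sets
                         if all(g in matrix.values.index for g in s)]
            if present and sets_here:
                tab = normalizer_impact_table(matrix, present, sets_here,
                                              control_pooling=config.control_pooling)
                tab.insert(0, "card", card)
                impact_frames.append(tab)
        impact = (pd.concat(impact_frames, ignore_index=True) if impact_frames
                  else pd.DataFrame(columns=["card", "target", "normalizer_set",
                                             "log2_fc", "direction", "sign_flip"]))
        _write_tsv(impact, out / "impact.tsv", written)

    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(summary_lines) + "\n")
    written.append(summary_path)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    written.append(report_path)
    if not any_candidates:
        raise EmptyCandidateSet("no card yielded any surviving candidate reference gene")
    return report
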