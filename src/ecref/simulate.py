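"""Synthetic Cq dataset generator with ground truth.

Emulates a two-card TLDA miRNA profiling study: a case group of tumour
specimens against a small control group of sorted stem/progenitor
populations derived from two cell lines.  Each well's Cq value is

    Cq = baseline + group_effect*[case] + card_offset
         + N(0, gene_noise_sd) [per sample]  + N(0, replicate_noise_sd) [per well]

censored at the detection ceiling (32 cycles by default).  A negative
``group_effect_cq`` means fewer cycles — i.e. higher expression — in the
case group; the true log2 fold change of a gene is therefore
``-group_effect_cq``.

:func:`paper_like_preset` builds a desk-scale study (~60 genes, 9 case
vs 4 control samples) containing the characters such a study turns up:
uniform sn/snoRNA and miRNA controls, a weakly over-expressed control
that misses significance, a moderately and a massively (~500-fold)
inflated control, a replicate-heavy gene with a 0.5-cycle card offset,
three strongly over-expressed target miRNAs, and null filler genes with
assorted noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cq import CqTable
from .errors import ConfigError


@dataclass(frozen=True)
class GeneSim:
    """Ground-truth parameters of one simulated assay."""

    assay_id: str
    baseline_cq: float
    rna_class: str = "miRNA"
    chrom_location: str = ""
    group_effect_cq: float = 0.0
    #: per-sample biological noise SD in cycles; scalar or {group: sd}
    noise_sd: float | dict[str, float] = 0.5
    #: additive per-card shift in cycles, e.g. {"B": 0.5}
    card_offset: dict[str, float] = field(default_factory=dict)
    #: replicate wells per card, e.g. {"A": 1, "B": 4}
    wells: dict[str, int] = field(default_factory=lambda: {"A": 1})
    role: str = "null"

    def noise_for(self, group: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd[group])
        return float(self.noise_sd)

    @property
    def true_log2_fc(self) -> float:
        return -self.group_effect_cq


@dataclass(frozen=True)
class SimConfig:
    """Study design: genes, sample layout, noise and censoring."""

    genes: tuple[GeneSim, ...]
    n_case: int = 9
    control_lines: tuple[str, ...] = ("hES3", "MEL1")
    control_subtypes: tuple[str, ...] = ("NSC", "NPC")
    replicate_noise_sd: float = 0.1
    ceiling: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or len(self.control_lines) * len(self.control_subtypes) < 2:
            raise ConfigError("each group needs >= 2 samples")
        if self.replicate_noise_sd < 0 or self.ceiling <= 0:
            raise ConfigError("noise SDs must be >= 0 and ceiling > 0")
        for g in self.genes:
            sds = (g.noise_sd.values() if isinstance(g.noise_sd, dict) else [g.noise_sd])
            if any(s < 0 for s in sds):
                raise ConfigError(f"{g.assay_id}: negative noise SD")
            if not g.wells or sum(g.wells.values()) < 1 or any(n < 0 for n in g.wells.values()):
                raise ConfigError(f"{g.assay_id}: invalid replicate layout {g.wells}")


@dataclass(frozen=True)
class SimTruth:
    """Realized ground truth of a simulated dataset (JSON-serializable)."""

    config: SimConfig
    sample_groups: dict[str, str]
    true_log2_fc: dict[str, float]
    designed_instability: dict[str, float]
    designed_stability_order: list[str]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["config"]["genes"] = [dataclasses.asdict(g) for g in self.config.genes]
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        cfg = payload["config"]
        genes = tuple(GeneSim(**g) for g in cfg.pop("genes"))
        for key in ("control_lines", "control_subtypes"):
            cfg[key] = tuple(cfg[key])
        config = SimConfig(genes=genes, **cfg)
        return cls(config=config,
                   sample_groups=payload["sample_groups"],
                   true_log2_fc=payload["true_log2_fc"],
                   designed_instability=payload["designed_instability"],
                   designed_stability_order=payload["designed_stability_order"])


def _sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = [{"sample_id": f"MB{i + 1:02d}", "group": "case", "subgroup": "tumour"}
            for i in range(config.n_case)]
    for line in config.control_lines:
        for sub in config.control_subtypes:
            rows.append({"sample_id": f"{line}_{sub}", "group": "control", "subgroup": line})
    return pd.DataFrame(rows)


def _designed_instability(config: SimConfig, n_case: int, n_control: int) -> dict[str, float]:
    """Model-implied composite instability: |inter-group half-shift| +
    intra-group SE, averaged over groups (gene-centred as the estimator is)."""
    delta = np.array([g.true_log2_fc for g in config.genes])
    centred = delta - delta.mean()
    scores = {}
    for g, dc in zip(config.genes, centred):
        se = (np.sqrt(g.noise_for("case") ** 2 / n_case)
              + np.sqrt(g.noise_for("control") ** 2 / n_control)) / 2.0
        scores[g.assay_id] = abs(dc) / 2.0 + se
    return scores


def simulate_cq_dataset(config: SimConfig) -> tuple[CqTable, SimTruth]:
    """Draw a full per-well Cq dataset; the seed fully determines the bytes."""
    rng = np.random.default_rng(config.seed)
    samples = _sample_sheet(config)
    sample_ids = samples["sample_id"].to_numpy()
    is_case = (samples["group"] == "case").to_numpy()
    n_samples = len(samples)

    frames = []
    assay_rows = []
    for g in config.genes:
        sd = np.where(is_case, g.noise_for("case"), g.noise_for("control"))
        bio = (g.baseline_cq + g.group_effect_cq * is_case
               + rng.standard_normal(n_samples) * sd)
        for card in sorted(g.wells):
            n_wells = g.wells[card]
            if n_wells == 0:
                continue
            vals = (bio[:, None] + g.card_offset.get(card, 0.0)
                    + rng.standard_normal((n_samples, n_wells)) * config.replicate_noise_sd)
            vals = np.clip(vals, 0.0, config.ceiling)
            frames.append(pd.DataFrame({
                "sample_id": np.repeat(sample_ids, n_wells),
                "card": card,
                "assay_id": g.assay_id,
                "well": np.tile([f"w{i + 1}" for i in range(n_wells)], n_samples),
                "cq": vals.ravel(),
            }))
            assay_rows.append({"assay_id": g.assay_id, "rna_class": g.rna_class,
                               "chrom_location": g.chrom_location, "card": card,
                               "n_replicates": n_wells})
    wells = pd.concat(frames, ignore_index=True)
    wells = wells.merge(samples[["sample_id", "group"]], on="sample_id")
    wells = wells[["sample_id", "group", "card", "assay_id", "well", "cq"]]
    table = CqTable(wells=wells, samples=samples, assays=pd.DataFrame(assay_rows))

    n_control = int((~is_case).sum())
    instability = _designed_instability(config, int(is_case.sum()), n_control)
    order = sorted(instability, key=lambda g: (instability[g], g))
    truth = SimTruth(
        config=config,
        sample_groups=dict(zip(samples["sample_id"], samples["group"])),
        true_log2_fc={g.assay_id: g.true_log2_fc for g in config.genes},
        designed_instability=instability,
        designed_stability_order=order,
    )
    return table, truth


# ---------------------------------------------------------------------------
# paper-like preset

#: normalizer sets exercised in the normalizer-impact comparison
PRESET_UNIFORM_NORMALIZERS = (("miR-425s-like",), ("RNU24-like",), ("miR-877-like",),
                              ("miR-425s-like", "RNU24-like"))
PRESET_INFLATED_NORMALIZER = ("RNU43-like",)
PRESET_TARGETS = ("miR-21s-like", "miR-144s-like", "miR-923-like")

def _filler_cytoband(i: int) -> str:
    """Unique synthetic cytoband per filler so co-location flags arise only
    from the designed shared-band pair."""
    return f"{(i % 22) + 1}{'pq'[i % 2]}{11 + i // 2}.{(i % 3) + 1}"


def paper_like_gene_panel(n_genes: int = 60) -> tuple[GeneSim, ...]:
    """The designed gene panel behind :func:`paper_like_preset`."""
    genes = [
        # sn/snoRNA controls, replicate-heavy as on real cards
        GeneSim("RNU48-like", 15.0, "snoRNA", "6p21.33", -1.24, 1.43,
                wells={"A": 1, "B": 4}, role="warn_fc"),
        GeneSim("RNU44-like", 22.85, "snoRNA", "1q25.1", -0.03, 1.45,
                wells={"A": 1, "B": 4}, role="uniform"),
        GeneSim("MammU6-like", 20.0, "snRNA", "15q23", 0.0, 0.1,
                card_offset={"B": 0.5}, wells={"A": 4, "B": 4}, role="card_offset"),
        # zero sample-level noise: the one-way ANOVA null holds exactly, so
        # this gene calibrates the false-flag rate of the replicate QC
        GeneSim("U6null-like", 21.0, "snRNA", "15q24", 0.0, 0.0,
                wells={"A": 4, "B": 4}, role="replicate_null"),
        GeneSim("U6mod-like", 19.0, "snRNA", "15q26", -1.872, 2.1,
                wells={"A": 1}, role="moderate_fc"),
        GeneSim("RNU43-like", 24.0, "snoRNA", "22q13", -8.96, 1.2,
                wells={"B": 4}, role="inflated"),
        GeneSim("RNU24-like", 21.5, "snoRNA", "9q34", 0.0, 1.0,
                wells={"B": 4}, role="uniform"),
        GeneSim("RNU6B-like", 21.0, "snoRNA", "10p13", -3.905, 1.1,
                wells={"B": 4}, role="inflated_moderate"),
        # uniform miRNA candidates
        GeneSim("miR-425s-like", 24.87, "miRNA", "3q21.31", 0.0, 1.0,
                wells={"B": 1}, role="uniform"),
        GeneSim("miR-877-like", 23.99, "miRNA", "6p21.33", 0.0, 0.8,
                wells={"B": 1}, role="uniform"),
        GeneSim("miR-301a-like", 19.56, "miRNA", "17q22", 0.0, 1.35,
                wells={"A": 1}, role="uniform"),
        GeneSim("miR-339-5p-like", 24.28, "miRNA", "7p22.3", 0.0, 1.4,
                wells={"A": 1}, role="uniform"),
        GeneSim("miR-210-like", 20.96, "miRNA", "11p15.5", 0.0, 1.2,
                wells={"A": 1}, role="uniform"),
        GeneSim("miR-197-like", 21.94, "miRNA", "1p13.3", 0.0, 1.2,
                wells={"A": 1}, role="uniform"),
        GeneSim("miR-328-like", 20.5, "miRNA", "16q22.1", 0.0, 1.4,
                wells={"A": 1}, role="uniform"),
        # strongly over-expressed tumour targets (16-32 fold up)
        GeneSim("miR-21s-like", 25.0, "miRNA", "17q23.1", -4.0, 0.9,
                wells={"B": 1}, role="target"),
        GeneSim("miR-144s-like", 24.5, "miRNA", "17q11.2", -4.5, 0.9,
                wells={"B": 1}, role="target"),
        GeneSim("miR-923-like", 26.0, "miRNA", "17q11.1", -5.0, 0.9,
                wells={"B": 1}, role="target"),
    ]
    # null filler genes with assorted baselines and noise; parameters follow a
    # fixed grid so the panel itself is deterministic and seed-independent
    n_fill = max(0, n_genes - len(genes))
    for i in range(n_fill):
        baseline = 17.0 + 11.0 * ((i * 7) % n_fill) / max(1, n_fill - 1) if n_fill > 1 else 22.0
        noise = 0.8 + 1.2 * ((i * 5) % n_fill) / max(1, n_fill - 1) if n_fill > 1 else 1.2
        card = "A" if i % 2 == 0 else "B"
        genes.append(GeneSim(f"null-{i + 1:03d}", round(baseline, 3), "miRNA",
                             _filler_cytoband(i),
                             0.0, round(noise, 3), wells={card: 1}, role="null"))
    return tuple(genes)


def paper_like_preset(seed: int, n_genes: int = 60) -> tuple[CqTable, SimTruth]:
    """Desk-scale stand-in for the full 668-assay two-card study."""
    config = SimConfig(genes=paper_like_gene_panel(n_genes), seed=seed)
    return simulate_cq_dataset(config)
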