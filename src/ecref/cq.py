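"""Cq data containers and IO for TLDA-style RT-qPCR experiments.

The central object is :class:`CqTable`, a validated long-format table of
per-well quantification-cycle (Cq) values joined to sample and assay
annotations.  Downstream analyses work on :class:`CollapsedCqMatrix`
objects (genes x samples, technical replicates averaged, one matrix per
TLDA card).

Conventions
-----------
* Cq is on the PCR cycle scale; expression is proportional to ``2**-Cq``,
  so log2 relative expression is simply ``-Cq``.
* Wells reported as "Undetermined" are stored as missing (NaN) and imputed
  to the detection ceiling (default 32 cycles) by
  :func:`impute_cq_ceiling`.
* Genes assayed on both cards are kept separate per card throughout; the
  two cards are processed as independent gene panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

log = logging.getLogger(__name__)

DEFAULT_CEILING = 32.0

#: columns that uniquely identify a well measurement
WELL_KEY = ["sample_id", "card", "assay_id", "well"]

CQ_COLUMNS = ["sample_id", "card", "assay_id", "well", "cq"]
SAMPLE_COLUMNS = ["sample_id", "group", "subgroup"]
ASSAY_COLUMNS = ["assay_id", "rna_class", "chrom_location", "card", "n_replicates"]

#: sentinel used in TSV files for wells that never crossed threshold
UNDETERMINED = "Undetermined"


@dataclass(frozen=True)
class CqTable:
    """Long-format per-well Cq measurements with joined annotations.

    Attributes
    ----------
    wells:
        DataFrame with columns ``sample_id, group, card, assay_id, well,
        cq``; ``cq`` is float with NaN for undetermined wells.
    samples:
        DataFrame with columns ``sample_id, group, subgroup``.
    assays:
        DataFrame with columns ``assay_id, rna_class, chrom_location,
        card, n_replicates`` (one row per assay per card it appears on).
    """

    wells: pd.DataFrame
    samples: pd.DataFrame
    assays: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_wells(self.wells)
        if self.samples["sample_id"].duplicated().any():
            raise DataError("duplicate sample_id in sample annotation")
        known_samples = set(self.samples["sample_id"])
        unknown = set(self.wells["sample_id"]) - known_samples
        if unknown:
            raise DataError(f"wells reference unknown sample ids: {sorted(unknown)}")
        known_assays = set(zip(self.assays["assay_id"], self.assays["card"]))
        seen = set(zip(self.wells["assay_id"], self.wells["card"]))
        unknown = seen - known_assays
        if unknown:
            raise DataError(f"wells reference unknown (assay, card) pairs: {sorted(unknown)}")

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def cards(self) -> list[str]:
        return sorted(self.wells["card"].unique())

    def group_of(self) -> pd.Series:
        """sample_id -> group label."""
        return self.samples.set_index("sample_id")["group"]

    def subgroup_of(self) -> pd.Series:
        """sample_id -> subgroup (e.g. cell line of origin)."""
        return self.samples.set_index("sample_id")["subgroup"]


def _validate_wells(wells: pd.DataFrame) -> None:
    missing = [c for c in CQ_COLUMNS if c not in wells.columns]
    if missing:
        raise FormatError(f"Cq table missing columns: {missing}")
    dup = wells.duplicated(subset=WELL_KEY)
    if dup.any():
        first = wells.loc[dup, WELL_KEY].iloc[0].tolist()
        raise DataError(f"duplicate well key (sample, card, assay, well): {first}")
    cq = wells["cq"]
    if (cq.dropna() < 0).any():
        raise DataError("negative Cq values present")


@dataclass(frozen=True)
class CollapsedCqMatrix:
    """Genes x samples Cq matrix for a single card, replicates averaged.

    ``values`` has assay ids as the row index and sample ids as columns;
    ``groups`` and ``subgroups`` are aligned to the columns.
    """

    values: pd.DataFrame
    card: str
    groups: pd.Series
    subgroups: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise DataError("collapsed matrix contains missing entries")
        if list(self.groups.index) != list(self.values.columns):
            raise DataError("group vector not aligned to sample columns")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes: list[str]) -> "CollapsedCqMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise DataError(f"genes not in matrix: {missing}")
        return replace(self, values=self.values.loc[genes])


def read_cq_table(path, sample_meta, assay_meta) -> CqTable:
    """Read and validate the three input TSVs into a :class:`CqTable`.

    ``path`` holds per-well Cq values (columns ``sample_id, card,
    assay_id, well, cq``; ``cq`` decimal or ``"Undetermined"``),
    ``sample_meta`` the sample sheet and ``assay_meta`` the assay sheet.
    """
    wells = _read_tsv(path, CQ_COLUMNS)
    samples = _read_tsv(sample_meta, SAMPLE_COLUMNS)
    assays = _read_tsv(assay_meta, ASSAY_COLUMNS)

    def _parse_cq(raw: str) -> float:
        raw = raw.strip()
        if raw in (UNDETERMINED, "", "nan", "NA"):
            return np.nan
        try:
            return float(raw)  # exact round-trip parsing
        except ValueError:
            raise FormatError(f"non-numeric cq value: {raw!r}") from None

    wells = wells.assign(cq=wells["cq"].map(_parse_cq))

    for col in ("sample_id", "card", "assay_id", "well"):
        wells[col] = wells[col].astype(str)
    wells = wells.merge(samples[["sample_id", "group"]], on="sample_id", how="left")
    if wells["group"].isna().any():
        unknown = wells.loc[wells["group"].isna(), "sample_id"].unique().tolist()
        raise DataError(f"wells reference unknown sample ids: {unknown}")
    wells = wells[["sample_id", "group", "card", "assay_id", "well", "cq"]]
    assays = assays.assign(n_replicates=pd.to_numeric(assays["n_replicates"]).astype(int))
    return CqTable(wells=wells, samples=samples, assays=assays)


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_cq_table(table: CqTable, cq_path, sample_path, assay_path) -> None:
    """Write the three TSVs; inverse of :func:`read_cq_table`.

    Finite Cq values round-trip bit-exactly (shortest-repr float
    formatting); missing wells are written as ``Undetermined``.
    """
    wells = table.wells.drop(columns=["group"]).copy()
    wells["cq"] = wells["cq"].map(lambda v: UNDETERMINED if pd.isna(v) else repr(float(v)))
    wells.to_csv(cq_path, sep="\t", index=False)
    table.samples.to_csv(sample_path, sep="\t", index=False)
    table.assays.to_csv(assay_path, sep="\t", index=False)


def impute_cq_ceiling(table: CqTable, ceiling: float = DEFAULT_CEILING) -> CqTable:
    """Cap Cq values at the detection ceiling.

    Values above ``ceiling`` and missing (undetermined) wells are both set
    to ``ceiling`` — an undetermined well means the signal never crossed
    threshold, i.e. expression at or below the detection limit.  Returns a
    new table; the input is not mutated.
    """
    if ceiling <= 0:
        raise DataError("ceiling must be positive")
    wells = table.wells.copy()
    n_over = int((wells["cq"] > ceiling).sum())
    n_missing = int(wells["cq"].isna().sum())
    if n_over or n_missing:
        log.info("ceiling imputation: %d wells > %.6g, %d undetermined wells set to %.6g",
                 n_over, ceiling, n_missing, ceiling)
    wells["cq"] = wells["cq"].clip(upper=ceiling).fillna(ceiling)
    return replace(table, wells=wells)


def collapse_replicates(table: CqTable) -> dict[str, CollapsedCqMatrix]:
    """Average technical replicates into one genes x samples matrix per card.

    For every (gene, card, sample) the output is the arithmetic mean of
    that card's replicate wells (equivalently, the geometric mean on the
    expression scale).  Genes lacking wells on a card for one or more
    samples are dropped from that card's matrix with a warning.  Ceiling
    imputation must already have been applied (no missing Cq).
    """
    if table.wells["cq"].isna().any():
        raise DataError("collapse requires imputed Cq values (apply impute_cq_ceiling first)")
    group_of = table.group_of()
    subgroup_of = table.subgroup_of()
    out: dict[str, CollapsedCqMatrix] = {}
    sample_order = list(table.samples["sample_id"])
    for card, sub in table.wells.groupby("card", sort=True):
        mat = sub.pivot_table(index="assay_id", columns="sample_id", values="cq",
                              aggfunc="mean")
        cols = [s for s in sample_order if s in mat.columns]
        mat = mat[cols]
        incomplete = mat.index[mat.isna().any(axis=1)]
        if len(incomplete):
            log.warning("card %s: dropping %d gene(s) without wells for every sample: %s",
                        card, len(incomplete), list(incomplete))
            mat = mat.drop(index=incomplete)
        # deterministic gene order regardless of input row order
        mat = mat.sort_index()
        out[str(card)] = CollapsedCqMatrix(
            values=mat,
            card=str(card),
            groups=group_of.loc[cols],
            subgroups=subgroup_of.loc[cols],
        )
    return out


def to_log2_expression(matrix: CollapsedCqMatrix) -> pd.DataFrame:
    """Log2 relative expression: ``y = -Cq`` (the log of ``2**-Cq``)."""
    return -matrix.values
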