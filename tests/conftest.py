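import numpy as np
import pandas as pd
import pytest

from ecref.cq import CollapsedCqMatrix, CqTable
from ecref.simulate import paper_like_preset


def make_cq_table(records, samples=None, assays=None) -> CqTable:
    """Build a CqTable from (sample_id, group, card, assay_id, well, cq) tuples."""
    wells = pd.DataFrame(records, columns=["sample_id", "group", "card",
                                           "assay_id", "well", "cq"])
    if samples is None:
        samples = (wells[["sample_id", "group"]].drop_duplicates()
                   .assign(subgroup=lambda d: d["sample_id"]))
    if assays is None:
        assays = (wells.groupby(["assay_id", "card"]).size().rename("n_replicates")
                  .reset_index().assign(rna_class="miRNA", chrom_location=""))
        assays = assays[["assay_id", "rna_class", "chrom_location", "card", "n_replicates"]]
    return CqTable(wells=wells, samples=samples, assays=assays)


def make_matrix(values, groups, card="A", subgroups=None) -> CollapsedCqMatrix:
    """Genes x samples matrix with aligned group labels."""
    frame = pd.DataFrame(values)
    groups = pd.Series(list(groups), index=frame.columns)
    if subgroups is None:
        subgroups = pd.Series(list(frame.columns), index=frame.columns)
    else:
        subgroups = pd.Series(list(subgroups), index=frame.columns)
    return CollapsedCqMatrix(values=frame, card=card, groups=groups, subgroups=subgroups)


@pytest.fixture(scope="session")
def preset_seed1():
    return paper_like_preset(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
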