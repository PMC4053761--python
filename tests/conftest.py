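import numpy as np
import pytest

from h3k4spread.genome_io import (
    GeneAnnotation,
    GeneModel,
    GenomicInterval,
    TagCollection,
)
from h3k4spread.synthetic import SimulationParams, SyntheticDataset


def make_tags(
    positions,
    strands=None,
    chrom="chr1",
    fragment_extension=150,
    sample_id="test",
    library_size=None,
):
    """TagCollection from plain lists (single chromosome)."""
    positions = np.asarray(positions, dtype=np.int64)
    if strands is None:
        strands = np.ones(len(positions), dtype=np.int8)
    else:
        strands = np.asarray(
            [1 if s in (1, "+") else -1 for s in strands], dtype=np.int8
        )
    return TagCollection(
        sample_id,
        {chrom: (positions, strands)},
        fragment_extension=fragment_extension,
        library_size=library_size,
    )


def make_gene(gene_id="g1", chrom="chr1", start=10_000, end=20_000, strand="+"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


@pytest.fixture
def toy_annotation():
    return GeneAnnotation(
        [
            make_gene("gA", start=10_000, end=20_000, strand="+"),
            make_gene("gB", start=40_000, end=55_000, strand="-"),
            make_gene("gC", chrom="chr2", start=5_000, end=30_000, strand="+"),
        ]
    )


@pytest.fixture(scope="session")
def shift_dataset():
    """Default-scale synthetic dataset (control spread 0.1, knockdown 0.4)."""
    return SyntheticDataset.generate(SimulationParams(seed=0))


@pytest.fixture(scope="session")
def shift_si_tables(shift_dataset):
    """H3K4me3 spreading-index tables for both conditions of shift_dataset."""
    from h3k4spread.genome_io import MarkKind
    from h3k4spread.spreading import spreading_table

    mark = MarkKind.from_name("H3K4me3")
    out = {}
    for cond in ("control", "knockdown"):
        tags = shift_dataset.chip_tags(cond, "H3K4me3")
        out[cond], _ = spreading_table(
            tags, shift_dataset.annotation, mark, condition=cond
        )
    return out
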