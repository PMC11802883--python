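import numpy as np
import pandas as pd
import pytest

from repliid.barcode_io import BarcodeMap, ReadStructure, SampleCounts, SampleMeta

ANCHOR = "GATTACAGATT"


@pytest.fixture
def tiny_map() -> BarcodeMap:
    """Three well-separated 20-mers: two mutants and one wild type."""
    return BarcodeMap(
        pd.DataFrame(
            {
                "barcode": [
                    "ACGTACGTACGTACGTACGT",
                    "TTTTCCCCGGGGAAAATTTT",
                    "GACTGACTGACTGACTGACT",
                ],
                "strain_id": ["m1", "m2", "w1"],
                "gene": ["GENE1", "GENE2", "WT"],
                "strain_class": ["mutant", "mutant", "wildtype"],
            }
        )
    )


@pytest.fixture
def anchored_structure() -> ReadStructure:
    return ReadStructure(anchor=ANCHOR, barcode_length=20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240924)


def make_counts(
    counts: dict[str, int],
    role: str = "input",
    timepoint: int = 40,
    replicate: int = 1,
    sample_id: str | None = None,
    extra_unassigned: int = 0,
) -> SampleCounts:
    """Build a valid SampleCounts from a plain mapping."""
    assigned = sum(counts.values())
    return SampleCounts(
        sample=SampleMeta(sample_id or f"{role}_t{timepoint}_r{replicate}", role, timepoint, replicate),
        counts=dict(counts),
        total_reads=assigned + extra_unassigned,
        assigned_reads=assigned,
        unassigned_reads=extra_unassigned,
    )
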