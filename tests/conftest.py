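import logging

import numpy as np
import pandas as pd
import pytest

from microresilience import (
    Arm,
    GenusCountTable,
    SampleRecord,
    SimulationParams,
    Timepoint,
    generate_study,
)

logging.getLogger("microresilience").setLevel(logging.ERROR)


@pytest.fixture
def tiny_counts() -> GenusCountTable:
    """3 samples × 2 taxa with known totals."""
    df = pd.DataFrame(
        [[1, 2], [3, 4], [0, 5]],
        index=["s1", "s2", "s3"],
        columns=["gA", "gB"],
    )
    return GenusCountTable(df)


def make_subject_table(series: dict[str, dict[Timepoint, np.ndarray]], arm=Arm.PLACEBO):
    """Build a GenusCountTable from per-subject, per-visit count vectors."""
    rows, index, meta = [], [], {}
    n_taxa = None
    for subject, visits in series.items():
        for tp, counts in visits.items():
            counts = np.asarray(counts)
            n_taxa = len(counts)
            sid = f"{subject}_{tp.name}"
            rows.append(counts)
            index.append(sid)
            meta[sid] = SampleRecord(sid, subject, arm, tp)
    df = pd.DataFrame(rows, index=index, columns=[f"g{i}" for i in range(n_taxa)])
    return GenusCountTable(df, meta)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared by read-only tests."""
    return generate_study(SimulationParams(), seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
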