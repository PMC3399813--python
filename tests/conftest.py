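import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fastseqs as fs
from fastseqs import simulator

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PRIMER = "GGTGAAACCCCGTCTCTACG"


@pytest.fixture(scope="session")
def primer() -> str:
    return PRIMER


@pytest.fixture(scope="session")
def small_panel() -> fs.PositionPanel:
    """300-locus panel with reference tags at least 5 mismatches apart."""
    panel = fs.build_reference_panel(300, seed=3)
    return simulator.attach_reference_tags(panel, PRIMER, seed=3,
                                           min_pairwise_mm=5)


@pytest.fixture(scope="session")
def euploid_group(small_panel) -> pd.DataFrame:
    """Eight euploid count columns on the small panel."""
    specs = [fs.SampleSpec(f"s{i}", depth=200_000, seed=40 + i)
             for i in range(8)]
    return fs.simulate_count_table(small_panel, specs)


def toy_panel(records: list[tuple], weights=None) -> fs.PositionPanel:
    """Hand-built panel from (chrom, pos, strand, subfamily, frag_len[, tag])."""
    cols = ["chrom", "pos", "strand", "subfamily", "frag_len", "ref_tag"]
    df = pd.DataFrame([dict(zip(cols, r)) for r in records])
    if "ref_tag" in df and df["ref_tag"].isna().all():
        df = df.drop(columns="ref_tag")
    counts = df["chrom"].value_counts()
    w = pd.Series(weights) if weights is not None else counts / counts.sum()
    return fs.PositionPanel(records=df, chrom_weights=w)
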