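"""Plain-text table I/O shared across the pipeline stages.

Count matrices are TSVs with three position-identity columns (chrom, pos,
strand) followed by one column per sample; density curves and exclusion lists
are simple two/three-column TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import DensityCurve
from .simulator import POSITION_INDEX


def write_matrix(table: pd.DataFrame, path: str | Path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(POSITION_INDEX)


def write_positions(index: pd.MultiIndex, path: str | Path) -> None:
    index.to_frame(index=False).to_csv(path, sep="\t", index=False)


def write_density(curve: DensityCurve, path: str | Path) -> None:
    pd.DataFrame({"log_count": curve.grid, "density": curve.density}).to_csv(
        path, sep="\t", index=False
    )


def write_zscores(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
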