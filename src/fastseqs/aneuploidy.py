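"""Per-chromosome z-scores, aneuploidy calls and trisomic-fraction estimates.

A chromosome gain in a fraction ``f`` of a sample's DNA raises that
chromosome's expected tag share by ``f/2`` (one extra copy out of two).
Against a reference group of known-euploid samples, a sample's normalized
chromosome total ``chrN_i`` is standardized as

    z_i = (chrN_i - mu_chrN) / sd_chrN

with mu/sd the reference mean and sample (n-1) standard deviation. Samples
with z > 3.0 are called chromosomal gains (z < -3.0 losses); members of their
own reference group can never exceed |z| = (n-1)/sqrt(n) < 3 for n <= 10, so
euploid reference sets are structurally safe from self-flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import PositionPanel

DEFAULT_EXCLUDED_CHROMS = frozenset({"chrX", "chrY"})


def chromosome_totals(
    values: pd.DataFrame,
    exclusions: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS,
) -> pd.DataFrame:
    """Sum a positions x samples matrix by chromosome (rows = chromosomes).

    Sex chromosomes are excluded by default; the assay's autosomal dosage
    signal is what aneuploidy calling uses.
    """
    chroms = values.index.get_level_values("chrom")
    keep = ~chroms.isin(exclusions)
    return values.loc[keep].groupby(
        values.index.get_level_values("chrom")[keep].astype(str)
    ).sum()


@dataclass
class ReferenceGroup:
    """Per-chromosome mean and SD of normalized totals in euploid references."""

    mu: pd.Series
    sd: pd.Series
    n_ref: int
    sample_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_ref < 2:
            raise ValueError("reference group needs >= 2 samples")
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0].tolist()
            raise ValueError(f"zero reference SD on {bad}; group is degenerate")


def fit_reference(totals: pd.DataFrame, ref_sample_ids: Sequence[str]) -> ReferenceGroup:
    """Mean and sample SD (n-1) of chromosome totals over the reference samples."""
    missing = [s for s in ref_sample_ids if s not in totals.columns]
    if missing:
        raise KeyError(f"reference samples not in table: {missing}")
    if len(ref_sample_ids) < 2:
        raise ValueError("reference group needs >= 2 samples")
    ref = totals[list(ref_sample_ids)]
    return ReferenceGroup(mu=ref.mean(axis=1), sd=ref.std(axis=1, ddof=1),
                          n_ref=len(ref_sample_ids),
                          sample_ids=tuple(ref_sample_ids))


def zscore(
    totals: pd.DataFrame,
    ref: ReferenceGroup,
    cutoff: float = 3.0,
) -> pd.DataFrame:
    """Standardize every sample's chromosome totals against the reference.

    Returns a tidy frame (sample, chrom, total, z, call) where call is
    'aneuploid-gain' iff z > cutoff, 'aneuploid-loss' iff z < -cutoff and
    'euploid' otherwise (the cutoff itself is euploid).
    """
    unknown = totals.index.difference(ref.mu.index)
    if len(unknown):
        raise KeyError(f"chromosomes absent from reference: {list(unknown)}")
    rows = []
    for sample in totals.columns:
        t = totals[sample]
        z = (t - ref.mu) / ref.sd
        call = np.where(z > cutoff, "aneuploid-gain",
                        np.where(z < -cutoff, "aneuploid-loss", "euploid"))
        rows.append(pd.DataFrame({
            "sample": sample, "chrom": totals.index,
            "total": t.to_numpy(), "z": z.to_numpy(), "call": call,
            "cutoff": cutoff,
        }))
    return pd.concat(rows, ignore_index=True)


def zscore_loo(totals: pd.DataFrame, ref_sample_ids: Sequence[str],
               cutoff: float = 3.0) -> pd.DataFrame:
    """Leave-one-out variant: each reference member scored against the others.

    Off by default in the pipeline; the standard (leave-in) scoring matches
    the reproducibility experiments where plotted samples belong to their own
    reference group.
    """
    frames = []
    for sample in totals.columns:
        ids = [s for s in ref_sample_ids if s != sample]
        ref = fit_reference(totals, ids)
        frames.append(zscore(totals[[sample]], ref, cutoff))
    return pd.concat(frames, ignore_index=True)


def estimate_trisomic_fraction(
    totals: pd.DataFrame, ref: ReferenceGroup, chrom: str
) -> pd.Series:
    """Estimated trisomic DNA fraction f per sample from the 1 + f/2 scaling.

    f_hat = 2 (chrN_i / mu_chrN - 1), clipped to [-2, 2]. The observed extra
    chromosome fraction itself is f_hat / 2.
    """
    mu = ref.mu[chrom]
    if mu <= 0:
        raise ValueError(f"non-positive reference mean for {chrom}")
    f_hat = 2.0 * (totals.loc[chrom] / mu - 1.0)
    return f_hat.clip(-2.0, 2.0)


def subfamily_summary(table: pd.DataFrame, panel: PositionPanel) -> pd.DataFrame:
    """Observed vs panel-predicted per-chromosome position shares by subfamily.

    For each sample, a position is *observed* for a subfamily/chromosome if it
    has a nonzero count. Per subfamily, the mean observed percentage of
    positions per chromosome (across samples) is compared with the panel's
    predicted percentage by a paired two-tailed t-test across chromosomes.
    Identical observed and predicted shares (zero differences everywhere)
    report p = 1 by convention.

    Returns one row per (subfamily, chrom) with observed/predicted percentages
    and the subfamily-level p-value repeated on each row.
    """
    rec = panel.records.set_index(panel.position_index)
    sub = rec["subfamily"]
    chrom = rec["chrom"]
    missing = table.index.difference(rec.index)
    if len(missing):
        raise KeyError("table contains positions absent from the panel")

    plain = panel.records[["subfamily", "chrom"]]
    pred = (
        plain.groupby(["subfamily", "chrom"]).size()
        / plain.groupby("subfamily").size()
    ) * 100.0

    present = table > 0
    obs_frames = []
    for sample in table.columns:
        ident = table.index[present[sample]]
        counts = pd.crosstab(sub.loc[ident].to_numpy(),
                             chrom.loc[ident].to_numpy(),
                             rownames=["subfamily"], colnames=["chrom"])
        share = counts.div(counts.sum(axis=1), axis=0) * 100.0
        obs_frames.append(share.stack())
    obs = pd.concat(obs_frames, axis=1).mean(axis=1)
    obs.index.names = ["subfamily", "chrom"]

    out = pd.DataFrame({"observed_pct": obs, "predicted_pct": pred}).fillna(0.0)
    pvals = {}
    for fam, grp in out.groupby(level="subfamily"):
        diff = grp["observed_pct"] - grp["predicted_pct"]
        if np.allclose(diff, 0.0):
            pvals[fam] = 1.0
        else:
            pvals[fam] = float(
                stats.ttest_rel(grp["observed_pct"], grp["predicted_pct"]).pvalue
            )
    out["p_value"] = [pvals[f] for f in out.index.get_level_values("subfamily")]
    return out.reset_index()
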