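"""Synthetic data generation for repeat-amplicon aneuploidy screening.

The assay amplifies a few tens of thousands of dispersed LINE-1 (L1) loci with a
single primer pair and counts 37-base sequence tags per locus ("position").
This module fabricates the three layers of that data:

* a *position panel* — the reference set of amplifiable loci, with a bimodal
  amplicon-length mixture (peaks at 124 and 142 bp) and seven L1 subfamily
  labels, distributed over chr1..chr22, chrX, chrY;
* *tag-count tables* — negative-binomial per-position counts whose means
  combine a reproducible per-position amplification efficiency (lognormal,
  drawn once with the panel — the across-position spread real amplicon data
  shows within each size mode), preferential amplification of the
  small-fragment mode, and optional trisomy admixture (a fraction ``f`` of
  trisomic DNA multiplies the affected chromosome's expected counts by
  ``1 + f/2``);
* *reads* — 37-base FASTQ tags carrying primer-terminal bases, with optional
  per-template unique identifiers (UIDs) and configurable base-quality dropout.

All randomness flows from one integer seed per sample through a counter-based
(Philox) bit generator, so adding samples never perturbs earlier ones.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]

#: Approximate chromosome lengths (bp) used only to draw plausible coordinates.
CHROM_LENGTHS = {
    "chr1": 249_000_000, "chr2": 243_000_000, "chr3": 198_000_000,
    "chr4": 191_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
    "chr7": 159_000_000, "chr8": 146_000_000, "chr9": 141_000_000,
    "chr10": 134_000_000, "chr11": 135_000_000, "chr12": 134_000_000,
    "chr13": 115_000_000, "chr14": 107_000_000, "chr15": 103_000_000,
    "chr16": 90_000_000, "chr17": 81_000_000, "chr18": 78_000_000,
    "chr19": 59_000_000, "chr20": 63_000_000, "chr21": 48_000_000,
    "chr22": 51_000_000, "chrX": 155_000_000, "chrY": 59_000_000,
}

#: Seven L1 subfamily labels with default panel proportions (youngest first).
DEFAULT_SUBFAMILIES = {
    "L1PA2": 0.28, "L1PA3": 0.22, "L1PA4": 0.16, "L1PA5": 0.12,
    "L1PA6": 0.10, "L1PA7": 0.07, "L1PA8": 0.05,
}

#: Default two-component amplicon-length mixture: (mean, sd, weight) per mode.
DEFAULT_FRAG_LEN_MIX = ((124.0, 4.0, 0.5), (142.0, 4.0, 0.5))

#: Default SD (natural-log scale) of the per-position amplification
#: efficiency. Keeps the log-count density clearly bimodal (mode separation
#: log 2 ~ 0.69 for the default size bias) while giving each size mode the
#: across-position spread that lets quantile normalization track copy-number
#: shifts smoothly.
DEFAULT_EFFICIENCY_LOG_SD = 0.25

TAG_LENGTH = 37

POSITION_INDEX = ["chrom", "pos", "strand"]


def default_chrom_weights() -> pd.Series:
    """Per-chromosome expected position proportions.

    Derived from a bundled synthetic table of per-chromosome L1 position
    counts (roughly chromosome-length proportional with AT-rich enrichment);
    see ``fastseqs/data/l1_positions_by_chrom.synthetic.tsv``.
    """
    with resources.files("fastseqs.data").joinpath(
        "l1_positions_by_chrom.synthetic.tsv"
    ).open() as fh:
        tab = pd.read_csv(fh, sep="\t", comment="#")
    w = tab.set_index("chrom")["n_positions"].astype(float)
    return (w / w.sum()).reindex(CHROMOSOMES)


@dataclass(frozen=True)
class MixtureSpec:
    """Trisomy admixture ground truth: fraction ``f`` of trisomic DNA."""

    trisomic_chrom: str
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"admixture fraction f={self.f} outside [0, 1]")
        if self.trisomic_chrom not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {self.trisomic_chrom!r}")

    @property
    def copy_factor(self) -> float:
        """Expected count multiplier on the trisomic chromosome, ``1 + f/2``."""
        return 1.0 + self.f / 2.0


@dataclass(frozen=True)
class SampleSpec:
    """Simulation parameters for one sample.

    depth
        Expected total tag count over all panel positions.
    dispersion
        Negative-binomial size parameter r; variance = mu + mu^2/r.
    size_bias
        Amplification advantage of the small-fragment mode (>= 1).
    mixture
        Optional trisomy admixture.
    seed
        Integer seed; all of this sample's randomness derives from it.
    """

    sample_id: str
    depth: float
    dispersion: float = 20.0
    size_bias: float = 2.0
    mixture: MixtureSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.size_bias < 1:
            raise ValueError("size_bias must be >= 1")


@dataclass
class PositionPanel:
    """Reference set of amplifiable loci.

    ``records`` is a DataFrame with columns chrom, pos (1-based), strand,
    subfamily, frag_len, efficiency (reproducible per-position amplification
    factor) and, once :func:`attach_reference_tags` has run, ref_tag (the
    37-mer a perfect read from that locus would show).
    """

    records: pd.DataFrame
    chrom_weights: pd.Series

    def __post_init__(self) -> None:
        dup = self.records.duplicated(subset=POSITION_INDEX)
        if dup.any():
            raise ValueError("position identities (chrom,pos,strand) must be unique")
        if (self.records["pos"] < 1).any():
            raise ValueError("pos must be >= 1")
        if (self.records["frag_len"] <= 0).any():
            raise ValueError("frag_len must be > 0")
        if abs(self.chrom_weights.sum() - 1.0) > 1e-9:
            raise ValueError("chrom_weights must sum to 1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def position_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.records[POSITION_INDEX])

    def small_mode_mask(self, peaks: tuple[float, float] = (124.0, 142.0)) -> np.ndarray:
        """True where a locus belongs to the small-fragment mode (nearest peak)."""
        fl = self.records["frag_len"].to_numpy(float)
        return np.abs(fl - peaks[0]) < np.abs(fl - peaks[1])

    # -- BED-like TSV round trip: chrom, start(0-based), end, name=subfamily,
    #    score=frag_len, strand [, ref_tag] -----------------------------------
    def to_bed(self, path: str | Path) -> None:
        out = pd.DataFrame({
            "chrom": self.records["chrom"],
            "start": self.records["pos"] - 1,
            "end": self.records["pos"] - 1 + self.records["frag_len"],
            "name": self.records["subfamily"],
            "score": self.records["frag_len"],
            "strand": self.records["strand"],
            "efficiency": self.records.get(
                "efficiency", pd.Series(1.0, index=self.records.index)
            ),
        })
        if "ref_tag" in self.records:
            out["ref_tag"] = self.records["ref_tag"]
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "PositionPanel":
        names = ["chrom", "start", "end", "name", "score", "strand",
                 "efficiency", "ref_tag"]
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
        raw.columns = names[: raw.shape[1]]
        rec = pd.DataFrame({
            "chrom": raw["chrom"],
            "pos": raw["start"] + 1,
            "strand": raw["strand"],
            "subfamily": raw["name"],
            "frag_len": raw["score"].astype(int),
            "efficiency": raw["efficiency"].astype(float)
            if "efficiency" in raw else 1.0,
        })
        if "ref_tag" in raw:
            rec["ref_tag"] = raw["ref_tag"]
        counts = rec["chrom"].value_counts()
        weights = (counts / counts.sum()).reindex(
            [c for c in CHROMOSOMES if c in counts.index]
        )
        return cls(records=rec.reset_index(drop=True), chrom_weights=weights)


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    """Counter-based generator: one key per (seed, stream) pair."""
    return np.random.Generator(np.random.Philox(key=(np.uint64(seed) << np.uint64(16)) + np.uint64(stream)))


def build_reference_panel(
    n_positions: int,
    chrom_weights: pd.Series | dict | None = None,
    frag_len_mix: Sequence[tuple[float, float, float]] = DEFAULT_FRAG_LEN_MIX,
    seed: int = 0,
    subfamilies: dict[str, float] | None = None,
    efficiency_log_sd: float = DEFAULT_EFFICIENCY_LOG_SD,
) -> PositionPanel:
    """Draw a synthetic position panel.

    Chromosomes are drawn from ``chrom_weights`` (default: the bundled
    L1-position table), coordinates uniformly within each chromosome (unique
    per identity), fragment lengths from the two-component normal mixture,
    subfamily labels from the configured proportions, and per-position
    amplification efficiencies from a lognormal with the given log-scale SD
    (0 disables heterogeneity).
    """
    if n_positions <= 0:
        raise ValueError("n_positions must be > 0")
    if chrom_weights is None:
        chrom_weights = default_chrom_weights()
    chrom_weights = pd.Series(chrom_weights, dtype=float)
    if (chrom_weights < 0).any():
        raise ValueError("chrom_weights must be non-negative")
    if abs(chrom_weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"chrom_weights sum to {chrom_weights.sum()}, not 1")
    subfamilies = dict(subfamilies or DEFAULT_SUBFAMILIES)

    rng = _rng(seed)
    chroms = rng.choice(chrom_weights.index.to_numpy(), size=n_positions,
                        p=chrom_weights.to_numpy())
    # unique coordinates per chromosome; collision probability is tiny, redraw
    pos = np.empty(n_positions, dtype=np.int64)
    for c in np.unique(chroms):
        m = chroms == c
        hi = CHROM_LENGTHS.get(str(c), 100_000_000)
        draws = rng.integers(1, hi, size=m.sum())
        while len(np.unique(draws)) < len(draws):
            _, first = np.unique(draws, return_index=True)
            dupmask = np.ones(len(draws), bool)
            dupmask[first] = False
            draws[dupmask] = rng.integers(1, hi, size=dupmask.sum())
        pos[m] = draws
    strand = rng.choice(np.array(["+", "-"]), size=n_positions)
    sub_labels = np.array(list(subfamilies))
    sub_p = np.array(list(subfamilies.values()), float)
    sub_p /= sub_p.sum()
    subfam = rng.choice(sub_labels, size=n_positions, p=sub_p)

    means, sds, wts = (np.array(x, float) for x in zip(*frag_len_mix))
    wts = wts / wts.sum()
    comp = rng.choice(len(means), size=n_positions, p=wts)
    frag = np.maximum(np.rint(rng.normal(means[comp], sds[comp])), 50).astype(int)

    eff = (rng.lognormal(0.0, efficiency_log_sd, n_positions)
           if efficiency_log_sd > 0 else np.ones(n_positions))

    rec = pd.DataFrame({
        "chrom": chroms, "pos": pos, "strand": strand,
        "subfamily": subfam, "frag_len": frag, "efficiency": eff,
    })
    return PositionPanel(records=rec, chrom_weights=chrom_weights)


def expected_counts(panel: PositionPanel, spec: SampleSpec) -> np.ndarray:
    """Per-position expected counts (sums exactly to ``spec.depth``)."""
    w = np.where(panel.small_mode_mask(), spec.size_bias, 1.0)
    if "efficiency" in panel.records:
        w = w * panel.records["efficiency"].to_numpy(float)
    if spec.mixture is not None:
        tri = spec.mixture.trisomic_chrom
        on_tri = (panel.records["chrom"] == tri).to_numpy()
        if not on_tri.any():
            raise ValueError(f"trisomic chromosome {tri!r} has no panel positions")
        w = w * np.where(on_tri, spec.mixture.copy_factor, 1.0)
    return spec.depth * w / w.sum()


def simulate_counts(panel: PositionPanel, spec: SampleSpec) -> pd.Series:
    """One sample's per-position tag counts.

    Counts are negative binomial with mean proportional to the size-bias
    weight times the copy-number factor (``1 + f/2`` on the trisomic
    chromosome) and dispersion ``r`` such that var = mu + mu^2/r.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    mu = expected_counts(panel, spec)
    rng = _rng(spec.seed, stream=1)
    r = spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.Series(counts, index=panel.position_index, name=spec.sample_id)


def simulate_count_table(panel: PositionPanel, specs: Iterable[SampleSpec]) -> pd.DataFrame:
    """Tag-count table (positions x samples) for a group of samples."""
    cols = [simulate_counts(panel, s) for s in specs]
    return pd.concat(cols, axis=1)


def calibrate_dispersion(
    panel: PositionPanel,
    depth: float,
    chrom: str,
    target_rel_sd: float,
    size_bias: float = 2.0,
    apply_left_tail: bool = True,
) -> float:
    """Dispersion r giving a chromosome-total relative SD of ``target_rel_sd``.

    For a sum T of independent NB(mu_i, r) counts with total M = sum(mu_i)
    and S2 = sum(mu_i^2), relvar(T) = 1/M + S2/(r M^2), so
    r = S2 / (t^2 M^2 - M). The sums run over the positions expected to
    survive left-tail exclusion, predicted by applying the density-valley
    cutoff to the noiseless log-mean distribution.

    Raises ValueError when the Poisson floor 1/sqrt(M) already exceeds the
    target (no dispersion can reach it at this depth).
    """
    from . import normalize  # circularity-free; normalize has no simulator dep

    spec = SampleSpec("calib", depth=depth, size_bias=size_bias, seed=0)
    mu = expected_counts(panel, spec)
    keep = np.ones(len(mu), bool)
    if apply_left_tail:
        curve = normalize.estimate_log_density(mu)
        cutoff = normalize.find_left_tail_cutoff(curve)
        if cutoff is not None:
            keep = np.log(mu) > cutoff
    on_chrom = (panel.records["chrom"] == chrom).to_numpy()
    sel = keep & on_chrom
    if not sel.any():
        raise ValueError(f"no retained positions on {chrom}")
    m_tot = mu[sel].sum()
    s2 = (mu[sel] ** 2).sum()
    floor = 1.0 / np.sqrt(m_tot)
    if target_rel_sd <= floor:
        raise ValueError(
            f"target relative SD {target_rel_sd} below Poisson floor "
            f"{floor:.2e} at depth {depth:g}; increase depth"
        )
    return float(s2 / ((target_rel_sd * m_tot) ** 2 - m_tot))


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def attach_reference_tags(
    panel: PositionPanel,
    fwd_primer: str,
    seed: int = 0,
    min_terminal: int = 3,
    min_pairwise_mm: int = 0,
) -> PositionPanel:
    """Assign each locus its reference 37-mer.

    The tag is the last ``min_terminal`` bases of the forward primer followed
    by locus-specific random sequence. With ``min_pairwise_mm > 0`` the
    variable parts are redrawn until every pair differs at at least that many
    positions (O(n^2); intended for small panels in tests).
    """
    rng = _rng(seed, stream=2)
    n = len(panel)
    var_len = TAG_LENGTH - min_terminal
    prefix = fwd_primer[-min_terminal:] if min_terminal else ""

    def draw() -> np.ndarray:
        return rng.integers(0, 4, size=(n, var_len))

    codes = draw()
    if min_pairwise_mm > 0:
        for _ in range(100):
            dist = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
            np.fill_diagonal(dist, var_len)
            bad = np.unique(np.where(dist < min_pairwise_mm)[0])
            if len(bad) == 0:
                break
            codes[bad] = rng.integers(0, 4, size=(len(bad), var_len))
        else:
            raise RuntimeError("could not satisfy min_pairwise_mm")
    tags = [prefix + "".join(_BASES[row]) for row in codes]
    if len(set(tags)) < n:
        raise RuntimeError("reference tag collision; use min_pairwise_mm or reseed")
    rec = panel.records.copy()
    rec["ref_tag"] = tags
    return PositionPanel(records=rec, chrom_weights=panel.chrom_weights)


@dataclass
class SimulatedRead:
    """One synthetic 37-base tag with its FASTQ annotations."""

    read_id: str
    seq: str
    qual: np.ndarray
    uid: str | None
    barcode: str | None
    chastity: bool = True
    true_position: tuple | None = None

    def to_fastq(self) -> str:
        desc = [f"CF:{'1' if self.chastity else '0'}"]
        if self.barcode is not None:
            desc.append(f"BC:{self.barcode}")
        if self.uid is not None:
            desc.append(f"UID:{self.uid}")
        q = "".join(chr(33 + int(x)) for x in self.qual)
        return f"@{self.read_id} {' '.join(desc)}\n{self.seq}\n+\n{q}\n"


def simulate_reads(
    panel: PositionPanel,
    spec: SampleSpec,
    uid_len: int = 0,
    error_rate: float = 0.0,
    reads_per_template: int = 1,
    q20_fail_frac: float = 0.05,
    barcode: str | None = None,
) -> Iterator[SimulatedRead]:
    """Yield 37-base reads for one sample.

    Per-position molecule counts come from :func:`simulate_counts`; with
    ``reads_per_template > 1`` those counts are template molecules, each
    assigned a distinct ``uid_len``-base UID and emitted that many times
    (a perfectly even PCR). Substitution errors hit each base independently
    at ``error_rate``; a ``q20_fail_frac`` fraction of bases gets a quality
    below 20. Deterministic given ``spec.seed``.
    """
    if uid_len < 0:
        raise ValueError("uid_len must be >= 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if "ref_tag" not in panel.records:
        raise ValueError("panel has no reference tags; run attach_reference_tags")
    counts = simulate_counts(panel, spec)
    rng = _rng(spec.seed, stream=3)
    recs = panel.records
    serial = 0
    for i in range(len(recs)):
        n_templates = int(counts.iloc[i])
        if n_templates == 0:
            continue
        ref = np.frombuffer(recs["ref_tag"].iloc[i].encode(), dtype="S1")
        ident = (recs["chrom"].iloc[i], int(recs["pos"].iloc[i]), recs["strand"].iloc[i])
        uids = None
        if uid_len:
            uids = ["".join(_BASES[rng.integers(0, 4, uid_len)]) for _ in range(n_templates)]
        for t in range(n_templates):
            for _ in range(reads_per_template):
                seq = ref.copy()
                if error_rate > 0:
                    hits = np.nonzero(rng.random(TAG_LENGTH) < error_rate)[0]
                    for h in hits:
                        cur = seq[h].decode()
                        alt = [b for b in "ACGT" if b != cur]
                        seq[h] = alt[rng.integers(0, 3)].encode()
                low = rng.random(TAG_LENGTH) < q20_fail_frac
                qual = np.where(low, rng.integers(2, 20, TAG_LENGTH),
                                rng.integers(30, 41, TAG_LENGTH))
                yield SimulatedRead(
                    read_id=f"{spec.sample_id}:{serial}",
                    seq=seq.tobytes().decode(),
                    qual=qual,
                    uid=uids[t] if uids else None,
                    barcode=barcode,
                    true_position=ident,
                )
                serial += 1


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> int:
    """Write reads as 4-line Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.to_fastq())
            n += 1
    return n
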