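"""End-to-end orchestration: simulate -> tag processing -> normalize -> call.

A single YAML config defines the panel, the samples (with any trisomy
admixtures), the processing thresholds and the reference group; the run
writes every stage output to the output directory and records a manifest
with a content hash per file, so identical config + seed reproduce identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, aneuploidy, io as fio, normalize, simulator, tagproc

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed for one reproducible end-to-end run."""

    n_positions: int = 2000
    depth: float = 50_000
    dispersion: float = 20.0
    size_bias: float = 2.0
    fwd_primer: str = "GGTGAAACCCCGTCTCTACG"
    samples: list[dict] = field(default_factory=list)
    reference_samples: list[str] = field(default_factory=list)
    q_min: int = 20
    max_mm: int = 1
    min_terminal: int = 3
    uid_len: int = 0
    error_rate: float = 0.0
    q20_fail_frac: float = 0.05
    cutoff: float = 3.0
    seed: int = 1
    read_level: bool = True

    def __post_init__(self) -> None:
        if not self.samples:
            raise ConfigError("no samples defined")
        ids = [s["sample_id"] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate sample ids")
        missing = [r for r in self.reference_samples if r not in ids]
        if missing:
            raise ConfigError(f"reference sample(s) not defined: {missing}")
        if len(self.reference_samples) < 2:
            raise ConfigError("need >= 2 reference samples")
        if self.uid_len not in (0, 16, 20):
            raise ConfigError("uid_len must be 0, 16 or 20")
        if not 0 <= self.q_min <= 60:
            raise ConfigError("q_min out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def sample_specs(self) -> list[simulator.SampleSpec]:
        specs = []
        for i, s in enumerate(self.samples):
            mixture = None
            if s.get("trisomic_chrom"):
                mixture = simulator.MixtureSpec(
                    trisomic_chrom=s["trisomic_chrom"], f=float(s.get("f", 0.0))
                )
            specs.append(simulator.SampleSpec(
                sample_id=s["sample_id"],
                depth=float(s.get("depth", self.depth)),
                dispersion=float(s.get("dispersion", self.dispersion)),
                size_bias=float(s.get("size_bias", self.size_bias)),
                mixture=mixture,
                seed=int(s.get("seed", self.seed * 1000 + i)),
            ))
        return specs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        files[name] = _sha256(path)

    # --- simulate ---------------------------------------------------------
    try:
        panel = simulator.build_reference_panel(config.n_positions,
                                                seed=config.seed)
        panel = simulator.attach_reference_tags(panel, config.fwd_primer,
                                                seed=config.seed)
        panel_path = outdir / "panel.bed"
        panel.to_bed(panel_path)
        record("panel", panel_path)
        specs = config.sample_specs()

        if config.read_level:
            columns = {}
            for spec in specs:
                reads = simulator.simulate_reads(
                    panel, spec, uid_len=config.uid_len,
                    error_rate=config.error_rate,
                    q20_fail_frac=config.q20_fail_frac,
                )
                fq = outdir / f"{spec.sample_id}.fastq"
                simulator.write_fastq(reads, fq)
                record(f"fastq/{spec.sample_id}", fq)
                counts, acct = tagproc.process_sample(
                    tagproc.read_fastq(fq), panel, config.fwd_primer,
                    q_min=config.q_min, max_mm=config.max_mm,
                    min_terminal=config.min_terminal, uid_len=config.uid_len,
                )
                logger.info("%s: %s", spec.sample_id, acct)
                columns[spec.sample_id] = counts
            table = pd.DataFrame(columns)
        else:
            table = simulator.simulate_count_table(panel, specs)
        counts_path = outdir / "counts.tsv"
        fio.write_matrix(table, counts_path)
        record("counts", counts_path)
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError("simulate+tagproc", exc) from exc

    # --- normalize --------------------------------------------------------
    try:
        result = normalize.normalize_group(table)
        norm_path = outdir / "normalized.tsv"
        fio.write_matrix(result.values, norm_path)
        record("normalized", norm_path)
        excl_path = outdir / "excluded_positions.tsv"
        fio.write_positions(result.excluded_positions, excl_path)
        record("excluded_positions", excl_path)
        if result.density is not None:
            dens_path = outdir / "density.tsv"
            fio.write_density(result.density, dens_path)
            record("density", dens_path)
    except Exception as exc:
        raise StageError("normalize", exc) from exc

    # --- call -------------------------------------------------------------
    try:
        totals = aneuploidy.chromosome_totals(result.values)
        ref = aneuploidy.fit_reference(totals, config.reference_samples)
        report = aneuploidy.zscore(totals, ref, cutoff=config.cutoff)
        z_path = outdir / "zscores.tsv"
        fio.write_zscores(report, z_path)
        record("zscores", z_path)
        summary = {
            "max_abs_z": float(report["z"].abs().max()),
            "calls": report[report["call"] != "euploid"][
                ["sample", "chrom", "z", "call"]
            ].to_dict("records"),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        record("summary", outdir / "summary.json")
    except Exception as exc:
        raise StageError("aneuploidy", exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.__dict__ | {"depth": float(config.depth)},
        "files": files,
        "outdir": str(outdir),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def make_figures(manifest: dict, outdir: str | Path | None = None) -> list[Path]:
    """Density, per-chromosome z-score, and expected-vs-observed plots.

    Each figure's numeric data is also written as TSV next to the image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(manifest["outdir"])
    outdir = Path(outdir) if outdir else run_dir
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("density", "zscores", "normalized"):
        if name not in manifest["files"]:
            raise StageError("figures", FileNotFoundError(name))
    made = []

    dens = pd.read_csv(run_dir / "density.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(dens["log_count"], dens["density"])
    ax.set_xlabel("log normalized tag count")
    ax.set_ylabel("density")
    fig.tight_layout()
    p = outdir / "fig_density.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    dens.to_csv(outdir / "fig_density.tsv", sep="\t", index=False)
    made.append(p)

    z = pd.read_csv(run_dir / "zscores.tsv", sep="\t")
    chroms = sorted(z["chrom"].unique(), key=lambda c: (len(c), c))
    xmap = {c: i for i, c in enumerate(chroms)}
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for sample, grp in z.groupby("sample"):
        ax.scatter([xmap[c] for c in grp["chrom"]], grp["z"], s=12, label=sample)
    cut = float(z["cutoff"].iloc[0])
    ax.axhline(cut, ls=":", c="k")
    ax.axhline(-cut, ls=":", c="k")
    ax.set_xticks(range(len(chroms)), chroms, rotation=90, fontsize=7)
    ax.set_ylabel("z-score")
    fig.tight_layout()
    p = outdir / "fig_zscores.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    z.to_csv(outdir / "fig_zscores.tsv", sep="\t", index=False)
    made.append(p)

    # expected vs observed extra-chromosome fraction for admixed samples
    cfg = manifest["config"]
    mix_rows = []
    norm = fio.read_matrix(run_dir / "normalized.tsv")
    totals = aneuploidy.chromosome_totals(norm)
    ref = aneuploidy.fit_reference(totals, cfg["reference_samples"])
    for s in cfg["samples"]:
        chrom = s.get("trisomic_chrom") or "chr21"
        f = float(s.get("f", 0.0)) if s.get("trisomic_chrom") else 0.0
        f_hat = aneuploidy.estimate_trisomic_fraction(totals, ref, chrom)
        mix_rows.append({
            "sample": s["sample_id"], "chrom": chrom,
            "expected_extra": f / 2.0,
            "observed_extra": float(f_hat[s["sample_id"]]) / 2.0,
        })
    mix = pd.DataFrame(mix_rows)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(mix["expected_extra"], mix["observed_extra"])
    lim = max(0.02, mix[["expected_extra", "observed_extra"]].to_numpy().max() * 1.1)
    ax.plot([0, lim], [0, lim], ls="--", c="gray")  # identity line
    ax.set_xlabel("expected extra fraction (f/2)")
    ax.set_ylabel("observed extra fraction")
    fig.tight_layout()
    p = outdir / "fig_mixture.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    mix.to_csv(outdir / "fig_mixture.tsv", sep="\t", index=False)
    made.append(p)
    return made
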