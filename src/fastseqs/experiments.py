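"""Canonical simulation experiments: reproducibility and admixture detection.

These functions wire the simulator, normalization and z-score stages into the
study designs the method is validated on:

* an eight-sample euploid reference group scored against itself (leave-in),
  whose |z| can never exceed (n-1)/sqrt(n) ~ 2.475 for n = 8;
* trisomy-21 admixture experiments at 4% and 8% in quadruplicate against a
  reference group whose chr21 relative SD is calibrated to 0.003;
* a six-sample mixing series (0, 0, 5, 5, 10, 25% trisomic DNA) at a chr21
  relative SD of 0.0015, correlating expected (f/2) and observed extra
  chromosome-21 fractions.

Study conditions (panel size 21,676; depths; dispersion r = 20 for the
reproducibility run; calibration targets) are fixed defaults of the designs.
Each sample's seed is derived from the experiment base seed and a fixed
per-sample role key through a SeedSequence, so replicates are independent
and the whole experiment is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import aneuploidy, normalize, simulator

PANEL_SIZE = 21_676
REPRO_DEPTH = 4_000_000
REPRO_DISPERSION = 20.0
ADMIX_DEPTH = 20_000_000
ADMIX_TARGET_REL_SD = 0.003
SERIES_DEPTH = 70_000_000
SERIES_TARGET_REL_SD = 0.0015

#: role keys for seed derivation (replicate keys follow the study layout)
_PANEL_KEY = 0
_REF_KEYS = tuple(range(101, 109))
_SERIES_REF_KEYS = tuple(range(201, 209))


def derive_seed(base_seed: int, role_key: int) -> int:
    """Stable per-sample seed below 2^31 from (experiment seed, role key)."""
    ss = np.random.SeedSequence([int(base_seed), int(role_key)])
    return int(ss.generate_state(1)[0] % (2**31))


def _build_panel(base_seed: int) -> simulator.PositionPanel:
    return simulator.build_reference_panel(
        PANEL_SIZE, seed=derive_seed(base_seed, _PANEL_KEY)
    )


def _normalized_totals(panel, specs) -> pd.DataFrame:
    table = simulator.simulate_count_table(panel, specs)
    result = normalize.normalize_group(table)
    return aneuploidy.chromosome_totals(result.values)


@dataclass
class EuploidResult:
    max_abs_z: float
    report: pd.DataFrame


def euploid_reference_experiment(
    seed: int = 1,
    n_samples: int = 8,
    depth: float = REPRO_DEPTH,
    dispersion: float = REPRO_DISPERSION,
) -> EuploidResult:
    """Leave-in z-scores of a euploid group against itself (all autosomes)."""
    panel = _build_panel(seed)
    specs = [
        simulator.SampleSpec(f"ref{i+1}", depth=depth, dispersion=dispersion,
                             seed=derive_seed(seed, _REF_KEYS[i]))
        for i in range(n_samples)
    ]
    totals = _normalized_totals(panel, specs)
    ref = aneuploidy.fit_reference(totals, [s.sample_id for s in specs])
    report = aneuploidy.zscore(totals, ref)
    return EuploidResult(max_abs_z=float(report["z"].abs().max()), report=report)


@dataclass
class AdmixtureResult:
    z_by_sample: pd.Series        # chr21 z per test sample
    calls: pd.Series              # call per test sample
    achieved_rel_sd: float
    dispersion: float


def admixture_experiment(
    fractions: dict[int, float],
    seed: int = 1,
    depth: float = ADMIX_DEPTH,
    target_rel_sd: float = ADMIX_TARGET_REL_SD,
    chrom: str = "chr21",
    cutoff: float = 3.0,
) -> AdmixtureResult:
    """Admixed test samples against a calibrated euploid reference.

    ``fractions`` maps a replicate role key (e.g. 11..14) to its trisomic
    DNA fraction f (0 for euploid controls). All samples are normalized
    jointly; z is computed against the eight references only.
    """
    panel = _build_panel(seed)
    r = simulator.calibrate_dispersion(panel, depth, chrom, target_rel_sd)
    refs = [
        simulator.SampleSpec(f"ref{i+1}", depth=depth, dispersion=r,
                             seed=derive_seed(seed, k))
        for i, k in enumerate(_REF_KEYS)
    ]
    tests = []
    for key, f in fractions.items():
        mixture = simulator.MixtureSpec(chrom, f) if f > 0 else None
        tests.append(simulator.SampleSpec(
            f"mix{key}", depth=depth, dispersion=r, mixture=mixture,
            seed=derive_seed(seed, key),
        ))
    totals = _normalized_totals(panel, refs + tests)
    ref = aneuploidy.fit_reference(totals, [s.sample_id for s in refs])
    report = aneuploidy.zscore(totals, ref, cutoff=cutoff)
    on_chrom = report[report["chrom"] == chrom].set_index("sample")
    test_ids = [s.sample_id for s in tests]
    return AdmixtureResult(
        z_by_sample=on_chrom.loc[test_ids, "z"],
        calls=on_chrom.loc[test_ids, "call"],
        achieved_rel_sd=float((ref.sd / ref.mu)[chrom]),
        dispersion=r,
    )


def detection_limit_scan(
    seed: int = 1,
    fractions: tuple[float, ...] = (0.0, 0.04, 0.08),
    replicate_keys: tuple[int, ...] = tuple(range(31, 43)),
    cutoff: float = 3.0,
) -> float | None:
    """Smallest nonzero f at which all replicates are called gains.

    Four replicates per fraction, one joint normalization; a fraction
    qualifies only if additionally no euploid (f = 0) replicate is called.
    Returns f, or None when no fraction qualifies.
    """
    n_rep = len(replicate_keys) // len(fractions)
    mapping = {
        key: fractions[i // n_rep] for i, key in enumerate(replicate_keys)
    }
    res = admixture_experiment(mapping, seed=seed, cutoff=cutoff)
    gains = res.calls == "aneuploid-gain"
    by_f: dict[float, list[bool]] = {}
    for key, f in mapping.items():
        by_f.setdefault(f, []).append(bool(gains[f"mix{key}"]))
    if any(by_f.get(0.0, [])):
        return None
    for f in sorted(f for f in by_f if f > 0):
        if all(by_f[f]):
            return f
    return None


@dataclass
class MixtureSeriesResult:
    expected_extra: np.ndarray
    observed_extra: np.ndarray
    pearson_r: float
    achieved_rel_sd: float


def mixture_series_experiment(
    seed: int = 7,
    fractions: tuple[float, ...] = (0.0, 0.0, 0.05, 0.05, 0.10, 0.25),
    depth: float = SERIES_DEPTH,
    target_rel_sd: float = SERIES_TARGET_REL_SD,
    chrom: str = "chr21",
) -> MixtureSeriesResult:
    """Expected vs observed extra-chr21 fraction over a mixing series."""
    panel = _build_panel(seed)
    r = simulator.calibrate_dispersion(panel, depth, chrom, target_rel_sd)
    refs = [
        simulator.SampleSpec(f"ref{i+1}", depth=depth, dispersion=r,
                             seed=derive_seed(seed, k))
        for i, k in enumerate(_SERIES_REF_KEYS)
    ]
    tests = []
    for j, f in enumerate(fractions):
        mixture = simulator.MixtureSpec(chrom, f) if f > 0 else None
        tests.append(simulator.SampleSpec(
            f"mix{j+1}", depth=depth, dispersion=r, mixture=mixture,
            seed=derive_seed(seed, 301 + j),
        ))
    totals = _normalized_totals(panel, refs + tests)
    ref = aneuploidy.fit_reference(totals, [s.sample_id for s in refs])
    f_hat = aneuploidy.estimate_trisomic_fraction(
        totals[[s.sample_id for s in tests]], ref, chrom
    )
    expected = np.asarray(fractions) / 2.0
    observed = f_hat.to_numpy() / 2.0
    r_p = float(stats.pearsonr(expected, observed).statistic)
    return MixtureSeriesResult(
        expected_extra=expected, observed_extra=observed, pearson_r=r_p,
        achieved_rel_sd=float((ref.sd / ref.mu)[chrom]),
    )
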