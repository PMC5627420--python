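"""Arm-level SCNA / LOH detection from windowed minor-allele-fraction curves.

High-quality germline heterozygous SNVs (present in every sample with
coverage above 20, in dbSNP, het with normal MAF >= 0.25) are summarized in
overlapping windows of 1000 SNVs stepping by 500.  At a diploid het site the
minor-allele fraction sits near 0.5 in every sample; under a one-copy loss
diluted by tumor purity rho it drops toward (1-rho)/(2-rho) in the tumor.
Comparing the tumor curve against the normal curve calls arm-level losses;
sites whose tumor MAF collapses below 0.10 are counted as LOH sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .variantio import Arm, site_maf, table_samples


@dataclass
class SiteFilterConfig:
    """High-quality germline-SNV criteria (all strict as documented)."""

    min_coverage: int = 20  # strictly greater-than, in every sample
    require_dbsnp: bool = True
    require_het_normal: bool = True
    min_normal_maf: float = 0.25  # at least

    def __post_init__(self) -> None:
        if self.min_coverage < 0:
            raise ConfigurationError("min_coverage must be >= 0")
        if not 0.0 <= self.min_normal_maf <= 0.5:
            raise ConfigurationError("min_normal_maf must be in [0, 0.5]")


@dataclass
class WindowConfig:
    window_size: int = 1000  # SNVs per window
    step: int = 500  # SNVs between window starts
    summary: str = "median"

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_size:
            raise ConfigurationError("require 0 < step <= window_size")
        if self.summary not in ("median", "mean"):
            raise ConfigurationError(f"unknown summary {self.summary!r}")


@dataclass
class ArmCallConfig:
    """Decision constants for calling a loss from tumor-vs-normal curves."""

    max_tumor_arm_maf: float = 0.40
    min_maf_drop: float = 0.05
    min_windows: int = 2
    loh_site_max_maf: float = 0.10

    def __post_init__(self) -> None:
        for name in ("max_tumor_arm_maf", "min_maf_drop", "loh_site_max_maf"):
            if not 0.0 <= getattr(self, name) <= 0.5:
                raise ConfigurationError(f"{name} must be in [0, 0.5]")
        if self.min_windows < 1:
            raise ConfigurationError("min_windows must be >= 1")


@dataclass
class ArmReport:
    """Windowed MAF summary and call status for one (arm, tumor) pair."""

    arm: str
    tumor_sample: str
    n_hq_sites: int
    windows: pd.DataFrame  # columns: index, normal_maf, tumor_maf
    status: str  # neutral | loss | insufficient_data
    n_loh_sites: int


def select_hq_sites(
    table: pd.DataFrame, normal_sample: str, config: SiteFilterConfig | None = None
) -> pd.DataFrame:
    """Apply the high-quality germline-SNV criteria, ordered by (chrom, pos).

    Coverage must exceed ``min_coverage`` in *every* sample of the table; the
    dbSNP, heterozygosity and MAF conditions apply to the normal sample.
    """
    config = config or SiteFilterConfig()
    samples = table_samples(table)
    if normal_sample not in samples:
        raise DataIntegrityError(f"normal sample {normal_sample!r} missing from sites table")
    keep = np.ones(len(table), dtype=bool)
    for sample in samples:
        keep &= table[f"depth_{sample}"].to_numpy() > config.min_coverage
    if config.require_dbsnp:
        keep &= table["is_dbsnp"].to_numpy(dtype=bool)
    if config.require_het_normal:
        keep &= (table[f"gt_{normal_sample}"] == "het").to_numpy()
    keep &= site_maf(table, normal_sample) >= config.min_normal_maf
    out = table.loc[keep]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def window_maf_curve(maf_values: np.ndarray, config: WindowConfig | None = None) -> np.ndarray:
    """Window summaries over position-sorted site MAFs.

    Windows are runs of ``window_size`` consecutive sites starting at
    multiples of ``step``; a trailing partial window is dropped.  Returns an
    empty array when there are fewer sites than one window.
    """
    config = config or WindowConfig()
    maf_values = np.asarray(maf_values, dtype=float)
    n = maf_values.size
    w, s = config.window_size, config.step
    if n < w:
        return np.zeros(0)
    n_windows = (n - w) // s + 1
    stat = np.median if config.summary == "median" else np.mean
    return np.array([stat(maf_values[i * s : i * s + w]) for i in range(n_windows)])


def call_arm_events(
    normal_curve: np.ndarray,
    tumor_curve: np.ndarray,
    config: ArmCallConfig | None = None,
) -> str:
    """Loss / neutral / insufficient_data from matched window curves.

    A loss requires enough windows, a suppressed tumor curve (median window
    summary below ``max_tumor_arm_maf``) and a drop of at least
    ``min_maf_drop`` relative to the normal curve.
    """
    config = config or ArmCallConfig()
    normal_curve = np.asarray(normal_curve, dtype=float)
    tumor_curve = np.asarray(tumor_curve, dtype=float)
    if normal_curve.shape != tumor_curve.shape:
        raise DataIntegrityError("normal and tumor curves must come from the same windows")
    if tumor_curve.size < config.min_windows:
        return "insufficient_data"
    tumor_level = float(np.median(tumor_curve))
    drop = float(np.median(normal_curve)) - tumor_level
    if tumor_level < config.max_tumor_arm_maf and drop >= config.min_maf_drop:
        return "loss"
    return "neutral"


def count_loh_sites(
    table_on_arm: pd.DataFrame, tumor_sample: str, config: ArmCallConfig | None = None
) -> int:
    """Number of het sites whose tumor MAF collapsed below the LOH cap."""
    config = config or ArmCallConfig()
    if len(table_on_arm) == 0:
        return 0
    return int((site_maf(table_on_arm, tumor_sample) < config.loh_site_max_maf).sum())


def sites_on_arm(table: pd.DataFrame, arm: Arm) -> pd.DataFrame:
    """Sites whose 1-based position falls in the arm's half-open interval."""
    pos = table["pos"].to_numpy()
    mask = (table["chrom"].astype(str) == arm.chrom).to_numpy()
    mask &= (arm.start <= pos - 1) & (pos - 1 < arm.end)
    return table.loc[mask].sort_values("pos", kind="mergesort").reset_index(drop=True)


def genome_scna_scan(
    table: pd.DataFrame,
    arms: Sequence[Arm],
    normal_sample: str,
    tumor_samples: Sequence[str],
    site_config: SiteFilterConfig | None = None,
    window_config: WindowConfig | None = None,
    arm_config: ArmCallConfig | None = None,
) -> list[ArmReport]:
    """One ArmReport per (arm, tumor): windowed curves, call status, LOH count."""
    site_config = site_config or SiteFilterConfig()
    window_config = window_config or WindowConfig()
    arm_config = arm_config or ArmCallConfig()
    hq = select_hq_sites(table, normal_sample, site_config)
    reports = []
    for arm in arms:
        on_arm = sites_on_arm(hq, arm)
        normal_maf = site_maf(on_arm, normal_sample)
        for tumor in tumor_samples:
            tumor_maf = site_maf(on_arm, tumor)
            normal_curve = window_maf_curve(normal_maf, window_config)
            tumor_curve = window_maf_curve(tumor_maf, window_config)
            status = call_arm_events(normal_curve, tumor_curve, arm_config)
            reports.append(
                ArmReport(
                    arm=arm.name,
                    tumor_sample=tumor,
                    n_hq_sites=len(on_arm),
                    windows=pd.DataFrame(
                        {
                            "index": np.arange(normal_curve.size),
                            "normal_maf": normal_curve,
                            "tumor_maf": tumor_curve,
                        }
                    ),
                    status=status,
                    n_loh_sites=count_loh_sites(on_arm, tumor, arm_config),
                )
            )
    return reports


def arm_report_table(reports: Sequence[ArmReport]) -> pd.DataFrame:
    """Flat summary table (one row per arm x tumor) for TSV output."""
    rows = [
        {
            "arm": r.arm,
            "tumor_sample": r.tumor_sample,
            "n_hq_sites": r.n_hq_sites,
            "n_windows": len(r.windows),
            "median_normal_maf": float(r.windows["normal_maf"].median()) if len(r.windows) else np.nan,
            "median_tumor_maf": float(r.windows["tumor_maf"].median()) if len(r.windows) else np.nan,
            "status": r.status,
            "n_loh_sites": r.n_loh_sites,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)
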