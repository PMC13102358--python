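"""Site- and window-level SNP filters.

Quality thresholds follow the GATK-style hard filters used by the study:
drop non-biallelic or repeat-masked sites, FS >= 60, MQ <= 40, QD < 6.
Population-specific filters: >= 15% missing genotypes, and 10-kbp windows
whose summed population depth exceeds 1.5x the mode (collapsed-paralog
proxy).  Demography preparation additionally removes genic SNPs and thins
to one SNP per 50 kbp.  Missing FS/MQ/QD annotations pass their rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import covers, merge_intervals
from .vcf_io import VcfRecord

#: record used for site filtering; alias of the VCF I/O record
SiteRecord = VcfRecord


@dataclass
class FilterConfig:
    fs_max: float = 60.0
    mq_min: float = 40.0
    qd_min: float = 6.0
    missing_max_fraction: float = 0.15
    depth_window_bp: int = 10_000
    depth_mode_multiplier: float = 1.5
    thin_bp: int = 50_000

    def __post_init__(self) -> None:
        for name in ("fs_max", "mq_min", "qd_min", "depth_window_bp",
                     "depth_mode_multiplier", "thin_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.missing_max_fraction < 1):
            raise ValueError("missing_max_fraction must be in (0, 1)")


def filter_site(
    record: SiteRecord,
    config: FilterConfig,
    repeat_mask: list[tuple[int, int]] | None = None,
) -> tuple[bool, str]:
    """(keep, reason) for one site; the reason names the first failing rule.

    ``repeat_mask``: sorted, disjoint 0-based half-open intervals for the
    record's chromosome.  Absent FS/MQ/QD values pass their rule.
    """
    if not record.is_biallelic_snp:
        return False, "not_biallelic_snp"
    if repeat_mask and covers(repeat_mask, record.position - 1):
        return False, "repeat_mask"
    if record.fs is not None and record.fs >= config.fs_max:
        return False, "FS"
    if record.mq is not None and record.mq <= config.mq_min:
        return False, "MQ"
    if record.qd is not None and record.qd < config.qd_min:
        return False, "QD"
    return True, "pass"


def missingness_filter(genotypes: np.ndarray, missing_max_fraction: float = 0.15) -> bool:
    """Keep iff the within-population missing fraction is below the threshold.

    ``genotypes``: (n_individuals, 2) allele array with -1 for missing; an
    individual counts as missing when either allele is absent.  Drop when
    missing fraction >= threshold.
    """
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    if n == 0:
        raise ValueError("population has zero individuals")
    missing = (genotypes < 0).any(axis=1).sum()
    return missing / n < missing_max_fraction


def binned_mode(values: np.ndarray) -> float:
    """Mode after rounding to the nearest integer; smallest modal value on ties."""
    rounded = np.rint(np.asarray(values, dtype=float)).astype(np.int64)
    counts = np.bincount(rounded - rounded.min())
    return float(np.argmax(counts) + rounded.min())


def depth_window_filter(
    window_sums: np.ndarray, depth_mode_multiplier: float = 1.5
) -> np.ndarray:
    """Boolean exclusion mask over consecutive fixed-size depth windows.

    A window is excluded iff its per-population depth sum exceeds
    multiplier x the binned mode of the window-sum distribution.  Windows at
    or below the mode are never excluded.
    """
    window_sums = np.asarray(window_sums, dtype=float)
    if window_sums.size == 0 or not (window_sums > 0).any():
        raise ValueError("degenerate depth distribution: all window sums are zero")
    if (window_sums < 0).any():
        raise ValueError("depth sums must be non-negative")
    mode = binned_mode(window_sums)
    return window_sums > depth_mode_multiplier * mode


def excluded_depth_windows(
    depth_table: pd.DataFrame,
    individuals: list[str],
    depth_mode_multiplier: float = 1.5,
) -> set[tuple[str, int]]:
    """(chromosome, window start) pairs failing the population depth filter.

    ``depth_table`` columns: individual, chromosome, window_start,
    mean_depth; sums are taken over ``individuals`` (one population).
    """
    sub = depth_table[depth_table["individual"].isin(individuals)]
    sums = (
        sub.groupby(["chromosome", "window_start"])["mean_depth"].sum().sort_index()
    )
    mask = depth_window_filter(sums.to_numpy(), depth_mode_multiplier)
    return {key for key, flag in zip(sums.index, mask) if flag}


def thin_sites(positions: np.ndarray, thin_bp: int = 50_000) -> np.ndarray:
    """Greedy left-to-right thinning: keep a site iff >= thin_bp from the last kept."""
    positions = np.asarray(positions)
    if positions.size == 0:
        return positions.copy()
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    kept = [int(positions[0])]
    for p in positions[1:]:
        if p - kept[-1] >= thin_bp:
            kept.append(int(p))
    return np.asarray(kept, dtype=positions.dtype)


def exclude_genic(
    positions: np.ndarray, gene_intervals: list[tuple[int, int]]
) -> np.ndarray:
    """Retain positions not covered by any gene interval (0-based half-open)."""
    merged = merge_intervals(gene_intervals)
    positions = np.asarray(positions)
    keep = np.array([not covers(merged, int(p)) for p in positions], dtype=bool)
    return positions[keep]


def filter_vcf(
    records,
    config: FilterConfig,
    populations: dict[str, list[int]],
    repeat_mask: dict[str, list[tuple[int, int]]] | None = None,
    excluded_windows: dict[str, set[tuple[str, int]]] | None = None,
    report: list | None = None,
):
    """Yield records passing site, missingness and depth-window filters.

    ``populations`` maps population name to individual column indices;
    ``excluded_windows`` maps population name to the set produced by
    :func:`excluded_depth_windows`.  When ``report`` is a list, one
    (chrom, pos, verdict, reason) row is appended per input record.
    """
    repeat_mask = {
        c: merge_intervals(iv) for c, iv in (repeat_mask or {}).items()
    }
    for rec in records:
        keep, reason = filter_site(rec, config, repeat_mask.get(rec.chromosome))
        if keep:
            for pop, idx in populations.items():
                if not missingness_filter(rec.genotypes[idx], config.missing_max_fraction):
                    keep, reason = False, f"missingness:{pop}"
                    break
                if excluded_windows:
                    wstart = ((rec.position - 1) // config.depth_window_bp) * config.depth_window_bp
                    if (rec.chromosome, wstart) in excluded_windows.get(pop, set()):
                        keep, reason = False, f"depth_window:{pop}"
                        break
        if report is not None:
            report.append((rec.chromosome, rec.position, "keep" if keep else "drop", reason))
        if keep:
            yield rec


def demography_prep(
    positions_by_chrom: dict[str, np.ndarray],
    gene_intervals: dict[str, list[tuple[int, int]]],
    thin_bp: int = 50_000,
) -> dict[str, np.ndarray]:
    """Genic-SNP removal followed by 50-kbp thinning, per chromosome."""
    out = {}
    for chrom, pos in positions_by_chrom.items():
        kept = exclude_genic(pos, gene_intervals.get(chrom, []))
        out[chrom] = thin_sites(kept, thin_bp)
    return out
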