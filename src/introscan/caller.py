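"""Threshold decision rule and window-call post-processing.

A window's four class probabilities (ELtoIL, ILtoEL, BiDir, none) are turned
into a call by the probability-sum rule: the window is ELtoIL-qualified when
p(ELtoIL) + p(BiDir) exceeds the threshold P, ILtoEL-qualified symmetrically,
BiDir when both qualify, and none otherwise.  Windows adjacent to a primary
call are re-evaluated once at a relaxed threshold; consecutive same-class
windows merge into regions; region sets reduce to per-chromosome and
genome-wide bp fractions and cross-scan union partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import CLASS_LABELS
from .intervals import intersect, merge_intervals, subtract, total_length

_EL, _IL, _BI, _NONE = range(4)


@dataclass
class CallerConfig:
    p_threshold: float = 0.9
    p_neighbor: float = 0.7

    def __post_init__(self) -> None:
        if not (0.5 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0.5, 1]")
        if not (0 < self.p_neighbor <= self.p_threshold):
            raise ValueError("p_neighbor must be in (0, p_threshold]")


@dataclass
class WindowCall:
    chromosome: str
    bp_start: int
    bp_end: int
    snp_start: int
    snp_end: int
    probabilities: np.ndarray
    assigned: str = "none"
    stage: str = "primary"  # primary | neighbor-extended


@dataclass
class MergedRegion:
    chromosome: str
    bp_start: int
    bp_end: int
    assigned: str
    n_windows: int = 1


def assign_class(probs: np.ndarray, p_threshold: float) -> str:
    """Probability-sum decision rule at threshold ``p_threshold``."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (4,):
        raise ValueError("expected four class probabilities")
    el = probs[_EL] + probs[_BI] > p_threshold
    il = probs[_IL] + probs[_BI] > p_threshold
    if el and il:
        return "BiDir"
    if el:
        return "ELtoIL"
    if il:
        return "ILtoEL"
    return "none"


def call_windows(windows: list[WindowCall], config: CallerConfig | None = None) -> list[WindowCall]:
    """Primary-threshold calls followed by single-pass neighbor extension."""
    config = config or CallerConfig()
    called = [
        replace(w, assigned=assign_class(w.probabilities, config.p_threshold), stage="primary")
        for w in windows
    ]
    return neighbor_extension(called, config)


def _check_ordered(windows: list[WindowCall]) -> None:
    for a, b in zip(windows, windows[1:]):
        if a.chromosome == b.chromosome and b.snp_start < a.snp_start:
            raise ValueError("windows must be in genomic order per chromosome")


def neighbor_extension(windows: list[WindowCall], config: CallerConfig) -> list[WindowCall]:
    """Re-evaluate none-windows adjacent to primary calls at the relaxed threshold.

    Single pass over the original primary assignment: a none-window whose
    immediately previous or next window (same chromosome, sliding order) is
    a primary non-none call is re-assigned with :func:`assign_class` at
    ``p_neighbor``.  Newly extended calls never seed further extension, and
    primary calls are never modified.
    """
    _check_ordered(windows)

    def primary_called(i: int) -> bool:
        w = windows[i]
        return w.stage == "primary" and w.assigned != "none"

    out = list(windows)
    for i, w in enumerate(windows):
        if w.assigned != "none":
            continue
        neighbors = []
        if i > 0 and windows[i - 1].chromosome == w.chromosome:
            neighbors.append(i - 1)
        if i + 1 < len(windows) and windows[i + 1].chromosome == w.chromosome:
            neighbors.append(i + 1)
        if any(primary_called(j) for j in neighbors):
            relaxed = assign_class(w.probabilities, config.p_neighbor)
            if relaxed != "none":
                out[i] = replace(w, assigned=relaxed, stage="neighbor-extended")
    return out


def merge_calls(windows: list[WindowCall]) -> list[MergedRegion]:
    """Merge maximal runs of consecutive same-class non-none windows."""
    _check_ordered(windows)
    regions: list[MergedRegion] = []
    current: MergedRegion | None = None
    prev: WindowCall | None = None
    for w in windows:
        if w.assigned == "none":
            current = None
        elif (
            current is not None
            and prev is not None
            and w.chromosome == current.chromosome
            and w.assigned == current.assigned
        ):
            current.bp_end = max(current.bp_end, w.bp_end)
            current.n_windows += 1
        else:
            current = MergedRegion(w.chromosome, w.bp_start, w.bp_end, w.assigned)
            regions.append(current)
        prev = w
    return regions


def _by_chromosome(regions: list[MergedRegion]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        out.setdefault(r.chromosome, []).append((r.bp_start, r.bp_end))
    return out


def genome_fraction(
    regions: list[MergedRegion], chromosome_lengths: dict[str, int]
) -> dict:
    """Per-chromosome and genome-wide introgressed bp fractions per class.

    Per-class regions are flattened to a bp union first; the overall
    "any-introgression" fraction uses the union over all non-none classes.
    """
    genome_bp = sum(chromosome_lengths.values())
    for r in regions:
        if r.chromosome not in chromosome_lengths:
            raise ValueError(f"region on unknown chromosome {r.chromosome!r}")
        if r.bp_start < 0 or r.bp_end > chromosome_lengths[r.chromosome]:
            raise ValueError(
                f"region {r.chromosome}:{r.bp_start}-{r.bp_end} out of bounds"
            )
    report: dict = {"per_class": {}, "per_chromosome": {}, "genome_bp": genome_bp}
    classes = [c for c in CLASS_LABELS if c != "none"]
    for cls in classes:
        cls_regions = [r for r in regions if r.assigned == cls]
        per_chrom = _by_chromosome(cls_regions)
        report["per_class"][cls] = sum(total_length(iv) for iv in per_chrom.values()) / genome_bp
    all_per_chrom = _by_chromosome(regions)
    for chrom, length in chromosome_lengths.items():
        bp = total_length(all_per_chrom.get(chrom, []))
        report["per_chromosome"][chrom] = bp / length
    report["any"] = (
        sum(total_length(iv) for iv in all_per_chrom.values()) / genome_bp
    )
    return report


def union_scans(
    regions_a: list[MergedRegion],
    regions_b: list[MergedRegion],
    chromosome_lengths: dict[str, int],
) -> dict:
    """Partition the bp union of two scans into {A-only, B-only, both}.

    Exact interval arithmetic: the three parts are disjoint and their bp
    total equals the union total, so the reported fractions satisfy
    a_only + b_only + both == union.
    """
    genome_bp = sum(chromosome_lengths.values())
    a_by, b_by = _by_chromosome(regions_a), _by_chromosome(regions_b)
    parts = {"a_only": {}, "b_only": {}, "both": {}, "union": {}}
    chroms = set(a_by) | set(b_by)
    for chrom in chroms:
        a = merge_intervals(a_by.get(chrom, []))
        b = merge_intervals(b_by.get(chrom, []))
        parts["both"][chrom] = intersect(a, b)
        parts["a_only"][chrom] = subtract(a, b)
        parts["b_only"][chrom] = subtract(b, a)
        parts["union"][chrom] = merge_intervals(a + b)
    out = {"intervals": parts, "fractions": {}}
    for key in ("a_only", "b_only", "both", "union"):
        bp = sum(total_length(iv) for iv in parts[key].values())
        out["fractions"][key] = bp / genome_bp
    return out
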