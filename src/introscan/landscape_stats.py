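"""Genomic-landscape comparisons of called regions against a random null.

For each region we measure per-bp nucleotide diversity, bp distance to the
closest chromosome end, and bp overlap with annotated genes, then compare
the observed distributions against 100 random placements of the same window
lengths using a two-tailed Welch t-test and Cohen's d on log-transformed
values.  Per-chromosome introgression fractions relate to chromosome length
by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import intersect, merge_intervals


def nucleotide_diversity(haplotypes: np.ndarray, span_bp: int) -> float:
    """Unbiased per-bp nucleotide diversity of a binary haplotype window.

    pi = sum over sites of 2 p (1-p) n/(n-1), averaged per bp over the
    window span.  Invariant under allele relabeling (p <-> 1-p).
    """
    haplotypes = np.asarray(haplotypes)
    n = haplotypes.shape[0]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if span_bp <= 0:
        raise ValueError("window span must be positive")
    p = haplotypes.mean(axis=0)
    return float((2.0 * p * (1.0 - p) * n / (n - 1)).sum() / span_bp)


def telomere_distance(bp_start: int, bp_end: int, chromosome_length: int) -> int:
    """bp distance from a [start, end) window to the closest chromosome end."""
    if bp_start < 0 or bp_end > chromosome_length or bp_end <= bp_start:
        raise ValueError(
            f"window [{bp_start}, {bp_end}) out of bounds for length {chromosome_length}"
        )
    return min(bp_start, chromosome_length - bp_end)


def gene_overlap(bp_start: int, bp_end: int, gene_intervals) -> int:
    """Total bp of intersection with the union of gene intervals."""
    return sum(e - s for s, e in intersect([(bp_start, bp_end)], gene_intervals))


def random_null(
    observed_lengths,
    chromosome_lengths: dict[str, int],
    rng: np.random.Generator,
    replicates: int = 100,
) -> list[list[tuple[str, int, int]]]:
    """``replicates`` random window sets matching the observed length multiset.

    Each window keeps its length and is placed uniformly: chromosome chosen
    with probability proportional to length among chromosomes that fit it,
    start uniform on the feasible range.  Windows may overlap each other and
    any annotation.
    """
    observed_lengths = [int(w) for w in observed_lengths]
    chroms = list(chromosome_lengths)
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    out = []
    for _ in range(replicates):
        windows = []
        for w in observed_lengths:
            fits = lengths >= w
            if not fits.any():
                raise ValueError(f"window length {w} exceeds every chromosome")
            prob = np.where(fits, lengths, 0.0)
            prob /= prob.sum()
            ci = rng.choice(len(chroms), p=prob)
            start = int(rng.integers(0, chromosome_lengths[chroms[ci]] - w + 1))
            windows.append((chroms[ci], start, start + w))
        out.append(windows)
    return out


@dataclass
class ComparisonResult:
    cohens_d: float
    p_value: float
    observed_mean_log: float
    null_mean_log: float
    n_observed: int
    n_null: int


def _log_with_zero_floor(observed: np.ndarray, null: np.ndarray):
    pooled = np.concatenate([observed, null])
    if (pooled < 0).any():
        raise ValueError("values must be non-negative")
    positive = pooled[pooled > 0]
    if positive.size == 0:
        raise ValueError("all values are zero; nothing to compare on a log scale")
    floor = positive.min() / 2.0
    return (
        np.log(np.where(observed > 0, observed, floor)),
        np.log(np.where(null > 0, null, floor)),
    )


def compare_groups(observed, null) -> ComparisonResult:
    """Welch two-tailed t-test and pooled-SD Cohen's d on natural-log values.

    Zero values are floored at half the smallest positive pooled value
    before the log transform.  Sign convention: Cohen's d = (null mean -
    observed mean) / pooled SD, so d > 0 means the observed values are
    smaller.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValueError("both groups must be non-empty")
    lo, ln = _log_with_zero_floor(observed, null)
    if lo.std() == 0 and ln.std() == 0:
        if lo.mean() == ln.mean():
            return ComparisonResult(0.0, 1.0, float(lo.mean()), float(ln.mean()),
                                    observed.size, null.size)
        raise ValueError("zero variance in both groups")
    n1, n2 = lo.size, ln.size
    s1, s2 = lo.var(ddof=1) if n1 > 1 else 0.0, ln.var(ddof=1) if n2 > 1 else 0.0
    pooled_sd = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    d = (ln.mean() - lo.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    t = stats.ttest_ind(lo, ln, equal_var=False)
    return ComparisonResult(
        cohens_d=float(d),
        p_value=float(t.pvalue),
        observed_mean_log=float(lo.mean()),
        null_mean_log=float(ln.mean()),
        n_observed=n1,
        n_null=n2,
    )


def chromosome_correlation(fractions, lengths) -> tuple[float, float]:
    """Pearson r and two-tailed p for per-chromosome fraction vs length."""
    fractions = np.asarray(fractions, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if fractions.size != lengths.size or fractions.size < 3:
        raise ValueError("need >= 3 paired chromosome observations")
    if fractions.std() == 0 or lengths.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r = stats.pearsonr(lengths, fractions)
    return float(r.statistic), float(r.pvalue)


def window_stats(
    windows: list[tuple[str, int, int]],
    haplotype_windows,
    chromosome_lengths: dict[str, int],
    gene_intervals: dict[str, list[tuple[int, int]]],
) -> dict[str, np.ndarray]:
    """Per-window pi / telomere-distance / gene-overlap vectors.

    ``haplotype_windows`` pairs each (chrom, start, end) window with the
    binary haplotype matrix of its SNPs (or None to skip pi).
    """
    genes = {c: merge_intervals(iv) for c, iv in gene_intervals.items()}
    pis, tels, overlaps = [], [], []
    for (chrom, s, e), haps in zip(windows, haplotype_windows, strict=True):
        if haps is not None:
            pis.append(nucleotide_diversity(haps, e - s))
        tels.append(telomere_distance(s, e, chromosome_lengths[chrom]))
        overlaps.append(gene_overlap(s, e, genes.get(chrom, [])))
    return {
        "pi": np.asarray(pis, dtype=float),
        "telomere_distance": np.asarray(tels, dtype=float),
        "gene_overlap": np.asarray(overlaps, dtype=float),
    }
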