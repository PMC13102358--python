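"""Encode phased two-population SNP alignments as binary window tensors.

A window of 128 consecutive SNPs (step 64) from each population is
polarized to major=0 / minor=1 on the combined sample, the smaller
population is upsampled to the padded haplotype dimension ``H`` by
duplicating randomly chosen observed haplotypes, and the two populations
are stacked as the two layers of a (2, H, 128) image-like tensor.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

WINDOW_SNPS = 128
STEP_SNPS = 64


@dataclass
class HaplotypeAlignment:
    """Binary haplotype x site matrix with positions and a 2-way row split.

    ``matrix`` rows 0..n1-1 belong to population 1, the rest to population
    2.  ``positions`` are bp coordinates (0-based), strictly increasing.
    """

    matrix: np.ndarray
    positions: np.ndarray
    chromosome: str
    n_pop1: int
    population_names: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("positions length must match number of sites")
        if not (0 < self.n_pop1 < self.matrix.shape[0]):
            raise ValueError("n_pop1 must split the rows into two non-empty groups")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("matrix entries must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def pop(self, index: int) -> np.ndarray:
        if index == 0:
            return self.matrix[: self.n_pop1]
        if index == 1:
            return self.matrix[self.n_pop1 :]
        raise IndexError("population index must be 0 or 1")


@dataclass
class WindowTensor:
    """(2, H, window) binary tensor plus its SNP-index and bp spans."""

    array: np.ndarray
    snp_start: int
    snp_end: int  # exclusive
    bp_start: int
    bp_end: int  # exclusive (last SNP position + 1)
    chromosome: str = ""
    monomorphic_columns: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def polarize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recode columns so the major allele over all rows is 0.

    Input coding is 0=reference, 1=alternative.  Columns where the
    alternative allele has combined frequency > 0.5 are flipped; exact ties
    keep the reference as major.  Returns (binary matrix, boolean mask of
    monomorphic columns).  Idempotent.
    """
    matrix = np.asarray(matrix, dtype=np.int8)
    freq = matrix.mean(axis=0)
    flip = freq > 0.5
    out = np.where(flip[None, :], 1 - matrix, matrix)
    mono = (freq == 0) | (freq == 1)
    return out.astype(np.int8), mono


def upsample(rows: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Pad ``rows`` to ``target`` haplotypes.

    All originals are retained once, in order; the remaining rows are drawn
    uniformly with replacement from the originals and appended.
    """
    rows = np.asarray(rows)
    n = rows.shape[0]
    if n > target:
        raise ValueError(f"cannot upsample {n} haplotypes down to {target}")
    if n == target:
        return rows.copy()
    extra = rng.integers(0, n, size=target - n)
    return np.concatenate([rows, rows[extra]], axis=0)


def window_count(n_sites: int, window_snps: int = WINDOW_SNPS, step_snps: int = STEP_SNPS) -> int:
    """Number of full sliding windows: floor((S - window)/step) + 1, 0 if S < window."""
    if n_sites < window_snps:
        return 0
    return (n_sites - window_snps) // step_snps + 1


def extract_windows(
    alignment: HaplotypeAlignment,
    window_snps: int = WINDOW_SNPS,
    step_snps: int = STEP_SNPS,
) -> list[tuple[int, int]]:
    """SNP-index spans [start, end) of the sliding windows, trailing partial dropped."""
    count = window_count(alignment.n_sites, window_snps, step_snps)
    return [(i * step_snps, i * step_snps + window_snps) for i in range(count)]


def assemble_tensor(
    pop1_window: np.ndarray, pop2_window: np.ndarray, target_h: int | None = None
) -> np.ndarray:
    """Stack two equally padded population windows as a (2, H, S) tensor."""
    pop1_window = np.asarray(pop1_window, dtype=np.int8)
    pop2_window = np.asarray(pop2_window, dtype=np.int8)
    if pop1_window.shape != pop2_window.shape:
        raise ValueError(
            f"population windows disagree in shape: {pop1_window.shape} vs "
            f"{pop2_window.shape}"
        )
    if target_h is not None and pop1_window.shape[0] != target_h:
        raise ValueError(
            f"padded haplotype dimension {pop1_window.shape[0]} != target {target_h}"
        )
    return np.stack([pop1_window, pop2_window], axis=0)


def encode_window(
    alignment: HaplotypeAlignment,
    snp_start: int,
    snp_end: int,
    target_h: int | None = None,
    rng: np.random.Generator | None = None,
) -> WindowTensor:
    """Polarize, upsample and stack one SNP-index window of an alignment."""
    if rng is None:
        rng = np.random.default_rng(0)
    n1 = alignment.n_pop1
    n2 = alignment.n_haplotypes - n1
    if target_h is None:
        target_h = max(n1, n2)
    cols = alignment.matrix[:, snp_start:snp_end]
    polarized, mono = polarize(cols)
    t = assemble_tensor(
        upsample(polarized[:n1], target_h, rng),
        upsample(polarized[n1:], target_h, rng),
        target_h,
    )
    pos = alignment.positions[snp_start:snp_end]
    return WindowTensor(
        array=t,
        snp_start=snp_start,
        snp_end=snp_end,
        bp_start=int(pos[0]),
        bp_end=int(pos[-1]) + 1,
        chromosome=alignment.chromosome,
        monomorphic_columns=np.flatnonzero(mono),
    )


def encode_alignment(
    alignment: HaplotypeAlignment,
    target_h: int | None = None,
    window_snps: int = WINDOW_SNPS,
    step_snps: int = STEP_SNPS,
    seed: int = 0,
) -> list[WindowTensor]:
    """Sliding-window tensor sequence for a whole chromosome alignment.

    Upsampling is seeded per (chromosome, window index) so rerunning a scan
    reproduces identical tensors.
    """
    out = []
    for widx, (s, e) in enumerate(extract_windows(alignment, window_snps, step_snps)):
        # crc32, not hash(): str hashing is salted per process
        chrom_key = zlib.crc32(alignment.chromosome.encode())
        key = np.random.SeedSequence(entropy=seed, spawn_key=(chrom_key, widx))
        rng = np.random.default_rng(key)
        out.append(encode_window(alignment, s, e, target_h=target_h, rng=rng))
    return out


def central_window(n_sites: int, window_snps: int) -> tuple[int, int]:
    """SNP-index span of the centered window used for training examples."""
    if n_sites < window_snps:
        raise ValueError(f"{n_sites} sites cannot fill a {window_snps}-SNP window")
    start = (n_sites - window_snps) // 2
    return start, start + window_snps
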