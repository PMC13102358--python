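"""Classifier performance measurement and SFS model checking.

Precision is the fraction of calls of a class that are correct; recall the
fraction of simulated cases of a class that are recovered.  Presence metrics
collapse the three introgression classes against "none"; directionality
metrics are computed only over windows whose presence was correctly
detected.  Undefined (0/0) precisions are reported as absent rather than 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import CLASS_LABELS
from .caller import assign_class
from .demography import DemographicModel
from .scenario_simulator import (
    DepthErrorConfig,
    LabelledExample,
    RateHeterogeneityConfig,
    draw_scenario,
    example_tensor,
    inject_depth_errors,
    simulate_example,
)
from .tensor_encoder import HaplotypeAlignment

THRESHOLD_GRID = (0.75, 0.8, 0.85, 0.9, 0.95)

_NONE_IDX = CLASS_LABELS.index("none")


@dataclass
class ConfusionTable:
    """Counts indexed by (true class, predicted class) over the four classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError("confusion table must be 4x4")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(cls, true_labels, predicted_labels) -> "ConfusionTable":
        counts = np.zeros((4, 4), dtype=np.int64)
        for t, p in zip(true_labels, predicted_labels, strict=True):
            ti = t if isinstance(t, (int, np.integer)) else CLASS_LABELS.index(t)
            pi = p if isinstance(p, (int, np.integer)) else CLASS_LABELS.index(p)
            counts[ti, pi] += 1
        return cls(counts)


@dataclass
class MetricReport:
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    presence_precision: float | None
    presence_recall: float | None
    directionality_precision: dict[str, float | None] = field(default_factory=dict)
    directionality_recall: dict[str, float | None] = field(default_factory=dict)
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "precision": self.precision,
            "recall": self.recall,
            "presence_precision": self.presence_precision,
            "presence_recall": self.presence_recall,
            "directionality_precision": self.directionality_precision,
            "directionality_recall": self.directionality_recall,
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def precision_recall(table: ConfusionTable, threshold: float | None = None) -> MetricReport:
    """Per-class, binary-presence and directionality metrics from a table."""
    c = table.counts
    precision = {}
    recall = {}
    for i, label in enumerate(CLASS_LABELS):
        precision[label] = _ratio(int(c[i, i]), int(c[:, i].sum()))
        recall[label] = _ratio(int(c[i, i]), int(c[i, :].sum()))
    intro = [i for i in range(4) if i != _NONE_IDX]
    tp = int(c[np.ix_(intro, intro)].sum())
    called = int(c[:, intro].sum())
    simulated = int(c[intro, :].sum())
    presence_precision = _ratio(tp, called)
    presence_recall = _ratio(tp, simulated)
    # directionality: restrict to windows with correctly detected presence
    sub = c[np.ix_(intro, intro)]
    dir_precision = {}
    dir_recall = {}
    for k, i in enumerate(intro):
        label = CLASS_LABELS[i]
        dir_precision[label] = _ratio(int(sub[k, k]), int(sub[:, k].sum()))
        dir_recall[label] = _ratio(int(sub[k, k]), int(sub[k, :].sum()))
    return MetricReport(
        precision=precision,
        recall=recall,
        presence_precision=presence_precision,
        presence_recall=presence_recall,
        directionality_precision=dir_precision,
        directionality_recall=dir_recall,
        threshold=threshold,
    )


def evaluate_thresholds(
    probabilities: np.ndarray,
    true_labels: np.ndarray,
    thresholds=THRESHOLD_GRID,
) -> dict[float, MetricReport]:
    """Apply the decision rule at each threshold and report metrics per P."""
    probabilities = np.asarray(probabilities)
    true_labels = np.asarray(true_labels)
    out = {}
    for p in thresholds:
        predicted = [CLASS_LABELS.index(assign_class(row, p)) for row in probabilities]
        table = ConfusionTable.from_labels(true_labels, predicted)
        out[p] = precision_recall(table, threshold=p)
    return out


# ----------------------------------------------------------------------
# evaluation-set generation under error models
# ----------------------------------------------------------------------

def _corrupt_example(
    example: LabelledExample,
    depth: DepthErrorConfig,
    rng: np.random.Generator,
    individuals_pop1: list[int] | None,
    individuals_pop2: list[int] | None,
) -> LabelledExample:
    m = example.alignment.matrix
    n1_ind = example.alignment.n_pop1 // 2
    n2_ind = (m.shape[0] - example.alignment.n_pop1) // 2
    inds1 = list(range(n1_ind)) if individuals_pop1 is None else individuals_pop1
    inds2 = list(range(n2_ind)) if individuals_pop2 is None else individuals_pop2
    targets = list(inds1) + [n1_ind + i for i in inds2]
    corrupted = inject_depth_errors(m, depth, rng, individuals=targets)
    alignment = HaplotypeAlignment(
        matrix=corrupted,
        positions=example.alignment.positions,
        chromosome=example.alignment.chromosome,
        n_pop1=example.alignment.n_pop1,
    )
    return LabelledExample(
        spec=example.spec,
        alignment=alignment,
        introgressed=example.introgressed,
        donor_spans=example.donor_spans,
    )


def build_evaluation_set(
    model: DemographicModel,
    n_per_scenario: int,
    samples: tuple[int, int],
    rng: np.random.Generator,
    window_snps: int = 128,
    target_h: int | None = None,
    region_bp: float = 1.1e6,
    recombination_rate: float = 1e-8,
    mutation_scale: float = 1.0,
    depth: DepthErrorConfig | None = None,
    low_depth_individuals: tuple[int, int] | None = None,
    heterogeneity: RateHeterogeneityConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled (X, y) evaluation tensors under optional error models.

    ``depth`` corrupts heterozygous genotypes; ``low_depth_individuals``
    restricts corruption to the first k individuals per population (all
    individuals when None).  ``heterogeneity`` draws a shared region-level
    Gamma rate scaler per simulation.
    """
    if target_h is None:
        target_h = 2 * max(samples)
    if low_depth_individuals is not None:
        k1, k2 = low_depth_individuals
        if k1 > samples[0] or k2 > samples[1]:
            raise ValueError("low-depth counts exceed population sizes")
    xs, ys = [], []
    for label_idx, label in enumerate(CLASS_LABELS):
        for _ in range(n_per_scenario):
            ex = simulate_example(
                model, draw_scenario(label, rng), samples, rng,
                region_bp=region_bp, window_snps=window_snps,
                recombination_rate=recombination_rate,
                mutation_scale=mutation_scale, heterogeneity=heterogeneity,
            )
            if depth is not None:
                if low_depth_individuals is None:
                    inds1 = inds2 = None
                else:
                    inds1 = list(range(low_depth_individuals[0]))
                    inds2 = list(range(low_depth_individuals[1]))
                ex = _corrupt_example(ex, depth, rng, inds1, inds2)
            xs.append(example_tensor(ex, window_snps, target_h, rng))
            ys.append(label_idx)
    return np.asarray(xs, dtype=np.uint8), np.asarray(ys, dtype=np.int64)


def build_depth_sweep_sets(
    model: DemographicModel,
    n_per_scenario: int,
    samples: tuple[int, int],
    rng: np.random.Generator,
    depths=(2, 3, 4, 5, 6),
    **kwargs,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """One labelled evaluation set per mean depth, all individuals corrupted."""
    out = {}
    for lam in depths:
        out[lam] = build_evaluation_set(
            model, n_per_scenario, samples, rng,
            depth=DepthErrorConfig(mean_depth=float(lam)), **kwargs,
        )
    return out


_DEFAULT_HETEROGENEITY = object()


def build_realistic_set(
    model: DemographicModel,
    n_per_scenario: int,
    samples: tuple[int, int],
    low_depth_counts: tuple[int, int],
    rng: np.random.Generator,
    mean_depth: float = 4.0,
    heterogeneity=_DEFAULT_HETEROGENEITY,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-depth individuals at 4x plus Gamma rate heterogeneity per region.

    Pass ``heterogeneity=None`` to disable the rate scaler explicitly.
    """
    if heterogeneity is _DEFAULT_HETEROGENEITY:
        heterogeneity = RateHeterogeneityConfig()
    return build_evaluation_set(
        model, n_per_scenario, samples, rng,
        depth=DepthErrorConfig(mean_depth=mean_depth),
        low_depth_individuals=low_depth_counts,
        heterogeneity=heterogeneity,
        **kwargs,
    )


# ----------------------------------------------------------------------
# joint SFS and composite likelihood
# ----------------------------------------------------------------------

def joint_sfs(
    matrix: np.ndarray, n_pop1: int, fold_minor: bool = True
) -> np.ndarray:
    """(n1+1) x (n2+1) joint allele-count spectrum of a binary alignment.

    Cell (i, j) counts sites with derived/minor allele count i in population
    1 and j in population 2.  With ``fold_minor`` the allele that is minor in
    the combined sample is counted (the tensor polarization convention; ties
    count the alternative allele).
    """
    matrix = np.asarray(matrix)
    n1 = n_pop1
    n2 = matrix.shape[0] - n_pop1
    c1 = matrix[:n1].sum(axis=0)
    c2 = matrix[n1:].sum(axis=0)
    if fold_minor:
        total = c1 + c2
        flip = total > (n1 + n2) / 2
        c1 = np.where(flip, n1 - c1, c1)
        c2 = np.where(flip, n2 - c2, c2)
    if (c1 > n1).any() or (c2 > n2).any():
        raise ValueError("allele count exceeds sample size")
    sfs = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    np.add.at(sfs, (c1, c2), 1)
    return sfs


def save_sfs(path, sfs: np.ndarray, masked: bool = True) -> None:
    """Plain-text SFS matrix with a ``# n1 n2 mask`` header line."""
    n1, n2 = sfs.shape[0] - 1, sfs.shape[1] - 1
    header = f"{n1} {n2} {'corners-masked' if masked else 'unmasked'}"
    np.savetxt(path, sfs, fmt="%d", header=header)


def load_sfs(path) -> tuple[np.ndarray, dict]:
    """Inverse of :func:`save_sfs`; returns (matrix, header metadata)."""
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    sfs = np.loadtxt(path, dtype=np.int64, ndmin=2)
    meta = {"n1": int(header[0]), "n2": int(header[1]), "mask": header[2]}
    if sfs.shape != (meta["n1"] + 1, meta["n2"] + 1):
        raise ValueError("SFS shape does not match its header")
    return sfs, meta


def mask_corners(sfs: np.ndarray) -> np.ndarray:
    """Boolean mask of valid cells: the two fixed corners excluded."""
    mask = np.ones_like(sfs, dtype=bool)
    mask[0, 0] = False
    mask[-1, -1] = False
    return mask


def ll_multinom(data: np.ndarray, model: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Poisson composite log-likelihood with optimal rescaling of the model.

    The model is scaled by theta = sum(data)/sum(model) over unmasked cells,
    then LL = sum(d*ln(theta*m) - theta*m - ln Gamma(d+1)).  Invariant under
    multiplying the model by any positive constant.
    """
    data = np.asarray(data, dtype=float)
    model = np.asarray(model, dtype=float)
    if data.shape != model.shape:
        raise ValueError("data and model SFS must have the same shape")
    if mask is None:
        mask = mask_corners(data)
    d = data[mask]
    m = model[mask]
    if ((m == 0) & (d > 0)).any():
        warnings.warn("model SFS is zero where data is nonzero; LL = -inf")
        return float("-inf")
    if m.sum() == 0:
        raise ValueError("model SFS is identically zero on unmasked cells")
    theta = d.sum() / m.sum()
    mm = theta * m
    pos = d > 0
    ll = (d[pos] * np.log(mm[pos])).sum() - mm.sum() - gammaln(d + 1).sum()
    return float(ll)


def opposite_frequency_mass(sfs: np.ndarray, border: int = 2) -> float:
    """Fraction of sites in interior cells adjacent to the (0, n2) and
    (n1, 0) corners: variation shared by both populations at opposite
    frequencies (low in one, high in the other), the SFS signature that
    increases with introgression.  Boundary cells (count 0 in either
    population, or fixed in the high-frequency one) are excluded — those
    record divergence, not sharing.
    """
    n1, n2 = sfs.shape[0] - 1, sfs.shape[1] - 1
    total = sfs.sum()
    if total == 0:
        return 0.0
    m = 0
    for i in range(1, border + 1):
        for j in range(max(1, n2 - border), n2):
            m += sfs[i, j]
    for i in range(max(1, n1 - border), n1):
        for j in range(1, border + 1):
            m += sfs[i, j]
    return float(m) / float(total)
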