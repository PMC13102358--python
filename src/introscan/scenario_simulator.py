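"""Labelled training and evaluation examples by coalescent simulation.

Each example is a two-population phased alignment simulated under a
:class:`~introscan.demography.DemographicModel`, optionally carrying one
mass-migration pulse per direction (proportion uniform on [0.05, 0.50],
timing uniform on [1, 5000] generations before present).  Donor ancestry on
recipient haplotypes is tracked through the coalescent engine's migration
records; examples whose label promises introgression are resimulated
(bounded) until at least one recipient haplotype carries donor ancestry.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from . import CLASS_LABELS
from .demography import DemographicModel, to_msprime
from .tensor_encoder import HaplotypeAlignment, central_window, encode_window

PROPORTION_RANGE = (0.05, 0.50)
TIME_RANGE = (1.0, 5000.0)
#: pulse directions, forward time: "ELtoIL" moves EL lineages into the IL side
DIRECTIONS = ("ELtoIL", "ILtoEL")


@dataclass
class ScenarioSpec:
    """Class label plus the per-direction pulse parameters."""

    label: str
    pulses: dict[str, tuple[float, float]] = field(default_factory=dict)
    # pulses[direction] = (proportion, time in generations before present)

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        expected = {
            "none": set(),
            "ELtoIL": {"ELtoIL"},
            "ILtoEL": {"ILtoEL"},
            "BiDir": {"ELtoIL", "ILtoEL"},
        }[self.label]
        if set(self.pulses) != expected:
            raise ValueError(
                f"label {self.label!r} requires pulses {sorted(expected)}, "
                f"got {sorted(self.pulses)}"
            )
        for direction, (prop, t) in self.pulses.items():
            if not (PROPORTION_RANGE[0] <= prop <= PROPORTION_RANGE[1]):
                raise ValueError(f"{direction} proportion {prop} outside {PROPORTION_RANGE}")
            if not (TIME_RANGE[0] <= t <= TIME_RANGE[1]):
                raise ValueError(f"{direction} time {t} outside {TIME_RANGE}")


def draw_scenario(label: str, rng: np.random.Generator) -> ScenarioSpec:
    """Draw pulse parameters uniformly on the stated ranges (independent per direction)."""
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown label {label!r}")
    directions = {
        "none": (),
        "ELtoIL": ("ELtoIL",),
        "ILtoEL": ("ILtoEL",),
        "BiDir": DIRECTIONS,
    }[label]
    pulses = {
        d: (
            float(rng.uniform(*PROPORTION_RANGE)),
            float(rng.uniform(*TIME_RANGE)),
        )
        for d in directions
    }
    return ScenarioSpec(label=label, pulses=pulses)


@dataclass
class RateHeterogeneityConfig:
    """Gamma(shape, 1/shape) region-level scaler for mutation and recombination."""

    shape: float = 10.0
    scale: float | None = None  # defaults to 1/shape (mean-1 construction)

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.scale is None:
            self.scale = 1.0 / self.shape


def sample_rate_scaler(config: RateHeterogeneityConfig, rng: np.random.Generator) -> float:
    """One positive scaling factor applied to both mutation and recombination."""
    return float(rng.gamma(config.shape, config.scale))


@dataclass
class DepthErrorConfig:
    """Poisson read-depth genotyping-error model at heterozygous sites."""

    mean_depth: float
    min_depth: int = 1
    allele_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.min_depth < 1:
            raise ValueError("min_depth must be at least 1")


def inject_depth_errors(
    matrix: np.ndarray,
    config: DepthErrorConfig,
    rng: np.random.Generator,
    individuals: list[int] | None = None,
) -> np.ndarray:
    """Corrupt heterozygous genotypes of designated diploid individuals.

    Rows 2i and 2i+1 of ``matrix`` form individual i.  At each heterozygous
    site of a designated individual, depth d = max(min_depth, Poisson(λ))
    reads are assigned to the two alleles by Binomial(d, 0.5); observing
    only one allele rewrites the call (and both haplotypes) to the
    corresponding homozygote, otherwise the site is untouched.  Homozygous
    sites are never altered.
    """
    matrix = np.asarray(matrix, dtype=np.int8).copy()
    n_ind = matrix.shape[0] // 2
    if individuals is None:
        individuals = list(range(n_ind))
    for ind in individuals:
        a, b = matrix[2 * ind], matrix[2 * ind + 1]
        het = np.flatnonzero(a != b)
        if het.size == 0:
            continue
        d = np.maximum(config.min_depth, rng.poisson(config.mean_depth, size=het.size))
        alt_reads = rng.binomial(d, config.allele_prob)
        hom_ref = het[alt_reads == 0]
        hom_alt = het[alt_reads == d]
        a[hom_ref] = 0
        b[hom_ref] = 0
        a[hom_alt] = 1
        b[hom_alt] = 1
    return matrix


@dataclass
class LabelledExample:
    """A scenario, its phased alignment, and per-haplotype introgression flags."""

    spec: ScenarioSpec
    alignment: HaplotypeAlignment
    introgressed: np.ndarray  # bool per haplotype row
    donor_spans: dict[str, list[tuple[float, float, int]]] = field(default_factory=dict)
    # donor_spans[direction] = [(bp left, bp right, haplotype row), ...]


def _pulse_carriers(ts, pulse_time: float, recipient_id: int, donor_id: int):
    """(bp left, bp right, sample node) spans of donor ancestry from one pulse."""
    tab = ts.tables.migrations
    sel = (tab.time == pulse_time) & (tab.source == recipient_id) & (tab.dest == donor_id)
    spans = list(zip(tab.left[sel], tab.right[sel], tab.node[sel]))
    out: list[tuple[float, float, int]] = []
    for left, right, node in spans:
        tree = ts.at(left)
        while True:
            l, r = tree.interval
            if l >= right:
                break
            seg = (max(l, left), min(r, right))
            for s in tree.samples(node):
                out.append((seg[0], seg[1], int(s)))
            if r >= right or not tree.next():
                break
    return out


def _positions_bp(site_positions: np.ndarray) -> np.ndarray:
    """Floor float positions to strictly increasing integer bp."""
    pos = np.floor(site_positions).astype(np.int64)
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def _alignment_from_ts(mts, n1_hap: int, chromosome: str = "sim") -> HaplotypeAlignment:
    g = mts.genotype_matrix()  # sites x haplotypes
    g = np.minimum(g, 1)  # infinite-sites model: already 0/1
    return HaplotypeAlignment(
        matrix=np.ascontiguousarray(g.T, dtype=np.int8),
        positions=_positions_bp(mts.tables.sites.position),
        chromosome=chromosome,
        n_pop1=n1_hap,
    )


class PulseDemography:
    """Reusable demography template with in-place mutable pulse events.

    A forward-time pulse moving donor lineages into the recipient is a
    backward-time mass migration of recipient lineages to the donor.
    Rebuilding the full msprime demography per example dominates small-scale
    generation runs; this template builds it once per (model, direction set)
    and only rewrites the pulse parameters.
    """

    def __init__(self, model: DemographicModel, directions) -> None:
        self.dem = to_msprime(model)
        p1, p2 = model.populations  # (IL side, EL side)
        self._events: dict[str, msprime.MassMigration] = {}
        for direction in directions:
            recipient, donor = (p1, p2) if direction == "ELtoIL" else (p2, p1)
            self._events[direction] = self.dem.add_mass_migration(
                time=1.0, source=recipient, dest=donor, proportion=0.1
            )

    def configure(self, spec: ScenarioSpec) -> msprime.Demography:
        if set(spec.pulses) != set(self._events):
            raise ValueError("spec directions do not match this template")
        for direction, (prop, t) in spec.pulses.items():
            ev = self._events[direction]
            ev.time = t
            ev.proportion = prop
        self.dem.sort_events()
        return self.dem


def build_pulse_demography(model: DemographicModel, spec: ScenarioSpec) -> msprime.Demography:
    """One-off demography with the spec's mass-migration pulses added."""
    return PulseDemography(model, tuple(spec.pulses)).configure(spec)


def simulate_example(
    model: DemographicModel,
    spec: ScenarioSpec,
    samples: tuple[int, int],
    rng: np.random.Generator,
    region_bp: float = 1.1e6,
    window_snps: int = 128,
    recombination_rate: float = 1e-8,
    mutation_scale: float = 1.0,
    heterogeneity: RateHeterogeneityConfig | None = None,
    max_attempts: int = 100,
    chromosome: str = "sim",
    require_tract_in_window: bool = True,
    template: PulseDemography | None = None,
) -> LabelledExample:
    """Simulate one labelled example with at least ``window_snps`` biallelic sites.

    ``samples`` are diploid counts (population 1, population 2).  When the
    label promises introgression, migrant-ancestry tracking must flag at
    least one recipient haplotype per pulse direction; otherwise the region
    is resimulated, up to ``max_attempts`` times.  With
    ``require_tract_in_window`` (the training/evaluation setting) the donor
    ancestry must overlap the central ``window_snps`` analysis window, and
    the per-haplotype flags describe that window; otherwise ancestry
    anywhere in the region qualifies (whole-chromosome truth generation).
    """
    if template is not None:
        dem = template.configure(spec)
    elif spec.pulses:
        dem = build_pulse_demography(model, spec)
    else:
        dem = to_msprime(model)
    p1, p2 = model.populations
    n1_hap = 2 * samples[0]
    pulse_meta = {}
    for direction, (_, t) in spec.pulses.items():
        recipient_id, donor_id = (0, 1) if direction == "ELtoIL" else (1, 0)
        pulse_meta[direction] = (t, recipient_id, donor_id)

    scaler = 1.0
    if heterogeneity is not None:
        scaler = sample_rate_scaler(heterogeneity, rng)

    for _ in range(max_attempts):
        seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples={p1: samples[0], p2: samples[1]},
            demography=dem,
            sequence_length=region_bp,
            recombination_rate=recombination_rate * scaler,
            record_migrations=bool(spec.pulses),
            random_seed=seed,
            record_provenance=False,
        )
        # cheap pre-check: a pulse that moved no lineage can never satisfy
        # the tract requirement, skip the mutation pass
        if pulse_meta:
            mig_times = ts.tables.migrations.time
            if any(not np.any(mig_times == t) for t, _, _ in pulse_meta.values()):
                continue
        mts = msprime.sim_mutations(
            ts,
            rate=model.mutation_rate * mutation_scale * scaler,
            random_seed=seed,
            discrete_genome=False,
            record_provenance=False,
        )
        if mts.num_sites < window_snps:
            continue

        if require_tract_in_window and pulse_meta:
            s_idx, e_idx = central_window(mts.num_sites, window_snps)
            site_pos = mts.tables.sites.position
            win = (float(site_pos[s_idx]), float(site_pos[e_idx - 1]) + 1.0)
        else:
            win = None

        donor_spans: dict[str, list[tuple[float, float, int]]] = {}
        flags = np.zeros(2 * (samples[0] + samples[1]), dtype=bool)
        ok = True
        for direction, (t, recipient_id, donor_id) in pulse_meta.items():
            recipient_samples = set(int(s) for s in ts.samples(population=recipient_id))
            carriers = [
                c for c in _pulse_carriers(ts, t, recipient_id, donor_id)
                if c[2] in recipient_samples
            ]
            donor_spans[direction] = carriers
            if win is None:
                in_window = carriers
            else:
                in_window = [c for c in carriers if c[0] < win[1] and win[0] < c[1]]
            if not in_window:
                ok = False
                break
            for _, _, s in in_window:
                flags[s] = True
        if not ok:
            continue

        alignment = _alignment_from_ts(mts, n1_hap, chromosome=chromosome)
        return LabelledExample(
            spec=spec, alignment=alignment, introgressed=flags, donor_spans=donor_spans
        )

    raise RuntimeError(
        f"failed to produce a satisfying example for {spec} after "
        f"{max_attempts} attempts (need >= {window_snps} sites and, for "
        "introgression labels, donor ancestry in the recipient population)"
    )


def example_tensor(
    example: LabelledExample,
    window_snps: int,
    target_h: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Central fixed-width window of an example, encoded as a (2, H, S) tensor."""
    s, e = central_window(example.alignment.n_sites, window_snps)
    return encode_window(example.alignment, s, e, target_h=target_h, rng=rng).array


# ----------------------------------------------------------------------
# training set construction
# ----------------------------------------------------------------------

def _simulate_none_batch(
    model: DemographicModel,
    n: int,
    samples: tuple[int, int],
    rng: np.random.Generator,
    region_bp: float,
    window_snps: int,
    recombination_rate: float,
    mutation_scale: float,
) -> list[LabelledExample]:
    """Batched replicates for the pulse-free scenario (no migration tracking)."""
    spec = ScenarioSpec(label="none")
    dem = to_msprime(model)
    p1, p2 = model.populations
    n1_hap = 2 * samples[0]
    out: list[LabelledExample] = []
    reps = msprime.sim_ancestry(
        samples={p1: samples[0], p2: samples[1]},
        demography=dem,
        sequence_length=region_bp,
        recombination_rate=recombination_rate,
        num_replicates=n,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        record_provenance=False,
    )
    for ts in reps:
        mts = msprime.sim_mutations(
            ts,
            rate=model.mutation_rate * mutation_scale,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            discrete_genome=False,
            record_provenance=False,
        )
        if mts.num_sites < window_snps:
            continue
        out.append(
            LabelledExample(
                spec=spec,
                alignment=_alignment_from_ts(mts, n1_hap),
                introgressed=np.zeros(2 * (samples[0] + samples[1]), dtype=bool),
            )
        )
    # top up any replicates lost to too few segregating sites
    while len(out) < n:
        out.append(
            simulate_example(
                model, spec, samples, rng,
                region_bp=region_bp, window_snps=window_snps,
                recombination_rate=recombination_rate, mutation_scale=mutation_scale,
            )
        )
    return out[:n]


def build_training_set(
    models: list[DemographicModel],
    n_per_scenario: int,
    samples: tuple[int, int],
    out_dir: str | Path,
    seed: int = 0,
    region_bp: float = 1.1e6,
    window_snps: int = 128,
    target_h: int | None = None,
    recombination_rate: float = 1e-8,
    mutation_scale: float = 1.0,
    validation_fraction: float = 0.05,
) -> dict:
    """Simulate, encode and store the labelled tensor set plus its manifest.

    Produces ``n_per_scenario`` examples per (model, scenario) stratum for
    all four scenarios: ``n_per_scenario * 4 * len(models)`` tensors in
    total.  A stratified validation split (ceil of ``validation_fraction``
    per stratum) is recorded in the manifest.  Returns the manifest dict.
    """
    if n_per_scenario <= 0:
        raise ValueError("n_per_scenario must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if target_h is None:
        target_h = 2 * max(samples)

    xs, ys, model_ids, val = [], [], [], []
    per_stratum: dict[str, int] = {}
    for m_idx, model in enumerate(models):
        for label_idx, label in enumerate(CLASS_LABELS):
            if label == "none":
                examples = _simulate_none_batch(
                    model, n_per_scenario, samples, rng, region_bp,
                    window_snps, recombination_rate, mutation_scale,
                )
            else:
                directions = tuple(draw_scenario(label, np.random.default_rng(0)).pulses)
                template = PulseDemography(model, directions)
                examples = [
                    simulate_example(
                        model, draw_scenario(label, rng), samples, rng,
                        region_bp=region_bp, window_snps=window_snps,
                        recombination_rate=recombination_rate,
                        mutation_scale=mutation_scale,
                        template=template,
                    )
                    for _ in range(n_per_scenario)
                ]
            for ex in examples:
                xs.append(example_tensor(ex, window_snps, target_h, rng))
                ys.append(label_idx)
                model_ids.append(m_idx)
            n_val = math.ceil(validation_fraction * n_per_scenario)
            stratum_val = np.zeros(n_per_scenario, dtype=bool)
            stratum_val[rng.choice(n_per_scenario, size=n_val, replace=False)] = True
            val.extend(stratum_val.tolist())
            per_stratum[f"model{m_idx}/{label}"] = n_per_scenario

    x = np.asarray(xs, dtype=np.uint8)
    y = np.asarray(ys, dtype=np.int64)
    model_idx = np.asarray(model_ids, dtype=np.int64)
    val_mask = np.asarray(val, dtype=bool)
    manifest = {
        "total": int(len(x)),
        "n_models": len(models),
        "n_per_scenario": n_per_scenario,
        "class_labels": list(CLASS_LABELS),
        "per_stratum": per_stratum,
        "validation": {
            "fraction": validation_fraction,
            "rounding": "ceil-per-stratum",
            "total": int(val_mask.sum()),
        },
        "tensor_shape": list(x.shape[1:]),
        "window_snps": window_snps,
        "target_h": target_h,
        "samples": list(samples),
        "region_bp": region_bp,
        "seed": seed,
        "model_names": [m.name for m in models],
    }
    store = out_dir / "tensors.npz"
    manifest_path = out_dir / "manifest.json"
    try:
        np.savez(store, X=x, y=y, model_idx=model_idx, val_mask=val_mask)
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    except OSError:
        for p in (store, manifest_path):
            if p.exists():
                os.unlink(p)
        raise
    return manifest


def load_training_set(directory: str | Path):
    """Load (X, y, model_idx, val_mask, manifest) written by build_training_set."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    with np.load(directory / "tensors.npz") as data:
        return data["X"], data["y"], data["model_idx"], data["val_mask"], manifest
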