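"""Self-contained truth-annotated synthetic two-species cohorts.

Generates everything the pipeline consumes — a raw VCF with quality
annotations and missing genotypes, a phased/imputed VCF, gene and repeat
BED tracks, a per-individual 10-kbp depth table, a chromosome-length table
— plus a TruthSet recording where introgressed tracts were simulated.  All
randomness flows from one master seed through named per-chromosome
sub-streams, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demography import DemographicModel
from .intervals import merge_intervals
from .scenario_simulator import LabelledExample, ScenarioSpec, draw_scenario, simulate_example
from .vcf_io import VcfRecord, write_bed, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class CohortConfig:
    """Shape of the synthetic cohort; defaults mirror the study design."""

    individuals_per_population: tuple[int, int] = (22, 20)
    n_chromosomes: int = 18
    chromosome_lengths: list[int] | None = None  # default: 20 Mbp .. 3 Mbp ladder
    low_depth_individuals: tuple[int, int] = (12, 12)
    mean_depth_high: float = 20.0
    mean_depth_low: float = 5.0
    missing_rate: float = 0.02
    depth_window_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.individuals_per_population):
            raise ValueError("individual counts must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if self.chromosome_lengths is None:
            # descending ladder so length-vs-introgression correlations have spread
            self.chromosome_lengths = [
                int(x) for x in np.linspace(20e6, 3e6, self.n_chromosomes)
            ]
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths length must equal n_chromosomes")
        if any(x <= 0 for x in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for k, n in zip(self.low_depth_individuals, self.individuals_per_population):
            if k > n:
                raise ValueError("low-depth count exceeds population size")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class Tract:
    chromosome: str
    bp_start: int
    bp_end: int
    recipient: str
    donor: str
    haplotypes: list[int] = field(default_factory=list)


@dataclass
class TruthSet:
    """Known introgressed tracts and their carrier haplotypes."""

    tracts: list[Tract] = field(default_factory=list)

    def intervals(self, chromosome: str) -> list[tuple[int, int]]:
        return merge_intervals(
            (t.bp_start, t.bp_end) for t in self.tracts if t.chromosome == chromosome
        )

    def overlaps(self, chromosome: str, bp_start: int, bp_end: int) -> bool:
        return any(
            t.chromosome == chromosome and t.bp_start < bp_end and bp_start < t.bp_end
            for t in self.tracts
        )

    def to_json(self, path: str | Path) -> None:
        rows = [
            {
                "chromosome": t.chromosome,
                "bp_start": t.bp_start,
                "bp_end": t.bp_end,
                "recipient": t.recipient,
                "donor": t.donor,
                "haplotypes": t.haplotypes,
            }
            for t in self.tracts
        ]
        Path(path).write_text(json.dumps(rows, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        rows = json.loads(Path(path).read_text())
        return cls([Tract(**r) for r in rows])


def generate_annotations(
    config: CohortConfig,
    gene_density: float,
    rng: np.random.Generator,
    mean_feature_bp: int = 30_000,
) -> dict[str, list[tuple[int, int]]]:
    """Random non-overlapping half-open feature intervals at a target density.

    Alternates exponential gaps and feature lengths so the covered fraction
    converges to ``gene_density`` for large genomes.
    """
    if not (0 <= gene_density <= 1):
        raise ValueError("gene_density must be in [0, 1]")
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chromosome_names}
    if gene_density == 0:
        return out
    mean_gap = mean_feature_bp * (1 - gene_density) / gene_density if gene_density < 1 else 0.0
    for chrom, length in zip(config.chromosome_names, config.chromosome_lengths):
        pos = 0
        while True:
            pos += int(rng.exponential(mean_gap)) if mean_gap else 0
            feat = max(1, int(rng.exponential(mean_feature_bp)))
            if pos >= length:
                break
            end = min(pos + feat, length)
            out[chrom].append((pos, end))
            pos = end + 1
    return out


@dataclass
class CohortResult:
    config: CohortConfig
    vcf: Path
    phased_vcf: Path
    gene_bed: Path
    repeat_bed: Path
    depth_table: Path
    chrom_lengths: Path
    truth_json: Path
    truth: TruthSet
    examples: dict[str, LabelledExample]
    scenarios: dict[str, ScenarioSpec]


def _site_annotations(n_sites: int, rng: np.random.Generator):
    """Plausible FS/MQ/QD values, with a small failing tail per statistic."""
    fs = rng.exponential(8.0, n_sites)
    mq = np.clip(rng.normal(60.0, 3.0, n_sites), 0.1, None)
    qd = np.clip(rng.normal(20.0, 6.0, n_sites), 0.1, None)
    bad = rng.random(n_sites) < 0.02
    which = rng.integers(0, 3, n_sites)
    fs = np.where(bad & (which == 0), rng.uniform(60, 200, n_sites), fs)
    mq = np.where(bad & (which == 1), rng.uniform(5, 40, n_sites), mq)
    qd = np.where(bad & (which == 2), rng.uniform(0.1, 5.99, n_sites), qd)
    return fs, mq, qd


def _tracts_from_example(
    example: LabelledExample, chrom: str, populations: tuple[str, str]
) -> list[Tract]:
    p1, p2 = populations
    tracts = []
    for direction, spans in example.donor_spans.items():
        recipient, donor = (p1, p2) if direction == "ELtoIL" else (p2, p1)
        merged = merge_intervals((int(l), max(int(r), int(l) + 1)) for l, r, _ in spans)
        for s, e in merged:
            carriers = sorted(
                {h for l, r, h in spans if int(l) < e and s < max(int(r), int(l) + 1)}
            )
            tracts.append(Tract(chrom, s, e, recipient, donor, carriers))
    return tracts


def generate_cohort(
    config: CohortConfig,
    model: DemographicModel,
    scenario_mix: dict[str, float],
    out_dir: str | Path,
    mutation_scale: float = 1.0,
    recombination_rate: float = 1e-8,
    min_sites: int = 2,
    max_attempts: int = 20,
) -> CohortResult:
    """Simulate and write a full synthetic cohort with known truth.

    ``scenario_mix`` gives the probability of each scenario label per
    chromosome.  Chromosomes with zero segregating sites are resimulated
    with a fresh sub-seed up to ``max_attempts`` times.
    """
    if abs(sum(scenario_mix.values()) - 1.0) > 1e-9:
        raise ValueError("scenario_mix probabilities must sum to 1")
    unknown = set(scenario_mix) - {"ELtoIL", "ILtoEL", "BiDir", "none"}
    if unknown:
        raise ValueError(f"unknown scenario labels: {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n1, n2 = config.individuals_per_population
    p1, p2 = model.populations
    master = np.random.SeedSequence(config.seed)
    labels = sorted(scenario_mix)
    probs = np.array([scenario_mix[k] for k in labels])

    examples: dict[str, LabelledExample] = {}
    scenarios: dict[str, ScenarioSpec] = {}
    truth = TruthSet()
    for ci, (chrom, length) in enumerate(
        zip(config.chromosome_names, config.chromosome_lengths)
    ):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, ci)))
        label = labels[rng.choice(len(labels), p=probs)]
        spec = draw_scenario(label, rng)
        example = simulate_example(
            model,
            spec,
            samples=(n1, n2),
            rng=rng,
            region_bp=float(length),
            window_snps=min_sites,
            recombination_rate=recombination_rate,
            mutation_scale=mutation_scale,
            max_attempts=max_attempts,
            chromosome=chrom,
            require_tract_in_window=False,
        )
        examples[chrom] = example
        scenarios[chrom] = spec
        truth.tracts.extend(_tracts_from_example(example, chrom, (p1, p2)))

    # ------------------------------------------------------------------
    # emit artifacts
    # ------------------------------------------------------------------
    sample_names = [f"{p1}_{i:02d}" for i in range(n1)] + [
        f"{p2}_{i:02d}" for i in range(n2)
    ]
    contigs = dict(zip(config.chromosome_names, config.chromosome_lengths))

    def records(with_noise: bool):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
        for chrom in config.chromosome_names:
            aln = examples[chrom].alignment
            n_sites = aln.n_sites
            fs, mq, qd = _site_annotations(n_sites, rng)
            ref_idx = rng.integers(0, 4, n_sites)
            refs = _BASES[ref_idx]
            alts = _BASES[(ref_idx + rng.integers(1, 4, n_sites)) % 4]
            miss = (
                rng.random((n_sites, n1 + n2)) < config.missing_rate
                if with_noise
                else np.zeros((n_sites, n1 + n2), dtype=bool)
            )
            for s in range(n_sites):
                gt = aln.matrix[:, s].reshape(-1, 2).copy()
                gt[miss[s]] = -1
                yield VcfRecord(
                    chromosome=chrom,
                    position=int(aln.positions[s]) + 1,
                    ref=str(refs[s]),
                    alts=(str(alts[s]),),
                    genotypes=gt,
                    phased=~miss[s],
                    fs=float(fs[s]),
                    mq=float(mq[s]),
                    qd=float(qd[s]),
                )

    vcf_path = out_dir / "cohort.vcf"
    phased_path = out_dir / "cohort.phased.vcf"
    write_vcf(vcf_path, sample_names, records(with_noise=True), contigs)
    write_vcf(phased_path, sample_names, records(with_noise=False), contigs)

    ann_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    genes = generate_annotations(config, 0.3, ann_rng)
    repeats = generate_annotations(config, 0.1, ann_rng, mean_feature_bp=5_000)
    gene_bed = out_dir / "genes.bed"
    repeat_bed = out_dir / "repeats.bed"
    write_bed(gene_bed, genes)
    write_bed(repeat_bed, repeats)

    depth_path = out_dir / "depth.tsv"
    _write_depth_table(config, sample_names, depth_path)

    chrom_path = out_dir / "chromosomes.tsv"
    with open(chrom_path, "w") as fh:
        for chrom, length in contigs.items():
            fh.write(f"{chrom}\t{length}\n")

    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)

    return CohortResult(
        config=config,
        vcf=vcf_path,
        phased_vcf=phased_path,
        gene_bed=gene_bed,
        repeat_bed=repeat_bed,
        depth_table=depth_path,
        chrom_lengths=chrom_path,
        truth_json=truth_path,
        truth=truth,
        examples=examples,
        scenarios=scenarios,
    )


def _write_depth_table(config: CohortConfig, sample_names: list[str], path: Path) -> None:
    """Per-individual mean depth in consecutive 10-kbp windows.

    The first ``low_depth_individuals`` of each population get the low mean;
    ~1% of windows are inflated 3x across all individuals (collapsed-paralog
    signal for the depth filter).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(4,)))
    n1, n2 = config.individuals_per_population
    k1, k2 = config.low_depth_individuals
    means = np.array(
        [config.mean_depth_low] * k1 + [config.mean_depth_high] * (n1 - k1)
        + [config.mean_depth_low] * k2 + [config.mean_depth_high] * (n2 - k2)
    )
    with open(path, "w") as fh:
        fh.write("individual\tchromosome\twindow_start\tmean_depth\n")
        for chrom, length in zip(config.chromosome_names, config.chromosome_lengths):
            n_windows = max(1, length // config.depth_window_bp)
            inflate = rng.random(n_windows) < 0.01
            for w in range(n_windows):
                depths = rng.gamma(8.0, means / 8.0)
                if inflate[w]:
                    depths = depths * 3.0
                start = w * config.depth_window_bp
                for name, d in zip(sample_names, depths):
                    fh.write(f"{name}\t{chrom}\t{start}\t{d:.3f}\n")
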