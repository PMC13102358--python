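"""End-to-end orchestration: synth -> simulate -> train -> scan -> stats.

Each stage writes its artifacts under the run directory plus a manifest
fragment (inputs, output hashes, seed); fragments chain by hashing the
previous fragment so a completed run validates end to end.  Stages are
individually resumable from the artifacts of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .caller import CallerConfig, MergedRegion, WindowCall, call_windows, genome_fraction, merge_calls
from .demography import load_fixture_model
from .discriminator import TrainConfig, predict, train
from .evaluation import build_evaluation_set, evaluate_thresholds
from .landscape_stats import compare_groups, random_null, window_stats
from .nn import ResNetClassifier
from .scenario_simulator import build_training_set, load_training_set
from .synthetic_data import CohortConfig, generate_cohort
from .tensor_encoder import encode_alignment
from .vcf_io import read_bed, read_haplotypes

STAGES = ("synth", "simulate", "train", "scan", "evaluate", "stats")

DEFAULT_CONFIG = {
    "pair": "ILa-ELw",
    "model_indices": [1, 2, 3],
    "seed": 0,
    "samples": [8, 6],
    "window_snps": 32,
    "step_snps": 16,
    "region_bp": 2e5,
    "mutation_scale": 20.0,
    "recombination_rate": 1e-8,
    "n_per_scenario": 50,
    "n_eval_per_scenario": 25,
    "preset": "desk",
    "max_epochs": 4,
    "steps_per_epoch": 60,
    "batch_size": 16,
    "p_threshold": 0.9,
    "p_neighbor": 0.7,
    "cohort": {"n_chromosomes": 4, "chromosome_lengths": None, "missing_rate": 0.02},
    "scenario_mix": {"none": 0.5, "ELtoIL": 0.25, "ILtoEL": 0.25},
    "null_replicates": 20,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _require(path: Path, stage: str, prerequisite: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires {path.name} — run the {prerequisite!r} stage first"
        )
    return path


def run_pipeline(out_dir: str | Path, stages=STAGES, config: dict | None = None) -> dict:
    """Run the requested stages, returning the combined run manifest."""
    cfg = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )
    manifest["config"] = cfg
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        outputs = _STAGE_FNS[stage](out_dir, cfg)
        prev = list(manifest["stages"].values())
        fragment = {
            "seed": cfg["seed"],
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
            "prev_hash": hashlib.sha256(
                json.dumps(prev[-1], sort_keys=True).encode()
            ).hexdigest() if prev else None,
        }
        manifest["stages"][stage] = fragment
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def validate_manifest(manifest: dict) -> bool:
    """Check the fragment hash chain of a completed run."""
    fragments = list(manifest["stages"].values())
    for prev, cur in zip(fragments, fragments[1:]):
        expected = hashlib.sha256(json.dumps(prev, sort_keys=True).encode()).hexdigest()
        if cur["prev_hash"] != expected:
            return False
    return True


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def _models(cfg):
    return [load_fixture_model(cfg["pair"], i) for i in cfg["model_indices"]]


def _stage_synth(out_dir: Path, cfg: dict) -> list[Path]:
    cohort_cfg = CohortConfig(seed=cfg["seed"], **{
        k: v for k, v in cfg["cohort"].items() if v is not None or k != "chromosome_lengths"
    })
    result = generate_cohort(
        cohort_cfg,
        _models(cfg)[0],
        cfg["scenario_mix"],
        out_dir / "cohort",
        mutation_scale=cfg["mutation_scale"],
        recombination_rate=cfg["recombination_rate"],
    )
    return [result.vcf, result.phased_vcf, result.gene_bed, result.repeat_bed,
            result.depth_table, result.chrom_lengths, result.truth_json]


def _stage_simulate(out_dir: Path, cfg: dict) -> list[Path]:
    sims = out_dir / "sims"
    build_training_set(
        _models(cfg),
        cfg["n_per_scenario"],
        tuple(cfg["samples"]),
        sims,
        seed=cfg["seed"],
        region_bp=cfg["region_bp"],
        window_snps=cfg["window_snps"],
        recombination_rate=cfg["recombination_rate"],
        mutation_scale=cfg["mutation_scale"],
    )
    return [sims / "tensors.npz", sims / "manifest.json"]


def _stage_train(out_dir: Path, cfg: dict) -> list[Path]:
    sims = out_dir / "sims"
    _require(sims / "tensors.npz", "train", "simulate")
    x, y, _, val_mask, _ = load_training_set(sims)
    net, history = train(
        x, y, config=TrainConfig(
            max_epochs=cfg["max_epochs"],
            steps_per_epoch=cfg["steps_per_epoch"],
            batch_size=cfg["batch_size"],
            patience=min(10, cfg["max_epochs"]),
            seed=cfg["seed"],
        ),
        val_mask=val_mask,
        preset=cfg["preset"],
    )
    ckpt = out_dir / "discriminator.npz"
    net.save(ckpt, extra={"preset": cfg["preset"]})
    hist = out_dir / "history.csv"
    history.to_csv(hist)
    return [ckpt, hist]


def scan_alignments(alignments, net, cfg) -> tuple[list[WindowCall], list[MergedRegion]]:
    """Encode, predict and call sliding windows over per-chromosome alignments."""
    calls: list[WindowCall] = []
    for chrom in sorted(alignments):
        aln = alignments[chrom]
        tensors = encode_alignment(
            aln,
            window_snps=cfg["window_snps"],
            step_snps=cfg["step_snps"],
            seed=cfg["seed"],
        )
        if not tensors:
            continue
        probs = predict(net, np.stack([t.array for t in tensors]))
        for t, p in zip(tensors, probs):
            calls.append(
                WindowCall(
                    chromosome=chrom,
                    bp_start=t.bp_start,
                    bp_end=t.bp_end,
                    snp_start=t.snp_start,
                    snp_end=t.snp_end,
                    probabilities=p,
                )
            )
    called = call_windows(calls, CallerConfig(cfg["p_threshold"], cfg["p_neighbor"]))
    return called, merge_calls(called)


def _stage_scan(out_dir: Path, cfg: dict) -> list[Path]:
    ckpt = _require(out_dir / "discriminator.npz", "scan", "train")
    phased = _require(out_dir / "cohort" / "cohort.phased.vcf", "scan", "synth")
    net, _ = ResNetClassifier.load(ckpt)
    n1 = cfg["cohort"].get(
        "individuals_per_population", CohortConfig().individuals_per_population
    )[0]
    alignments = read_haplotypes(phased, n1)
    called, regions = scan_alignments(alignments, net, cfg)

    windows_bed = out_dir / "windows.bed"
    with open(windows_bed, "w") as fh:
        for w in called:
            probs = ",".join(f"{p:.4f}" for p in w.probabilities)
            fh.write(
                f"{w.chromosome}\t{w.bp_start}\t{w.bp_end}\t{w.assigned}\t{w.stage}\t{probs}\n"
            )
    regions_bed = out_dir / "regions.bed"
    with open(regions_bed, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.bp_start}\t{r.bp_end}\t{r.assigned}\t{r.n_windows}\n")
    lengths = _chrom_lengths(out_dir)
    fractions = genome_fraction(regions, lengths)
    fractions_json = out_dir / "fractions.json"
    fractions_json.write_text(json.dumps(fractions, indent=2) + "\n")
    return [windows_bed, regions_bed, fractions_json]


def _chrom_lengths(out_dir: Path) -> dict[str, int]:
    out = {}
    for line in (out_dir / "cohort" / "chromosomes.tsv").read_text().splitlines():
        chrom, length = line.split("\t")
        out[chrom] = int(length)
    return out


def _stage_evaluate(out_dir: Path, cfg: dict) -> list[Path]:
    ckpt = _require(out_dir / "discriminator.npz", "evaluate", "train")
    net, _ = ResNetClassifier.load(ckpt)
    rng = np.random.default_rng(cfg["seed"] + 1)
    x, y = build_evaluation_set(
        _models(cfg)[0],
        cfg["n_eval_per_scenario"],
        tuple(cfg["samples"]),
        rng,
        window_snps=cfg["window_snps"],
        region_bp=cfg["region_bp"],
        recombination_rate=cfg["recombination_rate"],
        mutation_scale=cfg["mutation_scale"],
    )
    probs = predict(net, x)
    reports = evaluate_thresholds(probs, y)
    path = out_dir / "evaluation.json"
    path.write_text(
        json.dumps({str(p): r.to_dict() for p, r in reports.items()}, indent=2) + "\n"
    )
    return [path]


def _stage_stats(out_dir: Path, cfg: dict) -> list[Path]:
    regions_bed = _require(out_dir / "regions.bed", "stats", "scan")
    phased = _require(out_dir / "cohort" / "cohort.phased.vcf", "stats", "synth")
    lengths = _chrom_lengths(out_dir)
    genes = read_bed(out_dir / "cohort" / "genes.bed")
    n1 = cfg["cohort"].get(
        "individuals_per_population", CohortConfig().individuals_per_population
    )[0]
    alignments = read_haplotypes(phased, n1)

    observed = []
    for line in regions_bed.read_text().splitlines():
        chrom, s, e = line.split("\t")[:3]
        observed.append((chrom, int(s), int(e)))
    rng = np.random.default_rng(cfg["seed"] + 2)
    results: dict = {"n_regions": len(observed)}
    if observed:
        def haps(windows):
            out = []
            for chrom, s, e in windows:
                aln = alignments.get(chrom)
                if aln is None:
                    out.append(None)
                    continue
                cols = (aln.positions >= s) & (aln.positions < e)
                out.append(aln.matrix[:, cols] if cols.any() else None)
            return out

        obs_stats = window_stats(observed, haps(observed), lengths, genes)
        null_sets = random_null(
            [e - s for _, s, e in observed], lengths, rng,
            replicates=cfg["null_replicates"],
        )
        pooled = [w for rep in null_sets for w in rep]
        null_stats = window_stats(pooled, haps(pooled), lengths, genes)
        for key in ("pi", "telomere_distance", "gene_overlap"):
            obs, nul = obs_stats[key], null_stats[key]
            if obs.size and nul.size and (obs > 0).any() | (nul > 0).any():
                try:
                    c = compare_groups(obs, nul)
                    results[key] = {"cohens_d": c.cohens_d, "p_value": c.p_value}
                except ValueError as err:
                    results[key] = {"error": str(err)}
    path = out_dir / "stats.json"
    path.write_text(json.dumps(results, indent=2) + "\n")
    return [path]


_STAGE_FNS = {
    "synth": _stage_synth,
    "simulate": _stage_simulate,
    "train": _stage_train,
    "scan": _stage_scan,
    "evaluate": _stage_evaluate,
    "stats": _stage_stats,
}
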