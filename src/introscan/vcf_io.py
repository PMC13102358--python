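"""VCF 4.2 reading and writing.

Reading goes through cyvcf2; writing emits plain-text VCF.  Internal
coordinates are 0-based half-open; the 1-based VCF convention is converted
at this boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from cyvcf2 import VCF

from .tensor_encoder import HaplotypeAlignment

VCF_HEADER_LINES = [
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


@dataclass
class VcfRecord:
    """One site: 1-based position, alleles, optional quality annotations,
    genotype calls as an (n_individuals, 2) array with -1 for missing, and a
    per-individual phased flag."""

    chromosome: str
    position: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray
    phased: np.ndarray | bool = True
    fs: float | None = None
    mq: float | None = None
    qd: float | None = None

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
            and self.ref != self.alts[0]
        )


def write_vcf(
    path: str | Path,
    sample_names: list[str],
    records: Iterable[VcfRecord],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan\n")
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for rec in records:
            info = []
            for key, value in (("FS", rec.fs), ("MQ", rec.mq), ("QD", rec.qd)):
                if value is not None:
                    info.append(f"{key}={value:.2f}")
            phased = rec.phased
            if isinstance(phased, (bool, np.bool_)):
                phased = np.full(len(rec.genotypes), bool(phased))
            gts = []
            for (a, b), ph in zip(rec.genotypes, phased):
                sep = "|" if ph else "/"
                sa = "." if a < 0 else str(int(a))
                sb = "." if b < 0 else str(int(b))
                gts.append(f"{sa}{sep}{sb}")
            fh.write(
                f"{rec.chromosome}\t{rec.position}\t.\t{rec.ref}\t"
                f"{','.join(rec.alts)}\t.\tPASS\t{';'.join(info) or '.'}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_records(path: str | Path) -> Iterator[VcfRecord]:
    """Stream records with genotypes and FS/MQ/QD annotations (None if absent)."""
    vcf = VCF(str(path))
    try:
        for v in vcf:
            genotypes = np.array([[g[0], g[1]] for g in v.genotypes], dtype=np.int8)
            phased = np.array([bool(g[2]) for g in v.genotypes])
            def _info(key):
                value = v.INFO.get(key)
                return None if value is None else float(value)
            yield VcfRecord(
                chromosome=v.CHROM,
                position=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                genotypes=genotypes,
                phased=phased,
                fs=_info("FS"),
                mq=_info("MQ"),
                qd=_info("QD"),
            )
    finally:
        vcf.close()


def read_haplotypes(path: str | Path, n_pop1_individuals: int) -> dict[str, HaplotypeAlignment]:
    """Load a fully phased biallelic VCF into per-chromosome alignments.

    The first ``n_pop1_individuals`` sample columns form population 1.
    Missing or unphased genotypes are an error: alignments are built from
    phased, imputed data.
    """
    per_chrom: dict[str, tuple[list, list]] = {}
    for rec in read_records(path):
        if not rec.is_biallelic_snp:
            continue
        if (rec.genotypes < 0).any():
            raise ValueError(
                f"missing genotype at {rec.chromosome}:{rec.position}; "
                "phased input must be imputed"
            )
        cols, pos = per_chrom.setdefault(rec.chromosome, ([], []))
        cols.append(rec.genotypes.reshape(-1))
        pos.append(rec.position - 1)
    out = {}
    for chrom, (cols, pos) in per_chrom.items():
        out[chrom] = HaplotypeAlignment(
            matrix=np.array(cols, dtype=np.int8).T,
            positions=np.array(pos, dtype=np.int64),
            chromosome=chrom,
            n_pop1=2 * n_pop1_individuals,
        )
    return out


# ----------------------------------------------------------------------
# BED and simple tables
# ----------------------------------------------------------------------

def write_bed(path: str | Path, intervals: dict[str, list[tuple[int, int]]], names: dict | None = None) -> None:
    """Write 0-based half-open intervals, sorted by chromosome then start."""
    with open(path, "w") as fh:
        for chrom in intervals:
            for iv in sorted(intervals[chrom]):
                fields = [chrom, str(iv[0]), str(iv[1])]
                if len(iv) > 2:
                    fields.extend(str(x) for x in iv[2:])
                fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return out
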