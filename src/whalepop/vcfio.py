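"""VCF 4.2 emission and parsing for the genotype Dataset.

Annotations travel in INFO (``ANN_CLASS``, ``SIFT``, ``AA``); genotypes are
FORMAT ``GT`` (with placeholder ``DP``/``GQ`` columns for tool
compatibility).  Internally coordinates are 0-based half-open; VCF POS is
1-based.  Only biallelic SNP records are read back: multi-allelic records
are skipped with a warning and counted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .dataset import ANN_CODE, ANNOTATIONS, Dataset, MISSING

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: Dataset, path: str | Path) -> None:
    """Write the dataset as an uncompressed VCF 4.2 text file."""
    path = Path(path)
    names = [f"{p}{i:03d}" for i, p in enumerate(ds.pop_labels)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ds.contig},length={max(ds.seq_len, 1)}>\n")
        fh.write('##INFO=<ID=ANN_CLASS,Number=1,Type=String,'
                 'Description="Functional class: NEU/SYN/TOL/DEL/LOF">\n')
        fh.write('##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">\n')
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for pop in ds.populations:
            idx = ds.individuals_of(pop)
            fh.write(f"##SAMPLE_POP=<Population={pop},Samples="
                     f"{','.join(names[i] for i in idx)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j in range(ds.n_sites):
            info = [f"ANN_CLASS={ANNOTATIONS[ds.annotation[j]]}"]
            if np.isfinite(ds.sift_score[j]):
                info.append(f"SIFT={ds.sift_score[j]:.6g}")
            if ds.ancestral_known[j]:
                info.append("AA=A")
            gts = "\t".join(_GT[int(g)] + ":.:." for g in ds.genotypes[:, j])
            fh.write(
                f"{ds.contig}\t{ds.positions[j] + 1}\t.\tA\tT\t.\tPASS\t"
                f"{';'.join(info)}\tGT:DP:GQ\t{gts}\n"
            )


def read_vcf(path: str | Path, pop_labels=None) -> tuple[Dataset, int]:
    """Parse a VCF into a Dataset; returns (dataset, n_skipped_multiallelic).

    Population labels are recovered from the ``##SAMPLE_POP`` header lines
    written by :func:`write_vcf` unless given explicitly.
    """
    path = Path(path)
    header_pop: dict[str, str] = {}
    contig_len = 0
    contig = "1"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##SAMPLE_POP"):
                body = line.strip()[len("##SAMPLE_POP=<"):-1]
                fields = dict(kv.split("=", 1) for kv in body.split(",", 1))
                for s in fields["Samples"].split(","):
                    header_pop[s] = fields["Population"]
            if line.startswith("##contig"):
                body = line.strip()[len("##contig=<"):-1]
                fields = dict(kv.split("=", 1) for kv in body.split(","))
                contig = fields.get("ID", "1")
                contig_len = int(fields.get("length", 0))
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF: {exc}") from exc
    samples = vcf.samples
    genos, pos, ann, sift, aa = [], [], [], [], []
    n_skipped = 0
    for line_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            n_skipped += 1
            warnings.warn(
                f"skipping multi-allelic record at {var.CHROM}:{var.POS}"
            )
            continue
        g = var.genotype.array()[:, :2]
        dip = np.where((g < 0).any(axis=1), MISSING, g.clip(min=0).sum(axis=1))
        genos.append(dip.astype(np.int8))
        pos.append(var.POS - 1)
        ann.append(ANN_CODE.get(var.INFO.get("ANN_CLASS", "NEU"), 0))
        s = var.INFO.get("SIFT")
        sift.append(np.nan if s is None else float(s))
        aa.append(var.INFO.get("AA") is not None)
    vcf.close()
    if pop_labels is None:
        pop_labels = [header_pop.get(s, "pop") for s in samples]
    n = len(samples)
    ds = Dataset(
        genotypes=np.array(genos, dtype=np.int8).T if genos else np.zeros((n, 0), np.int8),
        positions=np.array(pos, dtype=np.int64),
        pop_labels=np.asarray(pop_labels),
        annotation=np.array(ann, dtype=np.int8),
        sift_score=np.array(sift, dtype=float),
        ancestral_known=np.array(aa, dtype=bool),
        seq_len=contig_len,
        contig=contig,
    )
    return ds, n_skipped
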