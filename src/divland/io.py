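"""Readers and writers for the standard input formats.

VCF is read with cyvcf2 (biallelic SNP records, per-sample GT); BED
files are 0-based half-open; recombination maps and landscape tables are
plain TSV.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .landscapes import AlleleTable

__all__ = ["read_vcf", "read_bed", "write_bed", "read_populations", "write_populations"]


def read_bed(path: str) -> np.ndarray:
    """Read a BED file into an (n, 2) array of 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append((int(parts[1]), int(parts[2])))
    return np.asarray(rows, dtype=np.int64).reshape(-1, 2)


def write_bed(intervals: np.ndarray, chrom: str, path: str) -> None:
    with open(path, "w") as fh:
        for s, e in np.asarray(intervals, dtype=np.int64).reshape(-1, 2):
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_populations(path: str) -> dict[str, list[str]]:
    """Read a sample-to-population TSV (columns: sample, population)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for sample, pop in zip(df["sample"], df["population"]):
        out.setdefault(pop, []).append(sample)
    return out


def write_populations(pops: Mapping[str, list[str]], path: str) -> None:
    rows = [{"sample": s, "population": p} for p in pops for s in pops[p]]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf(path: str, populations: Mapping[str, list[str]], outgroup_info_key: str = "AA") -> AlleleTable:
    """Read biallelic SNPs from a VCF into an :class:`AlleleTable`.

    ``populations`` maps population name to VCF sample names.  The
    outgroup (ancestral) allele, where present, is taken from the INFO
    field ``outgroup_info_key``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    idx = {p: np.array([samples.index(s) for s in names]) for p, names in populations.items()}

    positions, refs, alts, outg = [], [], [], []
    alt_counts: dict[str, list[int]] = {p: [] for p in populations}
    called: dict[str, list[int]] = {p: [] for p in populations}
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1:
            continue
        gt = rec.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        aa = rec.INFO.get(outgroup_info_key)
        outg.append(aa if aa in ("A", "C", "G", "T") else "")
        for p, ii in idx.items():
            g = gt[ii]
            ok = g != 3
            alt_counts[p].append(int(g[ok].sum()))
            called[p].append(int(2 * ok.sum()))
    return AlleleTable(
        np.asarray(positions),
        np.asarray(refs),
        np.asarray(alts),
        {p: np.asarray(v) for p, v in alt_counts.items()},
        {p: np.asarray(v) for p, v in called.items()},
        {p: len(v) for p, v in populations.items()},
        np.asarray(outg),
    )
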