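"""Reading and writing the package's on-disk formats.

VCF 4.2 is the interchange format for genotypes and allele depths
(cyvcf2 for reading, plain-text writing for generated data); truth
karyotypes, diagnostics, site depths and segments travel as TSV.
All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "write_genotype_vcf",
    "write_depth_vcf",
    "read_genotype_vcf",
    "read_depth_vcf",
    "read_vcf_samples",
]

_META_COLS = ["chrom", "pos", "ref", "alt"]


def _vcf_header(chrom_lengths: dict[str, int] | None, samples: Sequence[str], fields: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=musakaryo"]
    if chrom_lengths:
        for name, length in chrom_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if "AD" in fields:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Per-allele read depths">'
        )
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return "\n".join(lines) + "\n"


def _gt_string(dosage: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1"}.get(dosage, "./.")


def write_genotype_vcf(
    genotypes: pd.DataFrame,
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write a multi-sample genotype table (alt dosages) as VCF with GT.

    ``genotypes`` has columns ``chrom, pos, ref, alt`` plus one dosage
    column per sample (0/1/2, -1 = missing).
    """
    samples = [c for c in genotypes.columns if c not in _META_COLS]
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_lengths, samples, "GT"))
        for row in genotypes.itertuples(index=False):
            rec = dict(zip(genotypes.columns, row))
            gts = "\t".join(_gt_string(int(rec[s])) for s in samples)
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t{rec['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_depth_vcf(
    depth_tables: dict[str, pd.DataFrame],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write per-accession allele-depth tables as one multi-sample VCF.

    ``depth_tables`` maps accession id to a table with columns
    ``chrom, pos, ref, alt, ad_ref, ad_alt``. Sites are the union over
    accessions; accessions without data at a site get missing entries.
    """
    samples = list(depth_tables)
    site_records: dict[tuple[str, int], tuple[str, str]] = {}
    per_sample: dict[str, dict[tuple[str, int], tuple[int, int]]] = {s: {} for s in samples}
    for s, tab in depth_tables.items():
        for row in tab.itertuples(index=False):
            key = (str(row.chrom), int(row.pos))
            site_records.setdefault(key, (str(row.ref), str(row.alt)))
            per_sample[s][key] = (int(row.ad_ref), int(row.ad_alt))
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_lengths, samples, "GT:AD:DP"))
        for (chrom, pos) in sorted(site_records):
            ref, alt = site_records[(chrom, pos)]
            cells = []
            for s in samples:
                ad = per_sample[s].get((chrom, pos))
                if ad is None:
                    cells.append("./.:.:.")
                    continue
                ad_ref, ad_alt = ad
                if ad_ref > 0 and ad_alt > 0:
                    gt = "0/1"
                elif ad_alt > 0:
                    gt = "1/1"
                else:
                    gt = "0/0"
                cells.append(f"{gt}:{ad_ref},{ad_alt}:{ad_ref + ad_alt}")
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT:AD:DP\t" + "\t".join(cells) + "\n"
            )


def read_vcf_samples(path: str | Path) -> list[str]:
    """Sample names of a VCF."""
    return list(VCF(str(path)).samples)


def read_genotype_vcf(path: str | Path, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Read biallelic SNP genotypes as an alt-dosage table.

    Returns columns ``chrom, pos, ref, alt`` plus one dosage column per
    sample (0/1/2, -1 = missing). Non-biallelic records are skipped.
    """
    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if samples is None:
        samples = all_samples
    idx = [all_samples.index(s) for s in samples]
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        g = var.gt_types
        dosage = np.select([g == 0, g == 1, g == 3], [0, 1, 2], default=-1)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], *dosage[idx]))
    return pd.DataFrame(rows, columns=_META_COLS + list(samples))


def read_depth_vcf(path: str | Path, sample: str) -> pd.DataFrame:
    """Read one sample's per-allele depths from a VCF with AD.

    Returns columns ``chrom, pos, ref, alt, ad_ref, ad_alt``; sites
    where the sample has no depth data are dropped. Raises on records
    lacking the AD format field.
    """
    vcf = VCF(str(path))
    try:
        si = list(vcf.samples).index(sample)
    except ValueError:
        raise ValueError(f"sample {sample!r} not in {path}") from None
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"record {var.CHROM}:{var.POS} has no AD field")
        ad_ref, ad_alt = int(ad[si][0]), int(ad[si][1])
        if ad_ref < 0 or ad_alt < 0:  # missing entry
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], ad_ref, ad_alt))
    return pd.DataFrame(rows, columns=_META_COLS + ["ad_ref", "ad_alt"])
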