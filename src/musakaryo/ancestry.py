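"""Ancestry-diagnostic alleles and per-site A/B read counts.

The karyotyping method rests on assigning SNP alleles to the two
ancestral gene pools (*M. acuminata* = A, *M. balbisiana* = B). An
allele is *diagnostic* for a pool when it is (nearly) fixed there and
(nearly) absent from the other pool. Reads carrying diagnostic alleles
in a target accession are then counted per site as A-assigned and
B-assigned depth; the B-read fraction along a chromosome is the primary
dosage observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticAllele",
    "identify_diagnostic_alleles",
    "assign_site_depths",
    "extract_het_sites",
    "diagnostics_to_frame",
    "frame_to_diagnostics",
]


@dataclass(frozen=True, order=True)
class DiagnosticAllele:
    """An allele assigned to one ancestral pool.

    Attributes
    ----------
    chrom, pos : str, int
        Site coordinates (1-based).
    allele : str
        The diagnostic base(s).
    ancestry : str
        ``"A"`` or ``"B"``.
    """

    chrom: str
    pos: int
    allele: str
    ancestry: str

    def __post_init__(self) -> None:
        if self.ancestry not in ("A", "B"):
            raise ValueError(f"ancestry must be 'A' or 'B', got {self.ancestry!r}")


def _pool_allele_freq(genotypes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and call rate per site from a dosage matrix.

    ``genotypes`` holds alt-allele dosages (0/1/2) with -1 for missing,
    sites in rows, accessions in columns.
    """
    g = genotypes.to_numpy(dtype=float)
    g[g < 0] = np.nan
    called = np.sum(~np.isnan(g), axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(g, axis=1) / (2.0 * called)
    freq[called == 0] = np.nan
    call_rate = called / g.shape[1]
    return freq, call_rate


def identify_diagnostic_alleles(
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    *,
    min_own_pool_freq: float = 0.95,
    max_other_pool_freq: float = 0.02,
    max_missing: float = 0.2,
) -> list[DiagnosticAllele]:
    """Identify alleles private to the A or B ancestral pool.

    Parameters
    ----------
    panel_a, panel_b : pandas.DataFrame
        Per-pool genotype tables sharing the same site rows, with
        columns ``chrom``, ``pos``, ``ref``, ``alt`` followed by one
        alt-dosage column per panel accession (0/1/2, -1 = missing).
        Only biallelic SNP rows are expected (split multiallelics
        upstream).
    min_own_pool_freq : float
        Minimum frequency of the allele in its own pool.
    max_other_pool_freq : float
        Maximum frequency tolerated in the opposite pool.
    max_missing : float
        Maximum fraction of missing genotype calls per pool at a site.

    Returns
    -------
    list of DiagnosticAllele
        Sorted by (chrom, pos, allele). Both alleles of one site may be
        diagnostic, necessarily for opposite pools: mutual exclusivity
        per allele is guaranteed because ``min_own_pool_freq`` and
        ``max_other_pool_freq`` cannot hold for both pools at once
        (0.95 > 0.02).
    """
    meta_cols = ["chrom", "pos", "ref", "alt"]
    for name, panel in (("A", panel_a), ("B", panel_b)):
        sample_cols = [c for c in panel.columns if c not in meta_cols]
        if len(sample_cols) < 2:
            raise ValueError(f"panel {name} needs >=2 accessions, got {len(sample_cols)}")
    if min_own_pool_freq <= 0.5:
        raise ValueError("min_own_pool_freq must exceed 0.5 to keep assignments exclusive")
    shared_a = set(panel_a.columns) - set(meta_cols)
    shared_b = set(panel_b.columns) - set(meta_cols)
    if shared_a & shared_b:
        raise ValueError(f"panels must be disjoint; shared accessions: {sorted(shared_a & shared_b)}")
    if not (panel_a[meta_cols].reset_index(drop=True)
            .equals(panel_b[meta_cols].reset_index(drop=True))):
        raise ValueError("panel_a and panel_b must describe the same sites in the same order")

    ga = panel_a.drop(columns=meta_cols)
    gb = panel_b.drop(columns=meta_cols)
    freq_a, call_a = _pool_allele_freq(ga)
    freq_b, call_b = _pool_allele_freq(gb)

    ok_missing = (call_a >= 1.0 - max_missing) & (call_b >= 1.0 - max_missing)
    meta = panel_a[meta_cols].reset_index(drop=True)

    out: list[DiagnosticAllele] = []
    with np.errstate(invalid="ignore"):
        # alt allele diagnostic for A / for B
        alt_diag_a = ok_missing & (freq_a >= min_own_pool_freq) & (freq_b <= max_other_pool_freq)
        alt_diag_b = ok_missing & (freq_b >= min_own_pool_freq) & (freq_a <= max_other_pool_freq)
        # ref allele: frequency is 1 - alt frequency
        ref_diag_a = ok_missing & (1 - freq_a >= min_own_pool_freq) & (1 - freq_b <= max_other_pool_freq)
        ref_diag_b = ok_missing & (1 - freq_b >= min_own_pool_freq) & (1 - freq_a <= max_other_pool_freq)

    for i in range(len(meta)):
        chrom = str(meta.at[i, "chrom"])
        pos = int(meta.at[i, "pos"])
        ref = str(meta.at[i, "ref"])
        alt = str(meta.at[i, "alt"])
        if alt_diag_a[i]:
            out.append(DiagnosticAllele(chrom, pos, alt, "A"))
        elif alt_diag_b[i]:
            out.append(DiagnosticAllele(chrom, pos, alt, "B"))
        if ref_diag_a[i]:
            out.append(DiagnosticAllele(chrom, pos, ref, "A"))
        elif ref_diag_b[i]:
            out.append(DiagnosticAllele(chrom, pos, ref, "B"))
    return sorted(out)


def assign_site_depths(
    target: pd.DataFrame,
    diagnostics: list[DiagnosticAllele],
    *,
    min_depth: int = 4,
) -> pd.DataFrame:
    """Convert a target accession's allele depths to A/B-assigned counts.

    Parameters
    ----------
    target : pandas.DataFrame
        Allele-depth table with columns ``chrom``, ``pos``, ``ref``,
        ``alt``, ``ad_ref``, ``ad_alt`` (one biallelic record per row).
    diagnostics : list of DiagnosticAllele
        Diagnostic allele set from :func:`identify_diagnostic_alleles`.
    min_depth : int
        Minimum summed diagnostic depth (A + B) to retain a site.

    Returns
    -------
    pandas.DataFrame
        Columns ``chrom``, ``pos``, ``depth_a``, ``depth_b``, sorted by
        (chrom, pos). Only reads of diagnostic alleles are counted;
        sites without any diagnostic allele are dropped.
    """
    required = {"chrom", "pos", "ref", "alt", "ad_ref", "ad_alt"}
    missing = required - set(target.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    lookup: dict[tuple[str, int, str], str] = {
        (d.chrom, d.pos, d.allele): d.ancestry for d in diagnostics
    }
    rows = []
    for chrom, pos, ref, alt, ad_ref, ad_alt in target[
        ["chrom", "pos", "ref", "alt", "ad_ref", "ad_alt"]
    ].itertuples(index=False):
        if pd.isna(ad_ref) or pd.isna(ad_alt):
            raise ValueError(f"missing per-allele depth at {chrom}:{pos}")
        depth_a = depth_b = 0
        seen = False
        for allele, depth in ((str(ref), int(ad_ref)), (str(alt), int(ad_alt))):
            anc = lookup.get((str(chrom), int(pos), allele))
            if anc is None:
                continue
            seen = True
            if anc == "A":
                depth_a += depth
            else:
                depth_b += depth
        if not seen:
            continue
        if depth_a + depth_b < min_depth:
            continue
        rows.append((str(chrom), int(pos), depth_a, depth_b))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "depth_a", "depth_b"])
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def extract_het_sites(
    target: pd.DataFrame,
    diagnostics: list[DiagnosticAllele],
    *,
    min_depth: int = 8,
) -> pd.DataFrame:
    """Residual within-subgenome heterozygous sites of a target accession.

    Sites where the accession shows two alleles with positive depth but
    *neither* allele is ancestry-diagnostic are polymorphisms internal
    to one subgenome. Their minor-allele read fraction is multimodal in
    a copy-number-dependent way (at 1/2 for two copies, at {1/3, 2/3}
    for three) and disambiguates states with identical B-read fraction
    (A0:B2 vs A0:B3).

    Returns a DataFrame with columns ``chrom``, ``pos``,
    ``minor_fraction``, ``depth`` (depth feeds the binomial modality
    test downstream).
    """
    diag_sites = {(d.chrom, d.pos) for d in diagnostics}
    rows = []
    for chrom, pos, ref, alt, ad_ref, ad_alt in target[
        ["chrom", "pos", "ref", "alt", "ad_ref", "ad_alt"]
    ].itertuples(index=False):
        if (str(chrom), int(pos)) in diag_sites:
            continue
        ad_ref, ad_alt = int(ad_ref), int(ad_alt)
        total = ad_ref + ad_alt
        if total < min_depth or ad_ref == 0 or ad_alt == 0:
            continue
        rows.append((str(chrom), int(pos), min(ad_ref, ad_alt) / total, total))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "minor_fraction", "depth"])
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def diagnostics_to_frame(diagnostics: list[DiagnosticAllele]) -> pd.DataFrame:
    """Tabulate diagnostics as a TSV-ready DataFrame."""
    return pd.DataFrame(
        [(d.chrom, d.pos, d.allele, d.ancestry) for d in diagnostics],
        columns=["chrom", "pos", "allele", "ancestry"],
    )


def frame_to_diagnostics(df: pd.DataFrame) -> list[DiagnosticAllele]:
    """Inverse of :func:`diagnostics_to_frame`."""
    return [
        DiagnosticAllele(str(r.chrom), int(r.pos), str(r.allele), str(r.ancestry))
        for r in df.itertuples(index=False)
    ]
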