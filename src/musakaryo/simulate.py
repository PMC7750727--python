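"""Synthetic ancestral panels, mosaic karyotypes and read depths.

The generator emulates the statistical structure the karyotyping method
assumes: RADSeq-like sparse SNP sites, a subset of alleles private to
one ancestral pool, negative-binomial total depth proportional to local
copy number, and binomial allele sampling conditional on the local
Ax:By dosage state. Every output carries complete ground truth so each
downstream stage can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from musakaryo.ancestry import DiagnosticAllele
from musakaryo.chromosomes import ChromosomeSpec, chrom_map

__all__ = [
    "SimulationConfig",
    "KaryotypeSegment",
    "TruthKaryotype",
    "simulate_panels",
    "make_truth_karyotype",
    "simulate_accession_depths",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_panel_a, n_panel_b : int
        Accessions per ancestral panel.
    sites_per_chrom : int
        SNP sites simulated per chromosome.
    diagnostic_fraction : float
        Fraction of sites whose alleles are private to one pool.
    mean_depth : float
        Mean total read depth per site at baseline copy number.
        Defaults to 30x; depth per site is not reported for the real
        RADSeq data, so this is the package's own realistic choice.
    depth_dispersion : float
        Negative-binomial dispersion (variance = mu + mu^2/dispersion);
        RADSeq depth is overdispersed relative to Poisson.
    residual_het_fraction : float
        Fraction of additional subgenome-B-internal heterozygous sites
        simulated per chromosome (observable only where the A copy
        count is zero and B copy count is >= 2).
    other_pool_freq : float
        Leakiness: frequency of a "private" allele in the opposite
        pool. 0 means strictly private; small positive values test
        robustness of diagnostic discovery.
    seed : int
        Base seed; all randomness derives from it.
    """

    n_panel_a: int = 4
    n_panel_b: int = 4
    sites_per_chrom: int = 1000
    diagnostic_fraction: float = 0.5
    mean_depth: float = 30.0
    depth_dispersion: float = 10.0
    residual_het_fraction: float = 0.05
    other_pool_freq: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_panel_a <= 0 or self.n_panel_b <= 0:
            raise ValueError("panel sizes must be positive")
        if self.sites_per_chrom <= 0:
            raise ValueError("sites_per_chrom must be positive")
        if not 0.0 <= self.diagnostic_fraction <= 1.0:
            raise ValueError("diagnostic_fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if not 0.0 <= self.other_pool_freq < 0.5:
            raise ValueError("other_pool_freq must be in [0, 0.5)")


@dataclass(frozen=True)
class KaryotypeSegment:
    """A chromosome interval with known (a_copies, b_copies)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    a_copies: int
    b_copies: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.chrom}: start {self.start} > end {self.end}")
        if self.a_copies < 0 or self.b_copies < 0 or self.a_copies + self.b_copies < 1:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: invalid copies "
                f"({self.a_copies}, {self.b_copies})"
            )


@dataclass
class TruthKaryotype:
    """Ground-truth mosaic karyotype of one accession.

    ``segments`` tile every chromosome exactly (1-based inclusive, no
    gaps, no overlaps).
    """

    accession_id: str
    baseline_ploidy: int
    segments: list[KaryotypeSegment] = field(default_factory=list)

    def validate(self, chroms: list[ChromosomeSpec]) -> None:
        """Check the tiling invariant against chromosome metadata."""
        cmap = chrom_map(chroms)
        by_chrom: dict[str, list[KaryotypeSegment]] = {c.name: [] for c in chroms}
        for seg in self.segments:
            if seg.chrom not in cmap:
                raise ValueError(f"unknown chromosome {seg.chrom!r}")
            by_chrom[seg.chrom].append(seg)
        for name, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            expected_start = 1
            for seg in segs:
                if seg.start != expected_start:
                    raise ValueError(
                        f"{name}: segment gap/overlap at {seg.start} (expected {expected_start})"
                    )
                expected_start = seg.end + 1
            if expected_start != cmap[name].length + 1:
                raise ValueError(f"{name}: segments do not reach chromosome end")

    def state_at(self, chrom: str, pos: int) -> tuple[int, int]:
        """(a_copies, b_copies) covering ``pos``."""
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos <= seg.end:
                return seg.a_copies, seg.b_copies
        raise ValueError(f"position {chrom}:{pos} not covered by any truth segment")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.chrom, s.start, s.end, s.a_copies, s.b_copies, self.accession_id)
                for s in self.segments
            ],
            columns=["chrom", "start", "end", "a_copies", "b_copies", "accession"],
        )


def make_truth_karyotype(
    baseline_ploidy: int,
    events: list[tuple[str, int, int, int, int]],
    chroms: list[ChromosomeSpec],
    accession_id: str = "synthetic",
) -> TruthKaryotype:
    """Build a truth karyotype from deviating events over a baseline.

    The baseline state (A1:B2 for triploids, A1:B1 for diploids) fills
    every interval not listed in ``events``; events are
    ``(chrom, start, end, a_copies, b_copies)`` tuples with 1-based
    inclusive coordinates and must not overlap.
    """
    if baseline_ploidy == 2:
        base = (1, 1)
    elif baseline_ploidy == 3:
        base = (1, 2)
    else:
        raise ValueError(f"baseline_ploidy must be 2 or 3, got {baseline_ploidy}")
    cmap = chrom_map(chroms)
    per_chrom: dict[str, list[KaryotypeSegment]] = {c.name: [] for c in chroms}
    for chrom, start, end, a, b in events:
        if chrom not in cmap:
            raise ValueError(f"unknown chromosome {chrom!r} in event")
        if not (1 <= start <= end <= cmap[chrom].length):
            raise ValueError(
                f"event {chrom}:{start}-{end} outside chromosome bounds (1-{cmap[chrom].length})"
            )
        per_chrom[chrom].append(KaryotypeSegment(chrom, int(start), int(end), int(a), int(b)))
    segments: list[KaryotypeSegment] = []
    for c in chroms:
        evs = sorted(per_chrom[c.name], key=lambda s: s.start)
        for prev, nxt in zip(evs, evs[1:]):
            if nxt.start <= prev.end:
                raise ValueError(f"overlapping events on {c.name}: {prev} / {nxt}")
        cursor = 1
        for ev in evs:
            if ev.start > cursor:
                segments.append(KaryotypeSegment(c.name, cursor, ev.start - 1, *base))
            segments.append(ev)
            cursor = ev.end + 1
        if cursor <= c.length:
            segments.append(KaryotypeSegment(c.name, cursor, c.length, *base))
    kar = TruthKaryotype(accession_id, baseline_ploidy, segments)
    kar.validate(chroms)
    return kar


def _simulate_sites(rng: np.random.Generator, chroms: list[ChromosomeSpec], n: int) -> pd.DataFrame:
    """Random distinct site positions with ref/alt bases per chromosome."""
    frames = []
    for c in chroms:
        n_sites = min(n, c.length)
        pos = np.sort(rng.choice(np.arange(1, c.length + 1), size=n_sites, replace=False))
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_shift = rng.integers(1, 4, size=n_sites)
        alt_idx = (ref_idx + alt_shift) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c.name,
                    "pos": pos.astype(int),
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_panels(
    config: SimulationConfig, chroms: list[ChromosomeSpec]
) -> tuple[pd.DataFrame, pd.DataFrame, list[DiagnosticAllele]]:
    """Simulate A- and B-pool genotype panels with known diagnostic truth.

    Returns
    -------
    (panel_a, panel_b, truth)
        Genotype tables (columns ``chrom, pos, ref, alt`` + one alt-
        dosage column per accession) over the same sites, and the list
        of truly pool-private alleles. At a diagnostic site the alt
        allele is private to one pool, which makes the ref allele
        private to the other; both appear in the truth list. Shared
        sites segregate at a common moderate frequency in both pools.

    Notes
    -----
    With ``config.other_pool_freq > 0`` ("leaky" mode) the private
    allele also occurs at that frequency in the opposite pool; the
    truth list still records the intended assignment.
    """
    if config.n_panel_a < 2 or config.n_panel_b < 2:
        raise ValueError("simulate_panels needs >=2 accessions per panel")
    rng = np.random.default_rng(config.seed)
    sites = _simulate_sites(rng, chroms, config.sites_per_chrom)
    n_sites = len(sites)
    is_diag = rng.random(n_sites) < config.diagnostic_fraction
    # pool whose ALT allele is private: True -> B, False -> A
    alt_pool_b = rng.random(n_sites) < 0.5

    leak = config.other_pool_freq
    freq_a = np.empty(n_sites)
    freq_b = np.empty(n_sites)
    shared = ~is_diag
    shared_p = rng.uniform(0.2, 0.8, size=n_sites)
    freq_a[shared] = shared_p[shared]
    freq_b[shared] = shared_p[shared]
    # alt private to B: fixed in B, (almost) absent in A
    sel = is_diag & alt_pool_b
    freq_b[sel] = 1.0 - leak
    freq_a[sel] = leak
    sel = is_diag & ~alt_pool_b
    freq_a[sel] = 1.0 - leak
    freq_b[sel] = leak

    def genotypes(freq: np.ndarray, n_acc: int, prefix: str) -> pd.DataFrame:
        cols = {}
        for i in range(n_acc):
            cols[f"{prefix}{i + 1}"] = rng.binomial(2, freq)
        return pd.DataFrame(cols)

    panel_a = pd.concat([sites, genotypes(freq_a, config.n_panel_a, "A")], axis=1)
    panel_b = pd.concat([sites, genotypes(freq_b, config.n_panel_b, "B")], axis=1)

    truth: list[DiagnosticAllele] = []
    for i in np.flatnonzero(is_diag):
        chrom = str(sites.at[i, "chrom"])
        pos = int(sites.at[i, "pos"])
        ref = str(sites.at[i, "ref"])
        alt = str(sites.at[i, "alt"])
        if alt_pool_b[i]:
            truth.append(DiagnosticAllele(chrom, pos, alt, "B"))
            truth.append(DiagnosticAllele(chrom, pos, ref, "A"))
        else:
            truth.append(DiagnosticAllele(chrom, pos, alt, "A"))
            truth.append(DiagnosticAllele(chrom, pos, ref, "B"))
    return panel_a, panel_b, sorted(truth)


def _nb_depths(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial total depths with mean ``mu``."""
    mu = np.asarray(mu, dtype=float)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_accession_depths(
    truth: TruthKaryotype,
    diagnostics: list[DiagnosticAllele],
    config: SimulationConfig,
    chroms: list[ChromosomeSpec],
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-site allele depths for one accession.

    Per diagnostic site covered by a truth segment with state (a, b):
    total depth ~ NegBin(mean = mean_depth * (a+b) / baseline_ploidy),
    and reads of the B-diagnostic allele ~ Binomial(total, b/(a+b)).
    Additional subgenome-B-internal heterozygous sites (minor-allele
    fraction k/b, k = 1..b-1) are emitted in regions with a = 0 and
    b >= 2, where they carry the copy-number signal that separates
    e.g. A0:B2 from A0:B3.

    Returns
    -------
    pandas.DataFrame
        Columns ``chrom, pos, ref, alt, ad_ref, ad_alt, site_class``
        with ``site_class`` in {"diagnostic", "het_b"}; sorted by
        (chrom, pos). Zero-depth sites are dropped (unobserved).
    """
    if not diagnostics:
        raise ValueError("diagnostics must be nonempty")
    truth.validate(chroms)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    # orientation per site: ancestry of ref and alt alleles
    per_site: dict[tuple[str, int], dict[str, str]] = {}
    for d in diagnostics:
        per_site.setdefault((d.chrom, d.pos), {})[d.allele] = d.ancestry

    seg_index: dict[str, list[KaryotypeSegment]] = {}
    for seg in truth.segments:
        seg_index.setdefault(seg.chrom, []).append(seg)
    for segs in seg_index.values():
        segs.sort(key=lambda s: s.start)

    def state_at(chrom: str, pos: int) -> tuple[int, int]:
        segs = seg_index.get(chrom)
        if not segs:
            raise ValueError(f"no truth segment covers chromosome {chrom}")
        starts = [s.start for s in segs]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        seg = segs[i]
        if not (seg.start <= pos <= seg.end):
            raise ValueError(f"position {chrom}:{pos} not covered by truth segments")
        return seg.a_copies, seg.b_copies

    rows = []
    # diagnostic sites, grouped by site (two diagnostic alleles share one site)
    for (chrom, pos), alleles in sorted(per_site.items()):
        a, b = state_at(chrom, pos)
        mu = config.mean_depth * (a + b) / truth.baseline_ploidy
        total = int(_nb_depths(rng, np.array([mu]), config.depth_dispersion)[0])
        if total == 0:
            continue
        b_reads = int(rng.binomial(total, b / (a + b)))
        # map B reads onto whichever allele is B-diagnostic at this site
        allele_depth = {al: 0 for al in alleles}
        for al, anc in alleles.items():
            if anc == "B":
                allele_depth[al] = b_reads
            else:
                allele_depth[al] = total - b_reads
        b_alleles = [al for al, anc in alleles.items() if anc == "B"]
        a_alleles = [al for al, anc in alleles.items() if anc == "A"]
        if len(alleles) == 1:
            # single diagnostic allele at the site: the other observed
            # allele is non-diagnostic; emit it as ref with the rest of
            # the reads
            al = next(iter(alleles))
            other = "N"
            ref, alt = other, al
            ad_alt = allele_depth[al]
            ad_ref = total - ad_alt
        else:
            ref = a_alleles[0]
            alt = b_alleles[0]
            ad_ref = allele_depth[ref]
            ad_alt = allele_depth[alt]
        rows.append((chrom, int(pos), ref, alt, int(ad_ref), int(ad_alt), "diagnostic"))

    # residual subgenome-B heterozygosity
    diag_positions = {(c, p) for (c, p) in per_site}
    n_het = int(round(config.residual_het_fraction * config.sites_per_chrom))
    for c in chroms:
        placed = 0
        attempts = 0
        while placed < n_het and attempts < 20 * max(n_het, 1):
            attempts += 1
            pos = int(rng.integers(1, c.length + 1))
            if (c.name, pos) in diag_positions:
                continue
            a, b = state_at(c.name, pos)
            if a != 0 or b < 2:
                continue
            k = int(rng.integers(1, b))
            mu = config.mean_depth * (a + b) / truth.baseline_ploidy
            total = int(_nb_depths(rng, np.array([mu]), config.depth_dispersion)[0])
            if total == 0:
                continue
            minor = int(rng.binomial(total, k / b))
            ref_b, alt_b = "C", "T"  # B-internal alleles, neither diagnostic
            rows.append((c.name, pos, ref_b, alt_b, total - minor, minor, "het_b"))
            placed += 1

    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "ad_ref", "ad_alt", "site_class"]
    )
    out = out.drop_duplicates(subset=["chrom", "pos"], keep="first")
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
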