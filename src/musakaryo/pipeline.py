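"""End-to-end orchestration: panels -> diagnostics -> karyotypes ->
patterns -> diversity, with a reproducibility manifest.

Each stage failure aborts with a stage-labeled :class:`PipelineError`;
outputs of completed stages remain on disk and the manifest flags the
run as partial.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from musakaryo import __version__, io
from musakaryo.ancestry import (
    assign_site_depths,
    diagnostics_to_frame,
    extract_het_sites,
    identify_diagnostic_alleles,
)
from musakaryo.chromosomes import default_chromosomes, read_chromosome_table, write_chromosome_table
from musakaryo.diversity import cluster_with_bootstrap, mask_he_regions
from musakaryo.karyotype import KaryotypeParams, karyotype_accession, segments_to_frame
from musakaryo.patterns import (
    call_he_events,
    chromosome_counts,
    events_to_frame,
    group_patterns,
    load_pattern_events,
    load_table1_fixture,
)
from musakaryo.simulate import SimulationConfig, make_truth_karyotype, simulate_accession_depths, simulate_panels

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_fixture", "make_demo_cohort"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    panel_vcf: str
    target_vcf: str
    chrom_table: str
    panel_a_samples: list[str]
    panel_b_samples: list[str]
    target_samples: list[str]
    outdir: str
    baseline_ploidy: int = 3
    seed: int = 0
    min_own_pool_freq: float = 0.95
    max_other_pool_freq: float = 0.02
    max_missing: float = 0.2
    min_site_depth: int = 4
    window_size: int = 500_000
    min_sites_per_window: int = 10
    segmentation_penalty: float = 10.0
    breakpoint_tolerance: int = 1_000_000
    end_tolerance: int = 1_000_000
    n_boot: int = 100
    run_diversity: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineError("config", str(exc)) from exc

    def validate(self) -> None:
        for name in ("panel_vcf", "target_vcf", "chrom_table"):
            value = getattr(self, name)
            if not value:
                raise PipelineError("config", f"missing required path field: {name}")
            if not Path(value).exists():
                raise PipelineError("config", f"{name} does not exist: {value}")
        if not self.panel_a_samples or not self.panel_b_samples:
            raise PipelineError("config", "panel_a_samples and panel_b_samples must be non-empty")
        if not self.target_samples:
            raise PipelineError("config", "target_samples must be non-empty")


def _dosage_from_depths(depths: pd.DataFrame) -> pd.DataFrame:
    """Naive alt-dosage calls from allele depths (for diversity only)."""
    total = depths["ad_ref"] + depths["ad_alt"]
    frac = np.where(total > 0, depths["ad_alt"] / total.replace(0, 1), np.nan)
    dosage = np.select([frac < 0.2, frac > 0.8], [0, 2], default=1).astype(float)
    dosage[total == 0] = np.nan
    out = depths[["chrom", "pos", "ref", "alt"]].copy()
    out["dosage"] = dosage
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "outputs": {},
        "partial": True,
    }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    try:
        chroms = read_chromosome_table(config.chrom_table)
    except Exception as exc:
        raise PipelineError("chromosomes", str(exc)) from exc

    try:
        panel_a = io.read_genotype_vcf(config.panel_vcf, config.panel_a_samples)
        panel_b = io.read_genotype_vcf(config.panel_vcf, config.panel_b_samples)
        diagnostics = identify_diagnostic_alleles(
            panel_a,
            panel_b,
            min_own_pool_freq=config.min_own_pool_freq,
            max_other_pool_freq=config.max_other_pool_freq,
            max_missing=config.max_missing,
        )
        diag_path = outdir / "diagnostics.tsv"
        diagnostics_to_frame(diagnostics).to_csv(diag_path, sep="\t", index=False)
        emit("diagnostics", diag_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("diagnostics", str(exc)) from exc

    kparams = KaryotypeParams(
        window_size=config.window_size,
        min_sites=config.min_sites_per_window,
        penalty=config.segmentation_penalty,
    )
    events_by_acc: dict[str, list] = {}
    aneuploid_accs: set[str] = set()
    all_he_intervals: list[tuple[str, int, int]] = []
    target_genotypes: dict[str, pd.DataFrame] = {}
    try:
        for sample in config.target_samples:
            depths = io.read_depth_vcf(config.target_vcf, sample)
            sites = assign_site_depths(depths, diagnostics, min_depth=config.min_site_depth)
            het = extract_het_sites(depths, diagnostics)
            segments = karyotype_accession(
                sites, chroms, kparams, het_sites=het, baseline_ploidy=config.baseline_ploidy
            )
            seg_path = outdir / f"karyotype_{sample}.tsv"
            segments_to_frame(segments, sample).to_csv(seg_path, sep="\t", index=False)
            emit(f"karyotype_{sample}", seg_path)
            hes, aneu = call_he_events(
                segments, config.baseline_ploidy, chroms, config.end_tolerance
            )
            events_by_acc[sample] = hes
            if aneu:
                aneuploid_accs.add(sample)
            all_he_intervals.extend((e.chrom, e.start, e.end) for e in hes + aneu)
            n_a, n_b = chromosome_counts(segments, chroms)
            report = {
                "accession": sample,
                "baseline_ploidy": config.baseline_ploidy,
                "n_a_chromosomes": n_a,
                "n_b_chromosomes": n_b,
                "n_he_events": len(hes),
                "n_aneuploidies": len(aneu),
                "he_events": events_to_frame(hes).to_dict("records"),
                "aneuploidies": events_to_frame(aneu).to_dict("records"),
            }
            json_path = outdir / f"karyotype_{sample}.json"
            json_path.write_text(json.dumps(report, indent=2) + "\n")
            emit(f"karyotype_json_{sample}", json_path)
            target_genotypes[sample] = _dosage_from_depths(depths)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("karyotype", str(exc)) from exc

    try:
        groups = group_patterns(
            events_by_acc,
            breakpoint_tolerance=config.breakpoint_tolerance,
            aneuploid_accessions=aneuploid_accs,
        )
        rows = []
        for g in groups:
            for m in g.members:
                rows.append(
                    (
                        g.pattern_id,
                        m,
                        "+" if m in g.aneuploid_members else "",
                        len(g.canonical_events),
                    )
                )
        pat_path = outdir / "patterns.tsv"
        pd.DataFrame(
            rows, columns=["pattern_id", "accession", "aneuploidy_flag", "n_events"]
        ).to_csv(pat_path, sep="\t", index=False)
        emit("patterns", pat_path)
        pat_json = outdir / "patterns.json"
        pat_json.write_text(
            json.dumps(
                [
                    {
                        "pattern_id": g.pattern_id,
                        "members": g.members,
                        "aneuploid_members": g.aneuploid_members,
                        "events": events_to_frame(g.canonical_events).to_dict("records"),
                    }
                    for g in groups
                ],
                indent=2,
            )
            + "\n"
        )
        emit("patterns_json", pat_json)
    except Exception as exc:
        raise PipelineError("patterns", str(exc)) from exc

    if config.run_diversity and len(config.target_samples) >= 2:
        try:
            frames = []
            for sample, gt in target_genotypes.items():
                s = gt.set_index(["chrom", "pos"])["dosage"].rename(sample)
                frames.append(s)
            merged = pd.concat(frames, axis=1)
            matrix = merged.T
            matrix.columns = pd.MultiIndex.from_tuples(matrix.columns)
            masked = mask_he_regions(matrix, all_he_intervals)
            masked = masked.loc[:, masked.notna().all(axis=0)]
            newick, _supports = cluster_with_bootstrap(
                masked, n_boot=config.n_boot, seed=config.seed
            )
            tree_path = outdir / "diversity.nwk"
            tree_path.write_text(newick + "\n")
            emit("diversity_tree", tree_path)
        except Exception as exc:
            raise PipelineError("diversity", str(exc)) from exc

    manifest["partial"] = False
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def validate_fixture() -> dict:
    """Summary tallies of the packaged accession table.

    Counts per genome class, per pattern (with and without the
    aneuploidy marker), and per subgroup, as used by downstream
    consistency checks.
    """
    records = load_table1_fixture()
    abb = [r for r in records if r.genome.startswith("ABB")]
    ab = [r for r in records if r.genome == "AB"]
    abb_patterned = [r for r in abb if r.pattern != "N/A"]
    ab_no_deviation = [r for r in ab if r.base_pattern == "(2x)"]
    per_pattern: dict[str, int] = {}
    for r in records:
        per_pattern[r.base_pattern] = per_pattern.get(r.base_pattern, 0) + 1
    per_subgroup: dict[str, int] = {}
    for r in records:
        per_subgroup[r.subgroup] = per_subgroup.get(r.subgroup, 0) + 1
    return {
        "n_records": len(records),
        "n_abb": len(abb),
        "n_ab": len(ab),
        "n_abb_with_pattern": len(abb_patterned),
        "n_abb_without_pattern": len(abb) - len(abb_patterned),
        "n_ab_without_deviation": len(ab_no_deviation),
        "n_ab_with_deviation": len(ab) - len(ab_no_deviation),
        "n_aneuploid_flagged": sum(r.has_aneuploidy for r in records),
        "distinct_abb_patterns": sorted(
            {r.base_pattern for r in abb if r.pattern != "N/A"}
        ),
        "distinct_ab_patterns": sorted({r.base_pattern for r in ab}),
        "per_pattern": dict(sorted(per_pattern.items())),
        "per_subgroup": dict(sorted(per_subgroup.items())),
    }


# ---------------------------------------------------------------------------
# packaged demo cohort
# ---------------------------------------------------------------------------

DEMO_PATTERNS = ("1b", "4", "5")


def make_demo_cohort(
    outdir: str | Path,
    seed: int = 0,
    patterns: tuple[str, ...] = DEMO_PATTERNS,
    accessions_per_pattern: int = 3,
    sites_per_chrom: int = 800,
) -> PipelineConfig:
    """Simulate a small cohort (3 founding patterns x 3 accessions by
    default) and return a ready-to-run :class:`PipelineConfig`.

    Karyotypes are drawn from the packaged founding-pattern event sets;
    windows are widened to 1 Mb so the RADSeq-scale site density keeps
    every window callable, and the grouping tolerance is widened
    accordingly (breakpoints are quantized to window edges).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms = default_chromosomes()
    config = SimulationConfig(
        n_panel_a=4, n_panel_b=4, sites_per_chrom=sites_per_chrom,
        diagnostic_fraction=1.0, seed=seed,
    )
    panel_a, panel_b, truth_diag = simulate_panels(config, chroms)
    chrom_lengths = {c.name: c.length for c in chroms}
    panel_path = outdir / "panels.vcf"
    meta = ["chrom", "pos", "ref", "alt"]
    panel_all = pd.concat([panel_a, panel_b.drop(columns=meta)], axis=1)
    io.write_genotype_vcf(panel_all, panel_path, chrom_lengths)

    event_sets = load_pattern_events(chroms)
    depth_tables = {}
    rng = np.random.default_rng(seed + 1000)
    for p in patterns:
        ploidy, events = event_sets[p]
        if ploidy != 3:
            raise ValueError(f"demo cohort is triploid; pattern {p} has ploidy {ploidy}")
        ev_tuples = [(e.chrom, e.start, e.end, e.a_copies, e.b_copies) for e in events]
        for i in range(accessions_per_pattern):
            acc = f"P{p}_{i + 1}"
            truth = make_truth_karyotype(3, ev_tuples, chroms, acc)
            depth_tables[acc] = simulate_accession_depths(
                truth, truth_diag, config, chroms, rng=rng
            )
    target_path = outdir / "targets.vcf"
    io.write_depth_vcf(depth_tables, target_path, chrom_lengths)
    chrom_path = outdir / "chromosomes.tsv"
    write_chromosome_table(chroms, chrom_path)

    return PipelineConfig(
        panel_vcf=str(panel_path),
        target_vcf=str(target_path),
        chrom_table=str(chrom_path),
        panel_a_samples=[c for c in panel_a.columns if c not in meta],
        panel_b_samples=[c for c in panel_b.columns if c not in meta],
        target_samples=sorted(depth_tables),
        outdir=str(outdir / "results"),
        baseline_ploidy=3,
        seed=seed,
        window_size=1_000_000,
        breakpoint_tolerance=1_500_000,
        end_tolerance=1_500_000,
        n_boot=20,
    )
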