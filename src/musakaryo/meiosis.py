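"""Gamete and crossing-route simulation.

Simulates the meiotic routes proposed to explain founding HE patterns
in ABB bananas: unreduced 2x gametes from diploid AB hybrids via
first-division restitution (FDR, both parental centromeres retained)
or second-division restitution (SDR, two sister-derived centromeres),
ordinary reduced gametes, random 2-of-3 centromere segregation in
triploids, and backcross schemes. Chromosomes are represented as
ordered ancestry blocks (A = *M. acuminata*, B = *M. balbisiana*);
crossovers occur only between paired chromosomes, at uniform positions.

Trivalent pairing dynamics in triploids are deliberately not modeled:
for triploid 2x gametes only the random 2-of-3 centromere draw is
simulated, which is the segregation model the route hypotheses rest
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from musakaryo.chromosomes import ChromosomeSpec, chrom_map
from musakaryo.simulate import KaryotypeSegment, TruthKaryotype

__all__ = [
    "BlockChromosome",
    "GameteGenome",
    "MeiosisParams",
    "pure_chromosome",
    "make_parent",
    "meiosis",
    "triploid_2x_gamete",
    "triploid_x_gamete",
    "allotetraploid_2x_gamete",
    "cross",
    "route_expectations",
    "ROUTES",
]


@dataclass(frozen=True)
class BlockChromosome:
    """One homolog as ordered ancestry blocks (1-based inclusive)."""

    chrom: str
    blocks: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, anc in self.blocks:
            if anc not in ("A", "B"):
                raise ValueError(f"ancestry must be A or B, got {anc!r}")
            if start != prev_end + 1 or end < start:
                raise ValueError(f"{self.chrom}: blocks must tile contiguously")
            prev_end = end
        if not self.blocks:
            raise ValueError("empty block list")

    @property
    def length(self) -> int:
        return self.blocks[-1][1]

    def ancestry_at(self, pos: int) -> str:
        for start, end, anc in self.blocks:
            if start <= pos <= end:
                return anc
        raise ValueError(f"position {pos} outside {self.chrom} (1-{self.length})")

    def centromere_ancestry(self, spec: ChromosomeSpec) -> str:
        return self.ancestry_at(spec.centromere)


def _merge_blocks(blocks: list[tuple[int, int, str]]) -> tuple[tuple[int, int, str], ...]:
    merged: list[tuple[int, int, str]] = []
    for b in blocks:
        if merged and merged[-1][2] == b[2] and merged[-1][1] + 1 == b[0]:
            merged[-1] = (merged[-1][0], b[1], b[2])
        else:
            merged.append(b)
    return tuple(merged)


def pure_chromosome(spec: ChromosomeSpec, ancestry: str) -> BlockChromosome:
    """A non-recombinant homolog of a single ancestry."""
    return BlockChromosome(spec.name, ((1, spec.length, ancestry),))


@dataclass
class GameteGenome:
    """Per-chromosome homolog sets of a gamete (or genome).

    The homolog count is constant across chromosomes: 1 for an x
    gamete, 2 for a 2x gamete (and 2 or 3 for diploid/triploid somatic
    genomes, which reuse the same container).
    """

    homologs: dict[str, list[BlockChromosome]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {len(v) for v in self.homologs.values()}
        if len(counts) > 1:
            raise ValueError(f"inconsistent homolog counts across chromosomes: {sorted(counts)}")

    @property
    def n_homologs(self) -> int:
        return len(next(iter(self.homologs.values())))

    @property
    def ploidy_label(self) -> str:
        return {1: "x", 2: "2x", 3: "3x"}.get(self.n_homologs, f"{self.n_homologs}x")

    def centromere_ancestries(self, chroms: list[ChromosomeSpec]) -> dict[str, tuple[str, ...]]:
        cmap = chrom_map(chroms)
        return {
            name: tuple(h.centromere_ancestry(cmap[name]) for h in homs)
            for name, homs in self.homologs.items()
        }


@dataclass(frozen=True)
class MeiosisParams:
    """Meiosis model parameters.

    mode
        ``"reduced"`` (one chromatid per chromosome), ``"FDR"`` (both
        parental centromeres retained) or ``"SDR"`` (two sister-derived
        homologs, same centromere origin).
    pairing_prob
        Probability that the two homologs of a chromosome pair; the
        source describes only "partial pairing" between homoeologs, so
        this stays a free parameter (default 0.5).
    crossover_rate
        Expected crossovers per paired bivalent (Poisson; default 1).
    seed
        Seed for all randomness of this meiosis.
    """

    mode: str = "FDR"
    pairing_prob: float = 0.5
    crossover_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("reduced", "FDR", "SDR"):
            raise ValueError(f"mode must be reduced/FDR/SDR, got {self.mode!r}")
        if not 0.0 <= self.pairing_prob <= 1.0:
            raise ValueError("pairing_prob must be in [0, 1]")
        if self.crossover_rate < 0:
            raise ValueError("crossover_rate must be >= 0")


def make_parent(composition: str, chroms: list[ChromosomeSpec]) -> GameteGenome:
    """A non-recombinant genome from a composition string like "AB" or "ABB"."""
    if not composition or set(composition) - {"A", "B"}:
        raise ValueError(f"composition must be a string over A/B, got {composition!r}")
    return GameteGenome(
        {c.name: [pure_chromosome(c, anc) for anc in composition] for c in chroms}
    )


def _splice(
    h_first: BlockChromosome, h_second: BlockChromosome, cuts: list[int]
) -> BlockChromosome:
    """Recombinant chromatid: ``h_first`` up to the first cut, then
    alternating sources at each subsequent cut. ``cuts`` are the first
    positions taken from the next source."""
    sources = (h_first, h_second)
    bounds = [1, *sorted(cuts), h_first.length + 1]
    blocks: list[tuple[int, int, str]] = []
    for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        if lo >= hi:
            continue
        src = sources[i % 2]
        for start, end, anc in src.blocks:
            s, e = max(start, lo), min(end, hi - 1)
            if s <= e:
                blocks.append((s, e, anc))
    return BlockChromosome(h_first.chrom, _merge_blocks(blocks))


def _chromatids(
    h1: BlockChromosome,
    h2: BlockChromosome,
    spec: ChromosomeSpec,
    params: MeiosisParams,
    rng: np.random.Generator,
) -> tuple[list[BlockChromosome], list[BlockChromosome]]:
    """The four chromatids of one bivalent, grouped by centromere origin.

    Crossovers involve one chromatid of each homolog, so each homolog
    keeps one non-recombinant sister; the two recombinant chromatids
    carry complementary centromere origins.
    """
    cuts: list[int] = []
    if rng.random() < params.pairing_prob:
        n_co = int(rng.poisson(params.crossover_rate))
        if n_co > 0:
            cuts = sorted(int(p) for p in rng.integers(2, spec.length + 1, size=n_co))
    rec1 = _splice(h1, h2, cuts) if cuts else h1
    rec2 = _splice(h2, h1, cuts) if cuts else h2
    cen = spec.centromere
    group1 = [h1]  # chromatids whose centromere derives from homolog 1
    group2 = [h2]
    if cuts:
        # source at the centromere alternates at every cut left of it
        flips = sum(c <= cen for c in cuts) % 2
        (group2 if flips else group1).append(rec1)
        (group1 if flips else group2).append(rec2)
    else:
        group1.append(h1)
        group2.append(h2)
    return group1, group2


def meiosis(
    parent: GameteGenome, params: MeiosisParams, chroms: list[ChromosomeSpec]
) -> GameteGenome:
    """One meiosis of a diploid parent.

    ``reduced`` draws one random chromatid per chromosome (x gamete).
    ``FDR`` keeps one chromatid from each parental centromere group
    (2x gamete, one A-origin and one B-origin centromere per
    chromosome for an AB parent). ``SDR`` keeps the two sister
    chromatids of one randomly chosen homolog (2x gamete, identical
    centromere origin, possibly recombinant arms).

    Triploid parents are handled by :func:`triploid_2x_gamete` /
    :func:`triploid_x_gamete`, which implement the random centromere
    segregation model; calling ``meiosis`` on one is a configuration
    error.
    """
    ploidy = parent.n_homologs
    if ploidy != 2:
        raise ValueError(
            f"meiosis models diploid parents (got {ploidy} homologs); "
            "use triploid_2x_gamete / triploid_x_gamete for triploids"
        )
    rng = np.random.default_rng(params.seed)
    cmap = chrom_map(chroms)
    out: dict[str, list[BlockChromosome]] = {}
    for name, (h1, h2) in sorted(parent.homologs.items()):
        spec = cmap[name]
        group1, group2 = _chromatids(h1, h2, spec, params, rng)
        if params.mode == "reduced":
            pool = group1 + group2
            out[name] = [pool[int(rng.integers(len(pool)))]]
        elif params.mode == "FDR":
            out[name] = [
                group1[int(rng.integers(len(group1)))],
                group2[int(rng.integers(len(group2)))],
            ]
        else:  # SDR
            sisters = group1 if rng.random() < 0.5 else group2
            if len(sisters) == 1:  # no recombinant: sisters are identical copies
                sisters = sisters * 2
            out[name] = list(sisters[:2])
    return GameteGenome(out)


def triploid_2x_gamete(parent: GameteGenome, seed: int = 0) -> GameteGenome:
    """2x gamete from a triploid by random centromere segregation.

    Per chromosome, 2 of the 3 homologs are drawn uniformly without
    replacement (no recombination modeled). For an ABB parent the
    probability that both drawn centromeres are B is 1/3.
    """
    if parent.n_homologs != 3:
        raise ValueError("triploid_2x_gamete requires a triploid parent")
    rng = np.random.default_rng(seed)
    out = {}
    for name, homs in sorted(parent.homologs.items()):
        idx = rng.choice(3, size=2, replace=False)
        out[name] = [homs[int(i)] for i in idx]
    return GameteGenome(out)


def allotetraploid_2x_gamete(chroms: list[ChromosomeSpec]) -> GameteGenome:
    """2x gamete of an AABB allotetraploid under regular meiosis.

    With homologous bivalent pairing (A with A, B with B), every gamete
    carries 11 A and 11 B chromosomes; exchanges between same-ancestry
    homologs are invisible to ancestry analysis, and homoeologous
    pairing is expected to be infrequent, so none is modeled.
    """
    return GameteGenome(
        {c.name: [pure_chromosome(c, "A"), pure_chromosome(c, "B")] for c in chroms}
    )


def triploid_x_gamete(parent: GameteGenome, seed: int = 0) -> GameteGenome:
    """Reduced x gamete from a triploid: 1 of 3 homologs per chromosome."""
    if parent.n_homologs != 3:
        raise ValueError("triploid_x_gamete requires a triploid parent")
    rng = np.random.default_rng(seed)
    return GameteGenome(
        {name: [homs[int(rng.integers(3))]] for name, homs in sorted(parent.homologs.items())}
    )


def cross(
    gamete1: GameteGenome,
    gamete2: GameteGenome,
    chroms: list[ChromosomeSpec],
    accession_id: str = "offspring",
) -> tuple[GameteGenome, TruthKaryotype]:
    """Fuse two gametes and derive the offspring's truth karyotype.

    The karyotype sums ancestry copies per position over all homologs,
    yielding segments compatible with the synthetic read-depth
    generator (end-to-end simulations feed it directly).
    """
    if set(gamete1.homologs) != set(gamete2.homologs):
        raise ValueError("gametes carry different chromosome sets")
    cmap = chrom_map(chroms)
    merged = {
        name: list(gamete1.homologs[name]) + list(gamete2.homologs[name])
        for name in gamete1.homologs
    }
    offspring = GameteGenome(merged)
    ploidy = offspring.n_homologs

    segments: list[KaryotypeSegment] = []
    for name in sorted(merged):
        homs = merged[name]
        length = cmap[name].length
        edges = {1, length + 1}
        for h in homs:
            for start, _end, _anc in h.blocks:
                edges.add(start)
        bounds = sorted(edges)
        chrom_segs: list[KaryotypeSegment] = []
        for lo, hi in zip(bounds, bounds[1:]):
            a = sum(h.ancestry_at(lo) == "A" for h in homs)
            b = len(homs) - a
            chrom_segs.append(KaryotypeSegment(name, lo, hi - 1, a, b))
        # merge adjacent equal states
        merged_segs: list[KaryotypeSegment] = []
        for seg in chrom_segs:
            if merged_segs and (merged_segs[-1].a_copies, merged_segs[-1].b_copies) == (
                seg.a_copies,
                seg.b_copies,
            ):
                prev = merged_segs.pop()
                seg = KaryotypeSegment(name, prev.start, seg.end, seg.a_copies, seg.b_copies)
            merged_segs.append(seg)
        segments.extend(merged_segs)
    karyotype = TruthKaryotype(accession_id, ploidy, segments)
    karyotype.validate(chroms)
    return offspring, karyotype


ROUTES = ("AB_FDR_x_B", "A_x_BB", "ABB_2x_x_B", "AB_backcross_2x_x_B")


def _offspring_stats(
    karyotype: TruthKaryotype, offspring: GameteGenome, chroms: list[ChromosomeSpec]
) -> tuple[int, int]:
    """(number of chromosomes with an all-B centromere, HE segment count)."""
    baseline = (1, karyotype.baseline_ploidy - 1)
    cen_anc = offspring.centromere_ancestries(chroms)
    n_b_cen = sum(1 for ancs in cen_anc.values() if set(ancs) == {"B"})
    n_he = sum(
        1
        for seg in karyotype.segments
        if (seg.a_copies, seg.b_copies) != baseline
    )
    return n_b_cen, n_he


def route_expectations(
    route: str,
    n_reps: int,
    seed: int,
    chroms: list[ChromosomeSpec],
    params: MeiosisParams | None = None,
) -> pd.DataFrame:
    """Monte-Carlo expectations for a triploidization route.

    Simulates ``n_reps`` independent offspring of the named route and
    returns one row per replicate with the count of chromosomes whose
    centromeres are all B (an A0:B3 centromeric state) and the count
    of segments deviating from the A1:B2 baseline. These are
    descriptive expectations, not an inference procedure.

    Routes
    ------
    - ``AB_FDR_x_B``: unreduced FDR gamete of an AB hybrid x haploid B.
      Every chromosome keeps one A and one B centromere, so all-B
      centromere pairs never occur before the final cross.
    - ``A_x_BB``: haploid A x unreduced BB; no pre-triploidy
      recombination is possible.
    - ``ABB_2x_x_B``: random-segregation 2x gamete of an ABB triploid x
      haploid B; 1/3 of centromere pairs are expected BB.
    - ``AB_backcross_2x_x_B``: reduced gamete of an AB hybrid x haploid
      B gives a backcrossed hybrid (B^aB); its FDR 2x gamete (about
      half of its centromere pairs BB) x haploid B.
    """
    if route not in ROUTES:
        raise ValueError(f"unknown route {route!r}; choose from {ROUTES}")
    if params is None:
        params = MeiosisParams()
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        if route == "AB_FDR_x_B":
            parent = make_parent("AB", chroms)
            g2x = meiosis(parent, MeiosisParams("FDR", params.pairing_prob, params.crossover_rate, rep_seed), chroms)
            gx = GameteGenome({c.name: [pure_chromosome(c, "B")] for c in chroms})
        elif route == "A_x_BB":
            g2x = GameteGenome({c.name: [pure_chromosome(c, "B")] * 2 for c in chroms})
            gx = GameteGenome({c.name: [pure_chromosome(c, "A")] for c in chroms})
        elif route == "ABB_2x_x_B":
            parent = make_parent("ABB", chroms)
            g2x = triploid_2x_gamete(parent, seed=rep_seed)
            gx = GameteGenome({c.name: [pure_chromosome(c, "B")] for c in chroms})
        else:  # AB_backcross_2x_x_B
            ab = make_parent("AB", chroms)
            gx_ab = meiosis(
                ab, MeiosisParams("reduced", params.pairing_prob, params.crossover_rate, rep_seed), chroms
            )
            gx_b = GameteGenome({c.name: [pure_chromosome(c, "B")] for c in chroms})
            hybrid, _ = cross(gx_ab, gx_b, chroms, "backcrossed_hybrid")
            g2x = meiosis(
                hybrid,
                MeiosisParams("FDR", params.pairing_prob, params.crossover_rate, rep_seed + 1),
                chroms,
            )
            gx = GameteGenome({c.name: [pure_chromosome(c, "B")] for c in chroms})
        offspring, karyotype = cross(g2x, gx, chroms, f"{route}_{rep}")
        n_b_cen, n_he = _offspring_stats(karyotype, offspring, chroms)
        rows.append((route, rep, n_b_cen, n_he))
    return pd.DataFrame(rows, columns=["route", "rep", "n_all_b_centromeres", "n_he_segments"])
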