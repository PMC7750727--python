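"""Homologous-exchange events, founding patterns and chromosome tallies.

A segment whose Ax:By state deviates from the baseline (A1:B2 in a
triploid, A1:B1 in a diploid) while keeping the baseline total copy
number is a homologous exchange (HE); a deviating *total* copy number
is an aneuploidy, which arose after the founding triploidization and is
therefore excluded from pattern signatures. Accessions sharing an
identical HE event set (up to a breakpoint tolerance) form one founding
pattern, interpreted as a single triploidization event followed by
clonal propagation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from musakaryo.chromosomes import ChromosomeSpec, chrom_map
from musakaryo.karyotype import DosageSegment

__all__ = [
    "HEEvent",
    "HEPatternGroup",
    "AccessionRecord",
    "FixtureError",
    "locate_region",
    "call_he_events",
    "match_event",
    "group_patterns",
    "count_unique_hes",
    "chromosome_counts",
    "load_table1_fixture",
    "load_pattern_events",
    "events_to_frame",
]

DEFAULT_BREAKPOINT_TOLERANCE = 1_000_000  # ~2 windows; similarity judged visually in the field
DEFAULT_END_TOLERANCE = 1_000_000

_PATTERN_VOCAB = (
    {"1a", "1b", "1c", "2", "3", "4", "5", "6", "7", "N/A", "(2x)"}
    | {f"2x-{i}" for i in range(1, 5)}
)


class FixtureError(RuntimeError):
    """Raised when a packaged fixture fails its integrity checks."""


@dataclass(frozen=True, order=True)
class HEEvent:
    """A deviating segment, localized to arm and terminal/interstitial class."""

    chrom: str
    start: int
    end: int
    a_copies: int
    b_copies: int
    arm: str  # first | second | spanning
    locclass: str  # terminal | interstitial | whole_chromosome

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.chrom}: start must be < end")
        if self.arm not in ("first", "second", "spanning"):
            raise ValueError(f"invalid arm {self.arm!r}")
        if self.locclass not in ("terminal", "interstitial", "whole_chromosome"):
            raise ValueError(f"invalid locclass {self.locclass!r}")

    @property
    def state(self) -> tuple[int, int]:
        return (self.a_copies, self.b_copies)


@dataclass
class HEPatternGroup:
    """Accessions sharing one founding HE pattern."""

    pattern_id: str
    members: list[str]
    canonical_events: list[HEEvent]
    aneuploid_members: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AccessionRecord:
    """One row of the published accession table."""

    itc_code: str
    name: str
    doi: str
    genome: str
    subgroup: str
    collection: str
    origin: str
    cytotype: str
    pattern: str

    @property
    def base_pattern(self) -> str:
        """Pattern label with the aneuploidy marker ('+') stripped."""
        return self.pattern.rstrip("+")

    @property
    def has_aneuploidy(self) -> bool:
        return self.pattern.endswith("+")


def locate_region(
    start: int,
    end: int,
    chrom: ChromosomeSpec,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> tuple[str, str]:
    """Arm and terminal/interstitial class of a segment.

    A segment is *terminal* when it reaches a chromosome extremity
    (within ``end_tolerance``), *whole_chromosome* when it reaches
    both. Arms are "first"/"second" by position relative to the
    centromere (chromosome midpoint when the centromere is unknown);
    segments crossing it are "spanning".
    """
    if not (1 <= start <= end <= chrom.length):
        raise ValueError(f"segment {start}-{end} outside {chrom.name} (1-{chrom.length})")
    at_left = (start - 1) <= end_tolerance
    at_right = (chrom.length - end) <= end_tolerance
    if at_left and at_right:
        return ("spanning", "whole_chromosome")
    locclass = "terminal" if (at_left or at_right) else "interstitial"
    cen = chrom.centromere
    if end <= cen:
        arm = "first"
    elif start > cen:
        arm = "second"
    else:
        arm = "spanning"
    return (arm, locclass)


def call_he_events(
    karyotype: list[DosageSegment],
    baseline_ploidy: int,
    chroms: list[ChromosomeSpec],
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> tuple[list[HEEvent], list[HEEvent]]:
    """Split deviating segments into HE events and aneuploidies.

    Segments at the baseline state produce nothing. Deviating segments
    with the baseline total copy number become HE events; segments with
    a different total are genotype-specific aneuploidies, returned
    separately (they postdate the founding event and never enter
    pattern signatures).
    """
    if baseline_ploidy == 2:
        baseline = (1, 1)
    elif baseline_ploidy == 3:
        baseline = (1, 2)
    else:
        raise ValueError(f"baseline_ploidy must be 2 or 3, got {baseline_ploidy}")
    cmap = chrom_map(chroms)
    hes: list[HEEvent] = []
    aneu: list[HEEvent] = []
    for seg in karyotype:
        if seg.state == baseline:
            continue
        if seg.chrom not in cmap:
            raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
        arm, locclass = locate_region(seg.start, seg.end, cmap[seg.chrom], end_tolerance)
        ev = HEEvent(seg.chrom, seg.start, seg.end, seg.a_copies, seg.b_copies, arm, locclass)
        if seg.a_copies + seg.b_copies == baseline_ploidy:
            hes.append(ev)
        else:
            aneu.append(ev)
    return sorted(hes), sorted(aneu)


def match_event(
    e1: HEEvent, e2: HEEvent, breakpoint_tolerance: int = DEFAULT_BREAKPOINT_TOLERANCE
) -> bool:
    """Whether two HE events represent the same exchange.

    Requires identical chromosome, Ax:By state and locclass, and both
    breakpoints within ``breakpoint_tolerance``.
    """
    return (
        e1.chrom == e2.chrom
        and e1.state == e2.state
        and e1.locclass == e2.locclass
        and abs(e1.start - e2.start) <= breakpoint_tolerance
        and abs(e1.end - e2.end) <= breakpoint_tolerance
    )


def _sets_match(
    a: list[HEEvent], b: list[HEEvent], tolerance: int
) -> bool:
    """True iff a bijection of pairwise-matching events exists."""
    if len(a) != len(b):
        return False
    if not a:
        return True
    # small sets: backtracking bipartite matching
    candidates = [
        [j for j, eb in enumerate(b) if match_event(ea, eb, tolerance)] for ea in a
    ]

    used: set[int] = set()

    def assign(i: int) -> bool:
        if i == len(a):
            return True
        for j in candidates[i]:
            if j not in used:
                used.add(j)
                if assign(i + 1):
                    return True
                used.discard(j)
        return False

    return assign(0)


def group_patterns(
    events_by_accession: dict[str, list[HEEvent]],
    breakpoint_tolerance: int = DEFAULT_BREAKPOINT_TOLERANCE,
    aneuploid_accessions: set[str] | None = None,
    baselines: dict[str, int] | None = None,
) -> list[HEPatternGroup]:
    """Group accessions whose HE event sets fully match pairwise.

    Aneuploid accessions group by their HE signature alone and are
    flagged in ``aneuploid_members`` (the '+' annotation). Group labels
    ("G1", "G2", ...) are deterministic: groups are ordered by their
    alphabetically first member, and accession input order never
    matters.
    """
    if baselines is not None and len(set(baselines.values())) > 1:
        raise ValueError(f"mixed baseline ploidies in one grouping call: {sorted(set(baselines.values()))}")
    aneuploid_accessions = aneuploid_accessions or set()
    accs = sorted(events_by_accession)
    groups: list[list[str]] = []
    reps: list[list[HEEvent]] = []
    for acc in accs:
        evs = sorted(events_by_accession[acc])
        placed = False
        for gi, rep in enumerate(reps):
            if _sets_match(evs, rep, breakpoint_tolerance):
                groups[gi].append(acc)
                placed = True
                break
        if not placed:
            groups.append([acc])
            reps.append(evs)
    order = sorted(range(len(groups)), key=lambda gi: groups[gi][0])
    out = []
    for rank, gi in enumerate(order, start=1):
        members = groups[gi]
        out.append(
            HEPatternGroup(
                pattern_id=f"G{rank}",
                members=members,
                canonical_events=reps[gi],
                aneuploid_members=[m for m in members if m in aneuploid_accessions],
            )
        )
    return out


def count_unique_hes(
    groups: list[HEPatternGroup],
    breakpoint_tolerance: int = DEFAULT_BREAKPOINT_TOLERANCE,
) -> int:
    """Number of distinct HEs across groups, counting shared HEs once.

    Events are pooled over all groups' canonical sets and merged by
    transitive closure of :func:`match_event` (union-find); the count
    is the number of equivalence classes.
    """
    events = [e for g in groups for e in g.canonical_events]
    n = len(events)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if match_event(events[i], events[j], breakpoint_tolerance):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return len({find(i) for i in range(n)})


def chromosome_counts(
    karyotype: list[DosageSegment], chroms: list[ChromosomeSpec]
) -> tuple[int, int]:
    """Whole-genome A/B chromosome tallies from centromeric states.

    Each chromosome contributes the (a, b) state of the segment
    covering its centromere; for a euploid triploid the totals sum to
    33. Chromosomes whose centromere falls in a no-call segment are
    skipped with a warning (partial result).
    """
    n_a = n_b = 0
    for c in chroms:
        cen = c.centromere
        hit = None
        for seg in karyotype:
            if seg.chrom == c.name and seg.start <= cen <= seg.end:
                hit = seg
                break
        if hit is None or hit.confidence == 0.0:
            warnings.warn(f"centromere of {c.name} not covered by a classified segment; partial totals")
            continue
        n_a += hit.a_copies
        n_b += hit.b_copies
    return n_a, n_b


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str):
    return resources.files("musakaryo.fixtures").joinpath(name)


def load_table1_fixture() -> list[AccessionRecord]:
    """The 45-accession survey table (36 ABB, 9 AB).

    Raises :class:`FixtureError` when the packaged file drifts from its
    documented schema (row count, genome classes, pattern vocabulary).
    """
    with resources.as_file(_fixture_path("table1.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = [AccessionRecord(**row) for row in df.to_dict("records")]
    if len(records) != 45:
        raise FixtureError(f"expected 45 accession records, found {len(records)}")
    genomes = {r.genome for r in records}
    if not genomes <= {"AB", "ABB", "ABB (M)", "ABB (AB)"}:
        raise FixtureError(f"unexpected genome classes: {sorted(genomes)}")
    n_ab = sum(r.genome == "AB" for r in records)
    if n_ab != 9 or len(records) - n_ab != 36:
        raise FixtureError(f"expected 9 AB / 36 ABB-class records, found {n_ab}/{len(records) - n_ab}")
    bad = {r.base_pattern for r in records} - _PATTERN_VOCAB
    if bad:
        raise FixtureError(f"pattern labels outside controlled vocabulary: {sorted(bad)}")
    return records


def load_pattern_events(
    chroms: list[ChromosomeSpec] | None = None,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> dict[str, tuple[int, list[HEEvent]]]:
    """HE event sets of the text-described founding patterns.

    Returns ``{pattern_label: (baseline_ploidy, events)}`` for triploid
    patterns 1a/1b/1c/4/5 and diploid patterns 2x-1..2x-4. Breakpoint
    coordinates are synthetic stand-ins on the default chromosome
    metadata (see the fixture file header); arm placement, event class
    and Ax:By states follow the published descriptions.
    """
    from musakaryo.chromosomes import default_chromosomes

    if chroms is None:
        chroms = default_chromosomes()
    cmap = chrom_map(chroms)
    with resources.as_file(_fixture_path("pattern_events.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, tuple[int, list[HEEvent]]] = {}
    for pattern, g in df.groupby("pattern", sort=False):
        ploidies = set(g["baseline_ploidy"].astype(int))
        if len(ploidies) != 1:
            raise FixtureError(f"pattern {pattern}: inconsistent baseline ploidy")
        events = []
        for r in g.itertuples(index=False):
            chrom = cmap[str(r.chrom)]
            arm, locclass = locate_region(int(r.start), int(r.end), chrom, end_tolerance)
            events.append(
                HEEvent(
                    str(r.chrom), int(r.start), int(r.end),
                    int(r.a_copies), int(r.b_copies), arm, locclass,
                )
            )
        out[str(pattern)] = (ploidies.pop(), sorted(events))
    return out


def events_to_frame(events: list[HEEvent]) -> pd.DataFrame:
    """BED-like table of HE events with state columns."""
    return pd.DataFrame(
        [
            (e.chrom, e.start, e.end, e.a_copies, e.b_copies, e.arm, e.locclass)
            for e in events
        ],
        columns=["chrom", "start", "end", "a_copies", "b_copies", "arm", "locclass"],
    )
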