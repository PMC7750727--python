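"""Windowed dosage profiles, segmentation and Ax:By classification.

The observable model: at an ancestry-diagnostic site inside a region
with ``a`` A-copies and ``b`` B-copies, B-assigned reads are binomial
with success probability ``b/(a+b)``, and total site depth is
proportional to ``a+b``. Chromosomes are summarized in fixed windows,
segmented at change points of the joint (B-fraction, coverage)
likelihood, and each segment is assigned the (a, b) state that
maximizes the combined likelihood of its pooled B-read counts, its
normalized coverage, and — where the B fraction alone is uninformative,
e.g. A0:B2 vs A0:B3 — the modality of residual within-subgenome
heterozygous allele fractions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from musakaryo.chromosomes import ChromosomeSpec, chrom_map

__all__ = [
    "KaryotypeParams",
    "WindowProfile",
    "DosageSegment",
    "window_profiles",
    "expected_b_fraction",
    "het_modality",
    "segment_chromosome",
    "segment_exhaustive",
    "classify_segment",
    "karyotype_accession",
    "segments_to_frame",
]

_EPS = 1e-3  # clipping for binomial rates at states with f in {0, 1}


@dataclass(frozen=True)
class KaryotypeParams:
    """Tunable parameters of the karyotyping stage.

    window_size
        Window width in bp (default 500 kb).
    min_sites
        Minimum diagnostic sites for a window to be callable.
    penalty
        Change-point penalty scale; the per-breakpoint penalty is
        ``penalty * log(n_windows)`` on the -2 log-likelihood scale.
    cov_sd
        Assumed per-window standard deviation of normalized coverage,
        used in both segmentation and state classification.
    het_min_sites
        Minimum residual-heterozygosity sites for a modality call.
    het_weight
        Log-likelihood bonus granted to the copy-number state agreeing
        with an informative heterozygosity-modality call.
    min_total_depth
        Windows also need positive read depth to be callable.
    min_event_windows
        Minimum callable windows per reported segment. True change
        points rarely align with window edges, so the window straddling
        a breakpoint mixes two states and would otherwise surface as a
        spurious one-window segment of an intermediate state; segments
        below this size are absorbed into the likelihood-preferred
        neighbor.
    """

    window_size: int = 500_000
    min_sites: int = 10
    penalty: float = 10.0
    cov_sd: float = 0.1
    het_min_sites: int = 10
    het_weight: float = 50.0
    min_total_depth: int = 1
    min_event_windows: int = 2

    def allowed_states(self, baseline_ploidy: int) -> list[tuple[int, int]]:
        """Candidate (a, b) states for a baseline ploidy.

        Triploids may carry 2-4 total copies, diploids 1-2; states
        outside those totals are never emitted.
        """
        totals = {3: (2, 3, 4), 2: (1, 2)}.get(baseline_ploidy)
        if totals is None:
            raise ValueError(f"unsupported baseline ploidy {baseline_ploidy}")
        return [
            (a, t - a)
            for t in totals
            for a in range(t + 1)
        ]


@dataclass
class WindowProfile:
    """Per-window summary of ancestry-assigned depths."""

    chrom: str
    start: int
    end: int
    n_sites: int
    b_reads: int
    total_reads: int
    norm_coverage: float
    het_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))
    het_depths: np.ndarray = field(default_factory=lambda: np.empty(0))
    callable: bool = True

    @property
    def b_fraction(self) -> float:
        if self.total_reads == 0:
            return float("nan")
        return self.b_reads / self.total_reads


@dataclass(frozen=True)
class DosageSegment:
    """A chromosome interval with an inferred (a_copies, b_copies) state."""

    chrom: str
    start: int
    end: int
    a_copies: int
    b_copies: int
    confidence: float = 1.0

    @property
    def state(self) -> tuple[int, int]:
        return (self.a_copies, self.b_copies)


def expected_b_fraction(a_copies: int, b_copies: int) -> float:
    """Expected fraction of B-assigned reads for an Ax:By state.

    A0:B3 regions show only B-assigned SNP reads (1.0); A2:B1 regions
    show one-third B (1/3); A2:B0 means B-specific reads are missing
    entirely (0.0).
    """
    total = a_copies + b_copies
    if total <= 0:
        raise ValueError("a_copies + b_copies must be >= 1")
    return b_copies / total


def window_profiles(
    sites: pd.DataFrame,
    chroms: list[ChromosomeSpec],
    params: KaryotypeParams = KaryotypeParams(),
    het_sites: pd.DataFrame | None = None,
) -> list[WindowProfile]:
    """Summarize per-site A/B depths into fixed-width windows.

    Parameters
    ----------
    sites : pandas.DataFrame
        Columns ``chrom, pos, depth_a, depth_b`` (sorted or not).
    chroms : list of ChromosomeSpec
        Windows tile each chromosome exactly; the last window of a
        chromosome is truncated at its length.
    het_sites : pandas.DataFrame, optional
        Columns ``chrom, pos, minor_fraction`` (plus optional
        ``depth``) of residual within-subgenome heterozygous sites.

    Notes
    -----
    ``norm_coverage`` divides the window's mean per-site depth by the
    genome-wide per-site *median* depth, which is robust to regions of
    deviating copy number. Windows with fewer than ``min_sites``
    retained sites are flagged non-callable but kept in the output so
    that windows always tile chromosomes.
    """
    cmap = chrom_map(chroms)
    unknown = set(sites["chrom"].astype(str)) - set(cmap)
    if unknown:
        raise ValueError(f"sites reference unknown chromosomes: {sorted(unknown)}")
    depth = (sites["depth_a"] + sites["depth_b"]).to_numpy()
    median_depth = float(np.median(depth)) if len(depth) else float("nan")

    het_by_chrom: dict[str, pd.DataFrame] = {}
    if het_sites is not None and len(het_sites):
        het_by_chrom = {str(c): g for c, g in het_sites.groupby("chrom")}

    profiles: list[WindowProfile] = []
    grouped = {str(c): g for c, g in sites.groupby("chrom")}
    for c in chroms:
        g = grouped.get(c.name)
        pos = g["pos"].to_numpy() if g is not None else np.empty(0, dtype=int)
        da = g["depth_a"].to_numpy() if g is not None else np.empty(0, dtype=int)
        db = g["depth_b"].to_numpy() if g is not None else np.empty(0, dtype=int)
        gh = het_by_chrom.get(c.name)
        hpos = gh["pos"].to_numpy() if gh is not None else np.empty(0, dtype=int)
        hfr = gh["minor_fraction"].to_numpy() if gh is not None else np.empty(0)
        if gh is not None and "depth" in gh.columns:
            hdp = gh["depth"].to_numpy(dtype=float)
        else:
            hdp = np.full(len(hpos), _DEFAULT_HET_DEPTH, dtype=float)
        for start in range(1, c.length + 1, params.window_size):
            end = min(start + params.window_size - 1, c.length)
            in_win = (pos >= start) & (pos <= end)
            n = int(in_win.sum())
            b_reads = int(db[in_win].sum())
            total = int(da[in_win].sum() + b_reads)
            if n > 0 and median_depth > 0:
                norm_cov = (total / n) / median_depth
            else:
                norm_cov = float("nan")
            in_h = (hpos >= start) & (hpos <= end)
            ok = n >= params.min_sites and total >= params.min_total_depth
            profiles.append(
                WindowProfile(
                    chrom=c.name,
                    start=start,
                    end=end,
                    n_sites=n,
                    b_reads=b_reads,
                    total_reads=total,
                    norm_coverage=norm_cov,
                    het_fractions=hfr[in_h],
                    het_depths=hdp[in_h],
                    callable=ok,
                )
            )
    return profiles


_DEFAULT_HET_DEPTH = 20.0


def het_modality(
    het_fractions: np.ndarray | list[float],
    min_sites: int = 10,
    depths: np.ndarray | list[float] | None = None,
) -> str:
    """Classify residual-heterozygosity allele fractions by copy number.

    Compares, site by site, the binomial likelihood of the observed
    allele reads under a two-copy model (allele fraction 1/2) against a
    three-copy model (equal mixture of fractions 1/3 and 2/3), and
    returns ``"unimodal_half"`` or ``"multimodal_thirds"`` by the total
    log-likelihood, or ``"insufficient"`` below ``min_sites``
    observations. A likelihood comparison (not a distance to the modes)
    is required because the *folded* minor-allele fraction is biased
    below its mode at finite depth. Without per-site depths a nominal
    depth is assumed.
    """
    x = np.asarray(het_fractions, dtype=float)
    keep = (x > 0) & (x < 1)
    x = x[keep]
    if len(x) < min_sites:
        return "insufficient"
    if depths is None:
        n = np.full(len(x), _DEFAULT_HET_DEPTH)
    else:
        n = np.asarray(depths, dtype=float)[keep]
        n = np.where(n > 0, n, _DEFAULT_HET_DEPTH)
    k = np.round(x * n)

    def loglik(p: float) -> np.ndarray:
        return k * math.log(p) + (n - k) * math.log(1.0 - p)

    ll_half = float(np.sum(loglik(0.5)))
    per_site = np.logaddexp(loglik(1.0 / 3.0), loglik(2.0 / 3.0)) - math.log(2.0)
    ll_thirds = float(np.sum(per_site))
    return "unimodal_half" if ll_half >= ll_thirds else "multimodal_thirds"


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _segment_cost(
    b: np.ndarray, t: np.ndarray, c: np.ndarray, cov_sd: float
) -> float:
    """-2 x maximized log-likelihood of one segment (binomial + Gaussian)."""
    B, T = float(b.sum()), float(t.sum())
    cost = 0.0
    if T > 0:
        r = min(max(B / T, _EPS), 1.0 - _EPS)
        cost += -2.0 * (B * math.log(r) + (T - B) * math.log(1.0 - r))
    cmean = float(c.mean())
    cost += float(((c - cmean) ** 2).sum()) / (cov_sd**2)
    return cost


def _window_arrays(windows: list[WindowProfile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    b = np.array([w.b_reads for w in windows], dtype=float)
    t = np.array([w.total_reads for w in windows], dtype=float)
    c = np.array([w.norm_coverage for w in windows], dtype=float)
    c = np.nan_to_num(c, nan=1.0)
    return b, t, c


def segment_chromosome(
    windows: list[WindowProfile], params: KaryotypeParams = KaryotypeParams()
) -> list[int]:
    """Optimal penalized segmentation of one chromosome's windows.

    Minimizes total segment cost (-2 log-likelihood, binomial B-read
    counts plus Gaussian normalized coverage) plus
    ``penalty * log(n)`` per change point, by exact dynamic-programming
    optimal partitioning over callable windows.

    Returns
    -------
    list of int
        Breakpoint coordinates in bp: each is the ``start`` of the
        first window of a new segment. Empty when the chromosome is
        homogeneous.
    """
    callable_windows = [w for w in windows if w.callable]
    n = len(callable_windows)
    if n == 0:
        return []
    if len({w.chrom for w in callable_windows}) != 1:
        raise ValueError("segment_chromosome expects windows of a single chromosome")
    b, t, c = _window_arrays(callable_windows)
    beta = params.penalty * math.log(max(n, 2))

    # cost[i][j]: cost of segment spanning callable windows i..j-1
    cost = np.full((n + 1, n + 1), np.nan)
    for i in range(n):
        for j in range(i + 1, n + 1):
            cost[i, j] = _segment_cost(b[i:j], t[i:j], c[i:j], params.cov_sd)

    best = np.full(n + 1, np.inf)
    best[0] = -beta  # first segment pays no penalty
    prev = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        cands = best[:j] + cost[:j, j] + beta
        i = int(np.argmin(cands))
        best[j] = cands[i]
        prev[j] = i
    # backtrack
    cuts = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            cuts.append(i)
        j = i
    cuts.reverse()
    return [callable_windows[k].start for k in cuts]


def segment_exhaustive(
    windows: list[WindowProfile],
    params: KaryotypeParams = KaryotypeParams(),
    max_changepoints: int | None = None,
) -> list[int]:
    """Brute-force minimizer of the same penalized objective.

    Enumerates every breakpoint subset (optionally capped at
    ``max_changepoints``) — exponential, intended for small instances
    and for validating :func:`segment_chromosome`.
    """
    callable_windows = [w for w in windows if w.callable]
    n = len(callable_windows)
    if n == 0:
        return []
    b, t, c = _window_arrays(callable_windows)
    beta = params.penalty * math.log(max(n, 2))
    kmax = n - 1 if max_changepoints is None else min(max_changepoints, n - 1)

    def objective(cuts: tuple[int, ...]) -> float:
        bounds = (0, *cuts, n)
        total = beta * len(cuts)
        for i, j in zip(bounds, bounds[1:]):
            total += _segment_cost(b[i:j], t[i:j], c[i:j], params.cov_sd)
        return total

    best_cuts: tuple[int, ...] = ()
    best_val = objective(())
    for k in range(1, kmax + 1):
        for cuts in itertools.combinations(range(1, n), k):
            val = objective(cuts)
            if val < best_val - 1e-12:
                best_val = val
                best_cuts = cuts
    return [callable_windows[k].start for k in best_cuts]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_segment(
    b_reads: int,
    total_reads: int,
    norm_coverages: np.ndarray | list[float],
    het_fractions: np.ndarray | list[float],
    baseline_ploidy: int,
    params: KaryotypeParams = KaryotypeParams(),
    het_depths: np.ndarray | list[float] | None = None,
) -> tuple[int, int, float]:
    """Assign an (a_copies, b_copies) state to one segment.

    Combines the binomial likelihood of pooled B reads at rate
    ``b/(a+b)``, the Gaussian likelihood of per-window normalized
    coverage around ``(a+b)/baseline_ploidy``, and — when enough
    residual-heterozygosity sites are present — a bonus for the state
    matching the observed modality. Ties break toward the baseline
    state (an exchange call requires an observed change).

    Returns ``(a_copies, b_copies, confidence)``; confidence is the
    posterior weight of the chosen state under a flat prior over the
    allowed states.
    """
    if total_reads <= 0:
        raise ValueError("classify_segment needs a segment with observed reads")
    states = params.allowed_states(baseline_ploidy)
    baseline = (1, 1) if baseline_ploidy == 2 else (1, 2)
    cov = np.asarray(norm_coverages, dtype=float)
    cov = cov[~np.isnan(cov)]
    modality = het_modality(het_fractions, params.het_min_sites, depths=het_depths)

    logliks = []
    for a, b in states:
        f = min(max(expected_b_fraction(a, b), _EPS), 1.0 - _EPS)
        ll = b_reads * math.log(f) + (total_reads - b_reads) * math.log(1.0 - f)
        if len(cov):
            exp_cov = (a + b) / baseline_ploidy
            ll += -float(((cov - exp_cov) ** 2).sum()) / (2.0 * params.cov_sd**2)
        if modality == "unimodal_half" and (a, b) == (0, 2):
            ll += params.het_weight
        elif modality == "multimodal_thirds" and (a, b) == (0, 3):
            ll += params.het_weight
        if (a, b) == baseline:
            ll += 1e-9  # deterministic tie-break toward baseline
        logliks.append(ll)
    logliks = np.array(logliks)
    best = int(np.argmax(logliks))
    w = np.exp(logliks - logliks.max())
    confidence = float(w[best] / w.sum())
    a, b = states[best]
    return a, b, confidence


def karyotype_accession(
    sites: pd.DataFrame,
    chroms: list[ChromosomeSpec],
    params: KaryotypeParams = KaryotypeParams(),
    het_sites: pd.DataFrame | None = None,
    baseline_ploidy: int = 3,
) -> list[DosageSegment]:
    """Windows -> segmentation -> classification for one accession.

    Returns dosage segments tiling every chromosome in ``chroms``.
    Chromosomes without a single callable window are emitted as one
    baseline segment with confidence 0 (no-call).
    """
    profiles = window_profiles(sites, chroms, params, het_sites)
    baseline = (1, 1) if baseline_ploidy == 2 else (1, 2)
    out: list[DosageSegment] = []
    for c in chroms:
        wins = [w for w in profiles if w.chrom == c.name]
        callable_wins = [w for w in wins if w.callable]
        if not callable_wins:
            out.append(DosageSegment(c.name, 1, c.length, *baseline, confidence=0.0))
            continue
        cuts = segment_chromosome(wins, params)
        bounds = [1, *cuts, c.length + 1]
        pieces: list[tuple[int, int, list[WindowProfile]]] = []
        for lo, hi in zip(bounds, bounds[1:]):
            seg_wins = [w for w in callable_wins if lo <= w.start < hi]
            if seg_wins:
                pieces.append((lo, hi - 1, seg_wins))
        pieces = _absorb_short_segments(pieces, baseline_ploidy, params)
        for lo, hi, seg_wins in pieces:
            a, b, conf = _classify_windows(seg_wins, baseline_ploidy, params)
            out.append(DosageSegment(c.name, lo, hi, a, b, conf))
    return out


def _classify_windows(
    seg_wins: list[WindowProfile], baseline_ploidy: int, params: KaryotypeParams
) -> tuple[int, int, float]:
    return classify_segment(
        sum(w.b_reads for w in seg_wins),
        sum(w.total_reads for w in seg_wins),
        [w.norm_coverage for w in seg_wins],
        np.concatenate([w.het_fractions for w in seg_wins]),
        baseline_ploidy,
        params,
        het_depths=np.concatenate([w.het_depths for w in seg_wins]),
    )


def _piece_loglik(
    seg_wins: list[WindowProfile], state: tuple[int, int], baseline_ploidy: int,
    params: KaryotypeParams,
) -> float:
    """Log-likelihood of a window run under a fixed (a, b) state."""
    a, b = state
    B = sum(w.b_reads for w in seg_wins)
    T = sum(w.total_reads for w in seg_wins)
    f = min(max(expected_b_fraction(a, b), _EPS), 1.0 - _EPS)
    ll = B * math.log(f) + (T - B) * math.log(1.0 - f)
    cov = np.array([w.norm_coverage for w in seg_wins], dtype=float)
    cov = cov[~np.isnan(cov)]
    if len(cov):
        ll += -float(((cov - (a + b) / baseline_ploidy) ** 2).sum()) / (2.0 * params.cov_sd**2)
    return ll


def _absorb_short_segments(
    pieces: list[tuple[int, int, list[WindowProfile]]],
    baseline_ploidy: int,
    params: KaryotypeParams,
) -> list[tuple[int, int, list[WindowProfile]]]:
    """Merge segments shorter than ``min_event_windows`` into the
    neighbor whose state fits their data best (boundary windows mix two
    states and must not surface as events of their own)."""
    pieces = [list(p) for p in pieces]
    changed = True
    while changed and len(pieces) > 1:
        changed = False
        for i, (lo, hi, seg_wins) in enumerate(pieces):
            if len(seg_wins) >= params.min_event_windows:
                continue
            neighbors = []
            if i > 0:
                neighbors.append(i - 1)
            if i < len(pieces) - 1:
                neighbors.append(i + 1)
            if not neighbors:
                continue

            def neighbor_state(j: int) -> tuple[int, int]:
                a, b, _ = _classify_windows(pieces[j][2], baseline_ploidy, params)
                return (a, b)

            best = max(
                neighbors,
                key=lambda j: _piece_loglik(seg_wins, neighbor_state(j), baseline_ploidy, params),
            )
            j = best
            lo2, hi2, wins2 = pieces[j]
            merged = [min(lo, lo2), max(hi, hi2), (wins2 + seg_wins if j < i else seg_wins + wins2)]
            merged[2].sort(key=lambda w: w.start)
            pieces[min(i, j)] = merged
            del pieces[max(i, j)]
            changed = True
            break
    return [tuple(p) for p in pieces]


def segments_to_frame(segments: list[DosageSegment], accession: str = "") -> pd.DataFrame:
    """BED-like table of dosage segments."""
    df = pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.a_copies, s.b_copies, round(s.confidence, 4))
            for s in segments
        ],
        columns=["chrom", "start", "end", "a_copies", "b_copies", "confidence"],
    )
    if accession:
        df.insert(0, "accession", accession)
    return df
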