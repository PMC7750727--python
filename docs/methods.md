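# Methods

`musakaryo` infers the subgenome constitution of interspecific banana
hybrids — diploid AB and allotriploid ABB cultivars combining the
*Musa acuminata* (A) and *M. balbisiana* (B) genomes — from
ancestry-assigned SNP allele depths, and simulates the meiotic routes
that can generate the observed karyotypes. This note records the model,
the parameters that matter, and the design choices made where the
design was genuinely open.

## Observable model

Every analysis rests on *ancestry-diagnostic alleles*: alleles (nearly)
fixed in one ancestral gene pool and (nearly) absent from the other.
At a diagnostic site inside a genomic region carrying `a` copies of the
A subgenome and `b` copies of the B subgenome:

- reads carrying the B-diagnostic allele are binomial with success
  probability `f = b / (a + b)` — the expected B-read fraction is 1.0
  in an A0:B3 region, 2/3 at the ABB baseline A1:B2, 1/3 in A2:B1,
  0 in A2:B0;
- total site depth is proportional to the local copy number `a + b`,
  so normalized coverage (window mean depth over the genome-wide
  per-site median depth) is `(a + b) / ploidy` — 1.0 at baseline, 2/3
  for a monosomic region, 4/3 for a tetrasomic one;
- residual heterozygosity *within* a subgenome disambiguates states
  with identical B fraction: a site heterozygous inside the B
  subgenome shows allele fractions `k/b`, so fractions concentrate at
  1/2 when `b = 2` (A0:B2) and at {1/3, 2/3} when `b = 3` (A0:B3).

A *homologous exchange* (HE) is a segment whose (a, b) state deviates
from the baseline (A1:B2 in triploids, A1:B1 in diploids) while
keeping the baseline total; a deviating total is an *aneuploidy*.
Balanced (reciprocal) exchanges leave the allele ratio unchanged and
are invisible to this method by construction.

## Pipeline stages

**Diagnostic discovery.** An allele is diagnostic for a pool when its
frequency there is ≥ 0.95, its frequency in the other pool is ≤ 0.02,
and per-pool missingness is ≤ 0.2 (all tunable; the thresholds are this
package's choice — pool definitions are always an input, never
hard-coded). Only biallelic SNPs are considered. Mutual exclusivity of
assignments is structural: no allele can satisfy the frequency pair for
both pools.

**Depth assignment.** Per target site, reads of diagnostic alleles are
summed into A-assigned and B-assigned depth; sites without a diagnostic
allele, or with summed diagnostic depth < 4 (guarding ratio noise at
sparse RADSeq sites), are dropped.

**Windowing.** Fixed 500 kb windows (default) tile each chromosome.
Windows need ≥ 10 retained sites to be callable; non-callable windows
are kept (for tiling) but excluded from segmentation. With the
RADSeq-like densities simulated here (~1000 sites per 25–40 Mb
chromosome) this leaves essentially all windows callable.

**Segmentation.** Change points are found per chromosome by exact
optimal partitioning (an O(n²) dynamic program) over a joint objective:
per-segment −2 log-likelihood of pooled B reads (binomial at the
segment's MLE rate) plus normalized coverage (Gaussian with fixed
per-window standard deviation, default 0.1), with a penalty of
`penalty × log(n_windows)` per change point (default scale 10 on the
−2 log-likelihood scale). Exact optimization was preferred over greedy
binary splitting because it is provably identical to exhaustive
enumeration of the same objective, which the test suite checks directly
against a brute-force oracle on small instances.

**Classification.** Each segment is assigned the (a, b) pair
maximizing the combined likelihood of its pooled B reads, its
per-window coverage, and — when ≥ 10 residual-heterozygosity sites are
present — a bonus (default 50 log units) for the copy number matching
the heterozygosity modality. Modality itself is a per-site binomial
likelihood comparison of allele fraction 1/2 against an equal mixture
of 1/3 and 2/3; a likelihood test rather than a distance-to-mode rule
is required because the folded minor-allele fraction is biased below
its mode at finite depth. Allowed totals are {2, 3, 4} for triploids
and {1, 2} for diploids; other states are never emitted. Ties break
toward the baseline state, encoding the convention that an exchange
call requires an observed change.

**Minimum event size.** True breakpoints rarely coincide with window
edges, so the window straddling a breakpoint mixes two states and
would otherwise surface as a spurious one-window segment of an
intermediate state (e.g. A2:B2 between A1:B2 and A2:B1). Segments
shorter than `min_event_windows` (default 2) are therefore absorbed
into the neighbor whose state fits their data best. The method's
resolution limit is consequently `min_event_windows × window_size`
(1 Mb at defaults); breakpoint localization error is bounded by about
one window.

**HE calling and pattern grouping.** Deviating segments at the
baseline total become HE events, localized to an arm (first/second by
sequence order, relative to the centromere, chromosome midpoint when
unknown) and a class (terminal within 1 Mb of an extremity,
whole-chromosome when reaching both, else interstitial). Segments at a
different total are genotype-specific aneuploidies: they postdate the
founding triploidization and are excluded from pattern signatures but
flagged ('+'). Two events match when chromosome, state and class agree
and both breakpoints lie within a tolerance (default 1 Mb ≈ 2 windows;
the source literature judged similarity visually, so the tolerance is
a design decision and is surfaced in reports). Accessions whose event
sets fully match pairwise form one founding pattern; group labels are
deterministic under input permutation. Unique HE counts across
patterns use the transitive closure of event matching, so shared
events are counted once.

**Chromosome tallies.** Each chromosome contributes the (a, b) state
at its centromere; a euploid triploid therefore totals 33 chromosomes.

**Diversity.** Sites inside any analysed accession's HE (or
aneuploidy) interval are masked for all accessions, then pairwise
dissimilarity is 1 − mean identity-by-state over shared non-missing
sites (pairwise deletion), clustered by average linkage. Support per
clade is the fraction of site-bootstrap replicates (columns resampled
with replacement, default 100) reproducing its leaf set. IBS and
average linkage are this package's documented choices; the upstream
literature delegates both to external tools without fixing them.

## Meiosis simulation

Chromosomes are ordered A/B ancestry blocks; the centromere ancestry
of a homolog is the ancestry of the block containing the centromere.
Diploid meiosis pairs homologs with probability `pairing_prob`
(default 0.5 — "partial pairing" between homoeologs is described only
qualitatively, so this is a free parameter) and draws a Poisson number
of crossovers (mean `crossover_rate`, default 1) at uniform positions
between one chromatid of each homolog. Gamete modes:

- **reduced**: one random chromatid per chromosome (n = x);
- **FDR** (first-division restitution): one chromatid from each
  parental centromere group — an AB hybrid's FDR gamete always carries
  one A and one B centromere per chromosome;
- **SDR** (second-division restitution): the two sister chromatids of
  one homolog — identical centromere origin, possibly recombinant arms.

Triploid 2x gametes use only the random 2-of-3 centromere draw per
chromosome (P(BB) = 1/3 from an ABB parent); trivalent pairing
dynamics are deliberately not modeled, staying within the segregation
model the route hypotheses actually use. An AABB allotetraploid's
regular bivalent meiosis is modeled as a balanced 11 A + 11 B gamete
without homoeologous exchange.

Four crossing routes are cataloged: `AB_FDR_x_B` (unreduced AB gamete
× haploid B), `A_x_BB` (no pre-triploidy recombination possible),
`ABB_2x_x_B` (expected all-B centromeres 11/3), and
`AB_backcross_2x_x_B` (reduced AB gamete × B gives a backcrossed
hybrid whose FDR gamete has ≈ 11/2 all-B centromere pairs). The
simulator produces expectations only — no likelihood-based route
inference is attempted, since with 11 chromosomes the routes' count
distributions overlap substantially.

## Synthetic data: what it emulates and what it does not

The generator emulates RADSeq-scale sparse SNP sites, pool-private
alleles (with an optional "leaky" mode placing the private allele at
low frequency in the other pool), negative-binomial total depth
(mean `mean_depth × (a+b)/ploidy`, dispersion 10; RADSeq depth is
overdispersed relative to Poisson), binomial allele sampling given the
local state, and B-internal heterozygous sites at 5 % of the
per-chromosome site count (emitted only where `a = 0` and `b ≥ 2`,
where the signal is actually used; real data do not quantify this
rate). Defaults: 30× mean depth (per-site depth for the real data is
unreported; 30× is a realistic RADSeq choice), 1000 sites per
chromosome, 4 + 4 panel accessions.

Not emulated: read-level errors, mapping bias, restriction-site
dropout, allele-specific amplification, indels, population structure
within each ancestral pool, and linkage disequilibrium. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated statistical model, not robustness to every artifact of real
sequencing data.

Chromosome metadata defaults (11 chromosomes, 24–38 Mb, off-center
centromeres) are synthetic stand-ins in the realistic range for this
genome; the packaged founding-pattern event coordinates are likewise
synthetic stand-ins that encode the *qualitative* published
descriptions (chromosome, arm, terminal/interstitial, state) — the
source reports no coordinates. Patterns described only graphically
(2, 3, 6, 7) are deliberately not transcribed.

## Problem sizes

Test and demo workloads are sized for a desktop run: the demo cohort
uses 800 sites per chromosome with 1 Mb windows (the window is widened
so every window stays callable at that density, and the grouping
tolerance widens to 1.5 Mb accordingly); parameter-recovery suites use
20 seeds of six-chromosome accessions at 30× and 1000 sites per
chromosome; route expectations use a few hundred to 2000 replicates.
All are package choices that keep the full suite in the low minutes.

## Known limitations

- Events smaller than `min_event_windows × window_size` are not
  reportable; at RADSeq site densities this is an information limit,
  not merely an implementation one.
- Reciprocal (balanced) HEs are undetectable from allele ratios.
- Aneuploidy calls lean on coverage normalization by the genome-wide
  median; a genome in which most windows deviate from baseline would
  shift the median and bias copy-number calls.
- The A0:B2 / A0:B3 distinction requires enough residual-B
  heterozygous sites; in their absence the coverage term alone
  decides, with correspondingly lower confidence.
- Pattern grouping requires *complete* pairwise matching of event
  sets; an accession with one extra private HE founds its own pattern,
  mirroring the published convention rather than any clustering.
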