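# Methods

`asparascan` re-implements, as a tested pipeline, the comparative-genomics and
biochemical analysis used to delineate short-chain L-asparaginases (scASNases)
as a family distinct from the typical class 1 enzymes. This note records the
models and procedures, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Translated homology survey (`search`)

Genomes are translated in all six reading frames (codons containing N become
`X`; internal stops are kept as `*`; trailing partial codons are dropped) and
each protein query is aligned to each frame with an exact Smith–Waterman
local alignment under BLOSUM62 with affine gaps (open −11, extend −1 in the
BLAST convention, i.e. a gap of length *k* costs 11 + *k*). Exact dynamic
programming replaces the seeded heuristics of a production search tool:
exactness at desk scale matters more than speed here. `X` scores 0 against
everything; `*` scores −4 against everything, which confines alignments to
stop-free stretches without forbidding them outright.

Scores are converted to expectations with the Karlin–Altschul formula
E = K·m·n·e^(−λS), using the standard ungapped BLOSUM62 constants
(λ = 0.3176 nats, K = 0.134) as documented defaults, with *m* the query
length and *n* the total translated length of all six frames of the searched
genome set (per-search semantics of the cutoff). The survey keeps ORFs whose
best hit has E ≤ 0.01. Two caveats follow from this choice and are relied on
by the tests:

- An expectation cutoff of c *means* about c chance hits per query-search,
  so negative controls are validated in calibrated form — the total number
  of chance hits over many seeded backgrounds is Poisson-bounded, and any
  chance hit is a short spurious ORF — rather than by demanding literally
  zero hits on every run.
- Ungapped constants applied to gapped scores are permissive; this is
  irrelevant at the survey stage (planted genes score hundreds of points
  above threshold) but matters for the pairwise similarity graph (below).

ORFs are expanded from the aligned region to the flanking in-frame stop
codons (or sequence ends). Records carry both the stop-to-stop interval
(used for deduplication and for matching planted truth) and the
start-trimmed interval, beginning at the first in-frame ATG/GTG/TTG when one
exists (used for length statistics). Both conventions are exposed because
the field itself uses both. An in-frame stop inside the aligned region
triggers a warning and the sub-segment with the larger overlap wins.
Coordinates are 0-based half-open in memory and 1-based inclusive in every
written table; minus-strand features are always reported on forward-strand
coordinates.

## Length partition and similarity clustering (`familymap`)

Surveyed proteins split into short and long classes at 250 residues, the
midpoint of the gap in the bimodal length distribution (160–180 aa versus
300–400 aa); the cutoff is a parameter, not a claim about a boundary.
Pairwise similarities are computed on the N-terminal 150 residues (removing
length as a clustering signal) as w = min(cap, max(0, −log10 E)) with the
pairwise sequence lengths as m and n, cap 200.

Cluster membership uses a hard weight threshold plus connected components —
deterministic and testable, unlike an interactive force-directed
convergence. The default threshold is 10 (E ≤ 1e−10). This value is the one
genuinely open design choice of the module: measured Smith–Waterman scores
of *unrelated* random 150-mers average ~30 and reach ~57, so chance
similarities reach weights of 5–7 under the formula above, while family
members at ≥70% identity sit at weights of 60+. A threshold of 10 separates
the two regimes with a graph-wide false-edge probability around 1e−6 at
desk scale; a per-pair threshold of E ≤ 0.01 (weight 2) would, by the very
meaning of an expectation value, admit about one chance edge per hundred
pairs and cannot keep thousands of cross-family pairs clean.

The 2-D embedding is a seeded force-directed layout (attraction along edges
proportional to normalised weight, uniform repulsion, linear cooling from an
initial random placement in the unit square, default 1000 iterations). It is
for visualisation; the only asserted property is that planted families end
up closer within than between. Non-convergence returns the final coordinates
with a flag rather than raising.

Protein masses are average masses (residue masses plus one water, via
Biopython), reported in kDa; oligomer masses are protomer multiples.
Localization is consumed from a predictor label table (OTHER/SP/LIPO mapped
to cytoplasmic/SPI/SPII); records without a label default to cytoplasmic —
absence of a predicted signal peptide is read as cytoplasmic residence.
Re-implementing a signal-peptide predictor is out of scope.

## Co-occurrence statistics (`cooccur`)

One repertoire per species: long-chain counts by localization plus the
short-chain count. Species with several sequenced genomes are collapsed
presence-based: identical (length class, localization, protein sequence)
entries across a species' genomes count once. Coordinates cannot identify
"the same gene" across different assemblies, so sequence identity is the
collapsing key; a per-genome mode treats each genome as the counting unit.
The sc-fraction is reported for the long-chain count groups {0, 1, >1}; an
empty group is undefined (NaN), never 0.

## Conservation profiling (`conserve`)

Representatives are selected CD-HIT style: sequences sorted by decreasing
length greedily join the first representative they match at ≥0.9 identity
(identities in a global BLOSUM62 alignment divided by the shorter length,
the cited tool's convention). The built-in aligner is center-star (center =
minimal total edit distance; others merged through pairwise global
alignments under "once a gap, always a gap"); externally produced MSAs are
accepted as input wherever an alignment is consumed, since the aligner
behind the published figure is not named.

Per column, amino-acid frequencies exclude gaps and `X`; the Shannon score
is log2(20) − H in bits, so ~4.32 marks an invariant column and 0 a uniform
one. The alphabet size stays 20 even when `X` occurs. All-gap columns are
flagged and carry an undefined score.

The family consensus is the Levenshtein median string. Exact mode enumerates
all strings over the observed alphabet with lengths between the shortest and
longest input (a global minimiser exists in that range) and refuses
instances beyond ~2·10^6 candidates; heuristic mode starts from the set
medoid and hill-climbs over single-symbol substitutions, insertions and
deletions. The heuristic result is never worse than the best input string.
The median operates on ungapped sequences by default.

## Enzyme kinetics (`kinetics`)

The rate law is v = Vmax·S/(Km + S·(1 + S/Ki)), the standard single-site
uncompetitive substrate-inhibition form; Ki = ∞ recovers Michaelis–Menten.
Units: mM, mM·s⁻¹, s⁻¹. Vmax may be supplied directly or as kcat·E0.
Nessler absorbances convert to ammonia as c = 1000·A480/(ε·l) mM with
ε480 = 1302 M⁻¹cm⁻¹ and l = 1 cm defaults.

Two fitters are provided and both are reported in practice:

- Lineweaver–Burk: unweighted ordinary least squares of 1/v on 1/S (the
  classical double-reciprocal procedure), with points above S_max = 5 mM
  excluded by default because substrate inhibition above that concentration
  breaks the linearisation; Km = slope/intercept, Vmax = 1/intercept. A
  non-positive intercept flags failure rather than returning nonsense.
- Nonlinear least squares of the rate law itself (trust-region, positive
  bounds, starting values Vmax0 = 1.2·max v, Km0 = S at half-maximal v,
  Ki0 = 10·max S), the recommended fitter for noisy data.

A blank-rate column, when present, is subtracted before fitting. Relative
activities are 100·variant/wild-type with a detection floor of 0.1%
(turnovers three orders of magnitude below wild type are deemed inactive);
the floor is configurable. pH optima are the grid point of maximal mean
activity, ties broken to lower pH and flagged, boundary maxima flagged as
edges.

## Structure comparison (`structcmp`)

Cα traces are read from PDB/mmCIF (gemmi): first model, one Cα per residue,
highest-occupancy altloc, residues without Cα skipped. Same-protein chains
pair by residue number; cross-protein comparisons pair through a sequence
alignment, optionally with iterative outlier trimming (drop pairs deviating
by more than 2× the current rmsd, re-superpose, at most 5 cycles) because a
published "equivalent Cα pairs" selection is generally not enumerated.
Superposition is the Kabsch algorithm (SVD of the centred cross-covariance,
reflection corrected so the rotation is always proper); collinear inputs are
rejected as underdetermined. Percent sequence identity counts identical
columns over columns gap-free in both rows.

## Synthetic data (`synthdata`)

The generators define the study conditions for all desk-scale tests:

- Families: a random ancestor (first residue fixed to Met so planted genes
  begin with a start codon) copied with i.i.d. per-site substitution,
  replacements uniform over the other 19 residues. Uniform replacement is
  the simplest exchange model; a score-matrix-weighted variant would only
  sharpen the (already large) separation between families.
- Genomes: planted genes are reverse-translated (uniform synonymous codons),
  flanked by in-frame stops, embedded — reverse-complemented for minus-strand
  genes — in i.i.d. uniform A/C/G/T background (which maximises stop density
  and keeps spurious ORFs short), default 120 nt intergenic spacing. The
  truth table stores the forward-strand CDS interval; strand-aware
  translation of that locus reproduces the protein exactly, and the interval
  equals the stop-to-stop ORF the survey reports. Short-chain lengths default
  to 160–180 aa, long-chain to 300–400 aa.
- Kinetics: model velocities times mean-1 lognormal noise of a given
  coefficient of variation; the defaults mirror the published assay
  (substrate 0.095–67 mM, enzyme 282 nM or 72 nM, 5% a realistic assay CV).
- Coordinates: Gaussian reference clouds (sd 10 Å) under a supplied proper
  rotation/translation with optional per-coordinate Gaussian jitter.
- pH profiles: Gaussian bell in pH on the 14-buffer grid 4.5–11.

What the generators do **not** emulate: codon-usage bias, GC skew, operons,
promoters or RBS, sequencing error, phylogenetic correlation among species,
composition-biased proteomes, or assay drift. Passing the planted-truth
tests therefore demonstrates correctness of the algorithms under clean,
well-separated conditions — not recall or clustering accuracy on real
genome snapshots, where families are less separated and statistics are
confounded by shared ancestry.

## Problem sizes used by the test suite

The planted-truth checks run 3 genomes × 2 genes over 20 seeds for survey
recall, three families of sizes (40, 30, 30) over 20 seeds for clustering,
250 synthetic species for co-occurrence, 500 seeds × 20 points for the noisy
kinetics fits, and exhaustive-plus-sampled oracle comparisons for alignment,
median strings (alphabet 4, lengths ≤ 5) and superposition (100 instances).
These sizes make every check reproducible on a single CPU in minutes while
keeping each statistical assertion well-powered.

## Known limitations

- E-values use ungapped constants for gapped alignments and no edge
  correction; they are rankings with approximately calibrated scale, not
  exact tail probabilities.
- The center-star aligner is a stand-in; for publication-grade conservation
  figures an external progressive aligner should produce the MSA.
- The co-occurrence module reports descriptive fractions only; no
  phylogenetic correction for shared ancestry is attempted.
- Cross-protein rmsd depends on the pairing alignment and trimming
  parameters; small differences in the retained pair set move the value at
  the 0.1 Å scale.
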