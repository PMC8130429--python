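# Methods

## Problem and model

A somatic structural variant joins two reference loci into a breakpoint
junction that exists only in the tumor genome. Low-coverage long-read
sequencing detects such junctions at nucleotide resolution, but the raw
call set is dominated by two nuisance classes: alignment artifacts
(concentrated in repetitive sequence, carried by few, poorly mapping
reads) and germline variants (shared across unrelated genomes). `svenrich`
enriches for the somatic minority with a cascade of independent filters,
none of which requires matched germline sequencing:

- a deterministic pre-filter on caller FILTER status, insertion class and
  excluded chromosomes (Y, MT);
- a random-forest classifier over read-evidence, geometry and
  repeat-context features;
- a panel-of-normal (PON) blacklist of junctions seen in other samples;
- ranking by SV length, exploiting the empirical excess of very large
  events among somatic variants.

### Breakend representation

Each junction is two breakends `(chrom, pos, side)`, where `side` records
which reference flank is retained in the derived allele (`left` = sequence
up to `pos`, `right` = sequence from `pos` on). The four VCF bracket forms
map bijectively onto the four retained-side pairs; intrachromosomal
orientation classes correspond to deletion (left,right), tandem
duplication (right,left) and inversion (like-sided). Calls are stored
canonically (ends ordered by chromosome, then position; sides travel with
their ends), which makes junction identity, mate-pair deduplication and
window overlap well defined. Positions are 1-based internally (VCF
convention); BED tracks are 0-based half-open and converted at the
interface.

### Distance annotation

For a 1-based query `q` and 0-based half-open interval `[s, e)`, the
distance is 0 when `s < q ≤ e`, otherwise `min(|q − e|, |s + 1 − q|)`; a
call's distance to a track is the minimum over its two breakends (the
conservative choice for artifact flagging: one breakend in a repeat is
enough to doubt the call). Chromosomes with no track element return a
sentinel of 10^8 bp — finite, larger than any chromosome — so feature
vectors stay numeric. The index (sorted starts plus a running maximum of
ends per chromosome) answers point queries with two binary searches and is
property-tested against a linear scan.

### Classifier

Features (all user-overridable): supporting read count, median mapping
quality, median supporting read length, caller quality score, SV length
(translocations capped at 10^8 bp), a 4-way one-hot of the orientation
class, and log1p-transformed distances to simple repeats, gaps and
segmental duplications (log1p because the distances are heavy-tailed).
Missing caller features fall back to 0.

Training: stratified 2/3 train – 1/3 held-out split; 100 bootstrap rounds
each re-partition the training portion 90%–10% (seeded random partitions),
fit a forest on the 90% and score the 10%; precision and recall of
`score ≥ t` are averaged over rounds on a fixed grid of 201 thresholds.
The decision threshold is the smallest grid point whose mean precision
reaches the target (default 0.96); if that point misses the recall target
(default 0.995) the nearest feasible point is used with a warning, and if
no point reaches the precision target the maximum-precision point is used
with a warning. The final forest (500 trees, sqrt features per split,
seeded) is refit on the full training portion and evaluated once on the
held-out third; precision, recall and accuracy ((TP+TN)/n) are reported.
A fixed seed makes split, bootstraps, forest and threshold bit-
reproducible. The estimator follows the scikit-learn fit/predict protocol
and composes with sklearn model selection.

Truth sets for real data are built by window-intersecting three
independent call sets of the same genome (a call is a positive when it has
a ±100 bp partner in both other sets); calls not matching the intersection
are negatives.

### Panel-of-normal blacklist

Two databases are supported: a long-read panel (`sharc_db`) and a
short-read germline control panel (`ref_db`). A call is removed when both
breakends lie within the overlap window (default ±100 bp, accommodating
long-read breakpoint imprecision) of any entry from a *different* sample;
entries from the query sample are ignored so a sample present in the panel
cannot blacklist itself. Orientation must match by default; databases
derived from callers with lossy orientation can opt out
(`use_orientation=False`, the default for `ref_db`). The published
workflow does not state its overlap criterion; ±100 bp per breakend with
matching chromosome pair was chosen once as the analogous criterion and is
configurable.

### Ranking

Sized (intrachromosomal) calls are ordered by descending length, ties
broken by (chromosome, position) ascending for determinism; the Top-N
(default 20) is taken from this order. Translocations have no defined
length: they are appended after all sized calls in the full ranked output
and never enter the Top-N, but remain available for manual selection.

### Junction templates and primers

The derived-allele template is the retained flank of breakend A (read
5'→3' into the junction; reverse complemented when the right flank is the
retained one) concatenated with the retained flank of breakend B
(mirrored). `junction_offset` is the number of A-side bases; the template
records, per half, the source reference interval and reverse-complement
flag, so templates are verifiable by re-mapping. Flanks truncate at contig
edges; insertions have no reference-derivable template and are rejected
(they are removed by the pre-filter anyway, because the inserted sequence
cannot be inferred from low-coverage data).

The primer engine is self-contained: candidates of 18–27 nt with
nearest-neighbor Tm 57–63 °C (optimum 60 °C; 50 mM Na+ salt correction via
Biopython) and 20–80% GC; candidates containing N are disqualified. The
mutant pair must flank the junction (forward entirely left of the offset,
reverse entirely right), product size within the configured 30–230 bp;
pairs are scored by |Tm−60| per primer + pair ΔTm + 0.02/bp product-size
deviation from the range midpoint, ties broken by position, making output
deterministic. The best pair is provably optimal under this score
(exhaustive-enumeration oracle in the tests). Wild-type partners reuse the
mutant primer on the retained side of each breakend plus one new primer on
the reference continuation, so each wild-type amplicon shares exactly one
primer with the mutant amplicon; a side whose continuation admits no
candidate (e.g. low-complexity sequence) is omitted with a note, producing
single-sided assays. Hydrolysis probes (optional) aim for primer Tm + 8 °C,
with the mutant probe spanning the junction.

### Quantification

qPCR triage excludes a primer set when any of: more than one PCR product
(melt-curve peaks), germline−tumor Cq separation < 5 cycles, tumor
Cq > 20; all violated rules are reported. An undetected germline reaction
passes the separation rule (infinite separation) — that is the desired
outcome for a somatic junction — with an explanatory note.

dPCR inputs are chip-software molecule concentrations (molecules/µL); a
Poisson back-calculation from droplet counts (λ = −ln(1 − p/n)) is offered
as an optional helper only. VAF = 100·m/(m+w), computed against each
available wild-type side and, when both exist, also as their labeled mean.
Mutant molecules per mL plasma = m · V_chip / ((V_used/V_total) ·
V_plasma) with V_chip defaulting to the 28 µL chip input (kept
configurable). For log-scale displays, +1 is added to every value (axes
relabeled −1) so zeros survive. Concordance between paired measurement
series is Spearman's rank correlation (average ranks on ties) plus an
ordinary least-squares slope and intercept; constant series are flagged as
having undefined correlation.

## Synthetic data: what it emulates, and what it does not

The generator produces, under one seed, byte-identical: a random genome
(default four 500 kb autosome-like contigs plus 50 kb "chrY" and 16 kb
"chrMT", GC 0.41), Poisson-placed annotation tracks (simple repeats ~20
per 100 kb of 50–500 bp; gaps ~0.4 per 100 kb of 1–10 kb; segmental
duplications ~1 per 100 kb of 1–20 kb), a tumor call set, PON databases
and dPCR chip tables.

The default call set is 20 somatic + 50 germline + 500 false-positive
junctions — a desk-scale twin of the real composition in which somatic
calls are a small minority. Class-conditional distributions: somatic and
germline calls carry strong evidence (support 2+Poisson(8), mapq
N(55,4) clipped to 60, read length lognormal around 8 kb, caller score
N(0.85,0.08)) while false positives carry weak evidence (2+Poisson(0.5),
N(25,6), ~4 kb, N(0.30,0.10)) and are placed within ±200 bp of simple
repeat elements; somatic calls keep ≥2 kb clearance from repeats. Somatic
events are large (50–400 kb, log-uniform), germline events 1–50 kb, false
positives 60 bp–10 kb; 10% of each class are translocations; 10% of
germline and false positives are insertions, 30% of false positives are
non-PASS and 10% touch the excluded contigs — so every pre-filter clause
and the ranking assumption are exercised.

PON construction: each germline (90%) and false-positive (80%) junction is
injected under 1–3 of 10 panel samples with uniform ±half-window jitter on
both breakends, plus 20 random decoy junctions per panel sample; nothing
is ever injected within twice the overlap window of a somatic breakend, so
the somatic-absence guarantee is constructive. The classifier truth set
(default 1500 calls, half positive) draws the same evidence families, with
distance features reflecting track sparsity: negatives are near simple
repeats but only sometimes (20%) near the sparse gap/segdup tracks —
matching what annotation against sparse tracks actually produces.

dPCR tables draw molecule counts as Poisson variates whose expectations
satisfy the configured true VAF trajectory (default 8, 4, 1, 0, 2, 12 %)
at 50 wild-type molecules/µL and ~21,000 analyzable droplets.

Deliberately not modeled: read-level errors and mapping, breakpoint
micro-homology, real repeat families and GC structure, chromosome-scale
variation in artifact density, cross-sample batch effects, dPCR
fluorescence thresholding. Passing tests therefore demonstrate the
correctness and composition of the algorithms under controlled,
separable-by-construction conditions — not the classifier's real-world
error rate, which depends on the training data supplied.

## Numerical and design choices

- PASS semantics: the FILTER set must equal exactly {PASS}; missing ('.')
  is non-PASS.
- Chromosome matching is dialect-tolerant ("Y" ≡ "chrY", "M" ≡ "MT") by
  normalization rather than substring matching, so "MT" cannot match
  inside an unrelated contig name.
- BND mate pairs deduplicate to the canonical record; unmatched mates are
  kept as single calls with a warning. VCF INFO Float round trips at
  32-bit precision.
- Bootstrap rounds are seeded random partitions (not resamples) of the
  training portion, and the operating point is selected on the bootstrap
  mean curve.
- A score exactly at the threshold classifies as true (`score ≥ t`).
- Desk-scale sizes used throughout (500 kb contigs, 570-call sets, 1500
  training calls, 10-sample panels) are the package's standard test
  conditions; all are scenario parameters and scale up linearly.

## Known limitations

- The internal primer engine approximates, but does not bit-reproduce,
  Primer3's scoring; only the product-size range is shared. No genome-wide
  off-target search or multiplex compatibility check is performed.
- The blacklist criterion (±100 bp, orientation-aware) is a configurable
  stand-in for an unstated published criterion.
- Real caller INFO schemas vary; `caller_features` is an open named map
  and the feature schema must be configured to match the caller in use.
- The 28 µL chip constant does not scale with partial chip fills unless
  overridden.
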