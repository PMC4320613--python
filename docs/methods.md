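# Methods

## Coordinate conventions

Genomic intervals are GTF-style (1-based, closed); BED output is
0-based half-open; both conversions live in `repa.coords` and nowhere
else.  Acceptor windows use intron-anchored positions that skip zero:
−1 is the last intronic base (the G of the acceptor AG), +1 the first
exonic base.  This matches the field's habit of labelling the region
between the polypyrimidine tract and the AG as "−10…−3" and removes
the ambiguity of a position 0.

## The purine-rich acceptor rule

A site is called purine-rich when its acceptor dinucleotide is AG and
strictly more than 60% of the non-N bases at −10…−3 are A/G.  The
denominator is the 8 positions of that window with N bases removed;
with all 8 informative the strict inequality means 5/8 (0.625) passes
and 4/8 (0.50) fails, so integer counting leaves no boundary noise.
Soft-masked (lowercase) genome sequence is uppercased; N bases count
as neither purine nor pyrimidine.  Introns shorter than the requested
window are extracted truncated and flagged, and truncated windows are
never candidates.

G tracts are maximal runs of ≥3 Gs searched over −15…−3 — wider than
the −11…−6 band where observed first Gs concentrate, on the principle
of searching wide and reporting position.  A run may not end closer to
the acceptor than −3 (it would invade the AG).  Runs longer than 8 are
reported at their true length with an over-cap flag rather than
truncated.  Histograms use one representative tract per site: the
5′-most first G (ties broken by length, then 3′ position — distinct
maximal runs cannot actually tie on the first G, so the rule is
documentation more than arbitration).

Motif groups are literal matches within −12…−3 with a fixed precedence
(`gtggaa` > `ggggg` > `ggaaa` > `gaaaa` > `aaataa`); a window matching
none but carrying a purine at −3 (deviating from the constitutive `y`)
falls into an `nnnrag` bucket, everything else is `other`.  The
precedence order is a package choice — each site belongs to exactly
one group, and the annotation sources that motivated the groups do not
define tie rules.

## Acceptor strength: maximum-entropy model

Strength scoring follows the maximum-entropy framework for splice-site
discrimination: fit the least-committal distribution over 23-mers
(20 intronic + 3 exonic bases) consistent with empirical marginals of
a signal set (true acceptors) and of a background set (decoys), and
score a window by the log₂ likelihood ratio in bits.

Two constraint sets are supported.  *Singletons* (per-position
marginals) give the closed-form product of marginals — a position
weight matrix — with no iteration.  *Adjacent pairs* (all singleton
plus neighbouring-pair marginals) give a chain-structured model
P(x) ∝ ∏ᵢ ψᵢ(xᵢ, xᵢ₊₁) whose edge marginals are computed exactly by a
transfer-matrix recursion; the potentials are fitted by iterative
proportional fitting, one edge at a time with marginals recomputed
between updates (simultaneous updates diverge).  On a chain IPF
reaches the empirical marginals essentially exactly within two sweeps;
the convergence criterion is a maximum marginal residual below 1e−4
with an iteration cap of 200, and hitting the cap raises an error
carrying the residual.

Empirical marginal counts carry a +0.5 Laplace pseudocount so every
A/C/G/T window has finite probability and score.  Windows containing N
are not scorable and are excluded upstream.  At the full 23-nt window
at least 200 training sequences per class are required; reduced
windows (used by the exhaustive-enumeration checks, which sum model
probabilities over all 4^L sequences for L ≤ 6) accept any n ≥ 2.

The published MaxEntScan acceptor parameters are not bundled: they
came from an external web service and a maximal-dependence
decomposition model this package does not reimplement.  Scores are
therefore comparable within a training run, not numerically to
published MaxEntScan values; model parameters can be saved/loaded as
JSON to share a fitted model.

## Alternative-splicing events

Events are called from annotation alone, by pairwise isoform
comparison within a gene:

* **cassette exon** — an internal exon of one isoform whose two
  flanking junctions exist in it while the other isoform carries the
  single junction joining the flanks;
* **alternative 3′SS / 5′SS** — two introns sharing their donor
  (resp. acceptor) and differing at the other site, *with the two
  alternative exons overlapping each other*.  The overlap requirement
  (as in standard event catalogues) prevents every skipped exon from
  also surfacing as an alternative-splice-site pair through its
  junction comparisons;
* **retained intron** — an intron of one isoform strictly contained
  within a single exon of the other.

Events are deduplicated across isoform pairs by type and coordinates;
when one region satisfies several definitions the fixed precedence
retained_intron > alt_3ss > alt_5ss > cassette_exon applies and the
supersession is logged.  Detection is symmetric in isoform order.

A scanned site is *alternative* when at least one event's defining
acceptor coincides with its acceptor coordinate or the event interval
covers it; multi-type sites keep all types.  Type proportions among
the events touching purine-rich sites are compared to user-supplied
reference proportions (e.g. transcriptome-wide surveys) as fold
enrichments; folds are only defined where the reference proportion is
positive.

## Statistics

Hypergeometric upper tails P(X ≥ k) are summed exactly in log space
(gammaln + logsumexp), so p-values are exact at least down to 1e−300;
smaller values underflow the linear scale and are flagged, with the
log-scale value available — a deliberate replacement for tools that
print "p = 0".  The right-tailed Fisher test on a 2×2 table is the
same tail and the two implementations are cross-checked against each
other, against exhaustive draw enumeration, and against scipy.
Positional purine enrichment tests each window position by drawing the
query's purines from the query+background pool.  Group strength
comparisons use the classic equal-variance two-sample t (two-tailed);
degenerate groups (n < 2, zero variance) are flagged rather than
fatal.  Gene-set enrichment evaluates right-tailed Fisher p per
GMT-style set and repeats the test for a configurable number of
random query sets of matched size drawn from the universe, giving the
background bars against which real enrichment is judged.  No multiple-
testing correction is applied by default; the hypothesis count here is
small and fixed, and scipy's Benjamini–Hochberg is one call away for
users who screen many sets.

## Vertebrate emergence

The five clades — fish, reptiles, birds, marsupials, other mammals —
are treated as an ordered ladder (fish outermost; reptiles and birds
siblings at one level), which matches the questions the analysis asks
without requiring a resolved species tree.  Clade presence is an OR
over the clade's surveyed species, so a single-lineage loss (the
wallaby pattern: a tract interrupted by one base while opossum retains
it) leaves the clade positive.  A row is *complete* when every clade
is determined (no ND).  Emergence is called under Dollo parsimony —
the tract arose once, at the outermost clade with presence, and
absences nested inside the origin are secondary losses:
`mammalian_ancestor` when present only in marsupials and/or other
mammals, `pre_mammalian` when present in any of birds/reptiles/fish.
Percentages use complete rows only.

The packaged survey (`repa/data/vertebrate_gtract_survey.tsv`) carries
21 human acceptor windows (−15…−1) with clade-level presence codes for
the non-human clades; one species stands in per non-human clade
because per-species sequences are not available for those columns, and
presence for the human column is recomputed from the sequence itself.
The marsupial-presence subcount among mammalian-emergence rows is
reported but deliberately not asserted anywhere: reconstructing it
from a collapsed presence matrix is ambiguous.

## Synthetic data: what it emulates, and what it does not

The genome generator plants every acceptor:

* **constitutive** acceptors draw their purine count at −10…−3 from
  {0, 1, 2} with probabilities (0.1, 0.2, 0.7) — mean 1.6/8 = 0.20, so
  the per-position A/G marginal is 20% while no site can exceed 2/8
  purines.  Purines are planted as A on a G-free pyrimidine
  background, so constitutive windows never contain G runs.
* **purine-rich (REPA)** acceptors carry one planted G tract (first G
  in −11…−6 with mass peaking at −10 and −8; run lengths 3–8 with
  G₃–G₅ ≈ 98%), remaining −10…−3 positions purine (as A) with
  probability 0.7, topped up to at least 6/8 purines.  The 6/8 margin
  guarantees every planted site clears the strict 5/8 threshold, which
  is what makes 100% sensitivity/specificity a legitimate expectation
  in recovery tests; its cost is that the realized A/G marginal of
  planted purine-rich windows sits near 0.8 rather than the ~0.7 of
  real purine-rich acceptors, so profile tests on that class are
  qualitative (>0.6) by design.

Class labels, tract placements and alternative-splicing assignments
use deterministic largest-remainder apportionment, so recovered
fractions equal configured ones exactly rather than binomially.  The
default REPA fraction (0.25) is far above genome-wide rarity — a
deliberate oversampling so that small simulated genomes contain enough
positive sites to measure; it parameterizes the generator and is not a
claim about genomes.  Witness isoforms realize one event per selected
site (cassette, alt-3′/5′SS with a 12-nt shift, retained intron), with
geometric feasibility checks; the 12 exonic bases that turn intronic
in an alt-3′SS witness are pinned to pyrimidines so the shifted
acceptor can never become a spurious purine-rich call.  The default
event mixture (cassette 0.350, alt-3′SS 0.256, alt-5′SS 0.139,
retained intron 0.255) against the default reference proportions
(0.40/0.16/0.15/0.015) plants a 17-fold retained-intron enrichment and
a 1.6-fold alt-3′SS enrichment — the qualitative pattern these
elements show in real transcriptome comparisons.

The ortholog generator scripts each gene's emergence clade
(deterministic counts; default 87% mammalian / 13% pre-mammalian),
gives every clade a configurable number of species (default 3), and
injects species-level losses only in clades strictly interior to the
emergence clade — single-base tract interruptions in the wallaby
style.  Because the emergence clade itself never loses the tract,
scripted-clade recovery is exact at any loss rate; the ≥99% recovery
check therefore validates the caller's Dollo logic, not a noise
tolerance.  ND (not determined) clades are injected at a configurable
rate, default 0.

What the generators do **not** emulate: realistic splicing-regulatory
grammar beyond the planted features (no branch points, no donor-site
structure beyond a literal GT, no expression), sequencing evidence
(isoforms are given as annotation, not reads), overlapping genes, and
base composition heterogeneity along chromosomes.  Passing recovery
tests therefore demonstrates correctness of the scanning, event and
emergence logic under controlled conditions — not performance on real
genomes, where annotation quality and borderline compositions
dominate.

## Numerical and reproducibility choices

All generator randomness flows from a single integer seed through
`numpy.random.Generator`; discrete draws use integer-state methods, so
identical seeds give byte-identical FASTA/GTF/TSV across platforms.
Pipeline manifests record config and input hashes plus per-stage
record counts, making the site funnel (sites → purine-rich → G-tract →
alternative) visible on any input.  Report SVGs are rendered with a
fixed hash salt and no embedded date, so re-rendering identical inputs
is byte-identical.  Problem sizes used by the test suite and the
acceptance script — a ~50 kb genome for the scanner-oracle comparison,
200–400 genes for event recovery and model training, 1000 ortholog
sets for emergence recovery — are chosen as the smallest sizes at
which every planted class is populated well enough for the exact
recovery checks to be meaningful.

## Known limitations

* Only AG-terminated acceptors are candidates; non-canonical splice
  sites are scanned but never called purine-rich.
* Strength scores are training-set-relative (no published-parameter
  parity; see above).
* Event calling is annotation-driven: isoforms absent from the GTF do
  not exist for the classifier, and quantitative inclusion levels
  (PSI) are out of scope.
* The clade ladder hard-codes five vertebrate classes; finer
  phylogenies (or non-vertebrate ladders) require editing the clade
  vocabulary.
* `hypergeom_upper` returns 0.0 on the linear scale below ~1e−308;
  callers needing smaller tails must use `log_hypergeom_upper`.
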