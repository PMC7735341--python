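# Methods

This note documents the models and procedures implemented in `songculture`,
the choices behind their parameters, and what the synthetic corpus can and
cannot demonstrate.

## The song hierarchy and its encodings

Humpback song is hierarchical: *units* (single continuous sounds, labelled
by type) are sung in stereotyped order to form a *phrase*; a phrase repeated
several times is a *theme*; distinct themes sung in a stereotyped order form
a *song cycle*. The package works with two symbolic encodings:

* **phrase strings** — ordered unit-label sequences, one row per sung
  phrase, each assigned a phrase type (an integer with an optional variant
  letter, e.g. `2A`, used only when a numbered phrase has two or more
  consistent forms);
* **song strings** — ordered distinct theme IDs per song rendition. A theme
  enters the string once, at its first occurrence, regardless of how many
  times its phrase was repeated; the theme ID is the numeric part of the
  phrase-type label, so variant letters collapse at this level.

Tables are plain CSV with a header; ordered sequences are single
space-delimited columns, which forbids whitespace inside unit labels. Unit
labels are case-sensitive opaque tokens. Row order in the phrase table is
authoritative for reconstructing within-recording phrase sequence.

## String similarity

The Levenshtein distance LD(a, b) is the minimal number of unit-cost
insertions, deletions and substitutions turning one symbol sequence into the
other; no transposition operation is defined. The Levenshtein similarity
index normalizes it by the longer sequence:

    LSI(a, b) = 1 − LD(a, b) / max(|a|, |b|)

and is reported as a similarity (1 = identical); dissimilarity for
clustering is 1 − LSI. LSI for two empty sequences is undefined and raises.
The DP core is implemented in-package (two-row dynamic programme over
integer-coded symbols) and is cross-checked in the test suite against two
independent implementations.

The **median string** of a set is the member with the largest summed
pairwise LSI to the rest. Ties break to the smallest input index, with an
absolute tolerance of `1e-9` on the row sums so that the rule is stable
under floating-point summation order (exact ties can differ by one ulp
depending on the order terms are added). A singleton set is its own median
with score 0 and within-set similarity 1 by convention. **Within-set
similarity** is the mean of off-diagonal pairwise LSI values; the diagonal
is excluded because self-similarity would inflate the statistic.

**Phrase-type verification** contrasts within-type mean LSI against the
mean LSI to every other type; a type is flagged when its within-type
similarity does not strictly exceed all of its between-type similarities.
Singleton types take within-similarity 1.0 (a lone exemplar is trivially
self-consistent), so their flag depends only on the between terms.

## Song matching

Two complementary comparisons are used at song level:

* **sequence-aware** — LSI over theme-ID strings, either on every rendition
  (`mode='full'`) or on the median string per (location, year, recording,
  song-type) group (`mode='median'`, a point estimate per recording);
* **presence-only** — Dice's similarity index DSI = 2·|A∩B| / (|A| + |B|)
  over unordered theme sets, ignoring sequence. DSI operates on themes
  (variant letters collapsed); per-rendition presence rows are unioned per
  recording group before the matrix is built.

## Clustering and edge support

Similarity matrices are clustered agglomeratively on d = 1 − s with three
linkage rules: UPGMA (unweighted average, the default), single linkage, and
WPGMA (weighted average). The cophenetic correlation coefficient (CCC) — the
Pearson correlation between cophenetic and input distances — selects among
them; CCC > 0.8 is conventionally a good representation. Merge ties break
deterministically by cluster-index order. Average-family heights are checked
for monotonicity on every run.

Edge stability is assessed by **multiscale bootstrap**. The resampling unit
is the individual string within its group: at each ratio r, every group's
members are resampled with replacement to round(r·n), the group similarity
matrix and dendrogram are recomputed, and BP(r) is the fraction of
replicates containing the edge's exact leaf set. Because the leaf set of a
bootstrap tree must be fixed for edge counting, both cluster targets keep
groups as leaves: `'median'` clusters group median strings and `'full'`
clusters the mean pairwise LSI between the groups' member strings.

The approximately unbiased (AU) value corrects BP's curvature bias. With
σ² = n/n′ = 1/r, the normal-quantile transform of the BP profile is modelled
as σ·Φ̄⁻¹(BP) linear in σ², i.e.

    Φ⁻¹(1 − BP(r)) = v·√r + c/√r,

fitted by weighted least squares (binomial delta-method weights
B·φ(z)²/(p(1−p))), and AU = 1 − Φ(v − c), where v is the signed distance and
c the curvature of the cluster boundary. AU > 0.95 is read as a stable edge.
Numerical policy: scales whose count is exactly 0 or B carry no shape
information (clipping them would fabricate collinear points) and are
excluded from the fit; when fewer than two informative scales remain the AU
falls back to BP at r = 1 and the edge is flagged `degenerate`. Edges
present (absent) in every replicate at every scale get AU = 1 (0) directly.
With `scales=[1.0]` only, AU therefore degrades to the plain bootstrap
proportion, whose standard error is at most 0.5/√B.

Default scales are 11 ratios evenly log-spaced on [1/1.4, 1.4]; the odd
count places r = 1.0 exactly on the grid, which the plain-bootstrap BP and
the degenerate fallback both require. One master seed spawns one stream per
scale in sorted-scale order, so results are identical for identical seeds
regardless of how scales are executed.

Dendrograms export to Newick with AU (or BP) as internal-node labels, and
the full per-scale BP profile is available as a support table.

## Unit-label validation

Each unit carries 11 numeric parameters: duration (s); bandwidth, peak,
high, low, start and end frequency (Hz); frequency trend (start ÷ end);
frequency range (high ÷ low); inflection count; pulse rate (s⁻¹). The
qualitative type name is the response. A random forest (1000 trees, 3
candidate variables per split, bootstrap sampling) predicts the name from
the parameters; the out-of-bag error rate measures how well the qualitative
labels are supported by the measurements. The OOB confusion matrix is built
from the same OOB votes as the error, so trace/total = 1 − OOB error holds
by construction. Variable importance is the permutation-based mean decrease
in accuracy (computed on the training sample). No class balancing is
applied; the raw OOB rate is reported. Units without a pulse structure
carry pulse rate 0.

A caveat established during testing: OOB error is not invariant to exact
row duplication — a duplicated row's twin is in-bag while the row is out,
biasing the estimate towards training error. The duplication-stability check
is therefore only meaningful where the error is already near zero.

## Presence timelines

Recorders sample on a 900 s duty cycle (630 s at the song-band rate per
cycle, 96 files per day). Files are graded 0 (no song), 1 (song, low SNR) or
2 (high-SNR song suitable for transcription); presence is category ≥ 1. The
daily metric is the percentage of *files* per site-day containing song —
never seconds — and days without recordings are absent from the output, not
zero. Timestamps are taken as local recorder time with no timezone
conversion.

Singing is deemed to have **ceased** on the last date with presence at any
site only when the following five consecutive days are fully recorded
(every site's file count within a configurable tolerance of the expected 96)
and contain no song at any site. If the record ends sooner, or any of those
days is incompletely recorded, the result is right-censored and incomplete
days are reported as gaps.

## The synthetic song-culture generator

The generator emulates the cultural dynamics the analyses are designed to
detect, with full ground truth:

* **lineages** hold an ordered theme set (default 5 themes) and one or two
  phrase templates per theme (unit sequences of length 4–8 over a 71-unit
  inventory). A fixed fraction of the 16-theme inventory (0.3125, i.e.
  exactly 5 themes) carries two variants;
* **evolution** at a year transition gains one fresh theme and loses one,
  never removing all shared themes;
* **revolution** assigns a population a brand-new lineage whose theme block
  is disjoint from everything previously allocated (the generator errors if
  the inventory cannot supply a fresh block);
* **transcription noise** is symbol-level — substitute (0.025), delete
  (0.0125), insert (0.0125) per unit, a total per-unit error rate of 0.05
  split so substitutions are as likely as indels combined. Mirroring the
  three edit operations makes the noise magnitude map directly onto expected
  LSI. Renditions also omit each theme with probability 0.05, emulating
  individual variation between singers, which is what makes bootstrap
  support non-trivial;
* the **default scenario** is two populations over three years (three
  recordings per population-year, five renditions per recording): one
  population keeps its lineage with one evolution event, the other revolves
  to a disjoint lineage after the first year. All 16 inventory themes are
  sung somewhere.

The per-class unit-feature generator draws an 8-dimensional latent normal
per unit with class centroids `separation` standard deviations apart and
maps it monotonically onto the 11 parameters so the domain invariants
(high ≥ low, consistent ratios and bandwidth, non-negative counts) hold by
construction; degenerate draws are redrawn with a bounded retry.

What the generator does **not** emulate: acoustic measurement error in the
12 parameters of real units, phrase-boundary segmentation ambiguity,
hybrid songs, unequal recording effort between populations, and
misassignment of noisy phrases to the wrong phrase type (noise corrupts
unit strings but theme identity is emitted correctly). Passing the recovery
suites therefore shows the statistical machinery is sound under the stated
noise model, not that real transcriptions are this clean.

## Problem sizes and determinism

The default corpus is ≈1 270 phrase strings and 90 song strings over six
population-year groups; bootstrap support uses B = 1000 replicates at 11
scales, and the parameter-recovery suite repeats this over 20 seeds. All
randomness flows from explicit seeds: the generator spawns separate
structure and emission streams, and the bootstrap spawns one stream per
scale, so every reported number is exactly reproducible.

## Known limitations

* Which unit the original analyses resampled in their bootstrap is not
  public; strings-within-groups is this package's choice as the natural
  observation unit for an LSI matrix, and results may differ from analyses
  that resample matrix columns.
* The AU fit is unreliable when almost all scales sit at the count ceiling;
  the degenerate fallback reports plain BP in that case and flags it.
* The supplementary-table column layouts of the original datasets are not
  printed in any public text; the CSV schemas here are a declared
  convention, not a claim about the originals.
* DSI counts collapsed themes, not phrase-type variants; a flag-level
  alternative would require variant-resolved presence tables.
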