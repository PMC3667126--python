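# Methods

This note documents the models, defaults and numerical choices behind
`toxprofiler`, and what the synthetic-data tests do and do not demonstrate
about real screen data.

## Label model and cohorts

The screen classifies each overexpression clone into three growth
categories ("almost no growth", "slow growth", "normal growth") and three
GFP-fluorescence categories ("high fluorescence", "fluorescence", "no
fluorescence"). Exactly one of the nine cells is labeled toxic: almost no
growth *and* no fluorescence — the clones in which even a small amount of
expressed protein arrests the host. Records with an unknown category in
either axis are excluded from labeled cohorts and counted in the log.

The cytoplasmic cohort excludes secretory proteins, whose extreme toxicity
plausibly runs through saturation of the Sec translocation machinery
rather than the cytoplasmic mechanism of interest. Which proteins count as
secretory is genuinely ambiguous when a protein has predicted
trans-membrane (TM) segments but no membrane localization tag; because
TM-bearing proteins behave like the secretory class in the screen, the
default filter (`cytoplasmic_filter="localization_or_tm"`) excludes a
record if it has *either* a secretory localization tag (membrane, outer
membrane, periplasmic space; "inner membrane" maps to membrane) *or*
`tm_count >= 1`. `"localization_only"` restricts the exclusion to tags.
TM counts may come from an annotation column or from TMHMM short-format
output (`PredHel=k`); running TM prediction itself is out of scope.

## Sequence features

* **Charge counts.** `positive_count` = #Arg + #Lys, `negative_count` =
  #Asp + #Glu. Histidine is deliberately not counted as positive — the
  charge features follow the Arg/Lys definition — but it remains an
  ionizable group in the pI calculation; each formula keeps its own
  convention.
* **Isoelectric point.** Net charge at a given pH sums
  Henderson–Hasselbalch occupancies over both termini and the ionizable
  side chains (K, R, H positive; D, E, C, Y negative). The termini
  guarantee one group of each sign, so Q(pH) is strictly decreasing with
  Q(0) > 0 > Q(14) and the root is unique. It is found by bisection on
  [0, 14] to a 1e-3 pH tolerance (max 100 iterations; deterministic). The
  pKa table is selectable; the default is the EMBOSS convention (N-term
  8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1),
  with the Sillero table as an alternative. Absolute pI values shift by a
  few tenths of a pH unit between tables; every analysis here depends only
  on relative ordering and the U-shaped toxicity trend, which all common
  tables reproduce.
* **Hydropathy.** Per-residue Kyte–Doolittle values span −4.5 (Arg) to
  +4.5 (Ile); each residue maps to (v + 4.5)/9 and the mean over standard
  residues lies in [0, 1].
* **Ambiguity codes** (B, J, X, Z, U, O) are retained for length, carry no
  charge, no ionizable group and no hydropathy value — neutral defaults
  for rare codes.
* **Functional flags** are flat membership lookups against configured
  class identifiers (defaults: GO:0001071 transcription factor activity,
  GO:0050794 regulation of cellular processes, GO:0003824 catalytic
  activity, GO:0032991 macromolecular complex). No GO-graph propagation is
  performed; memberships are taken as the flat sets provided.

## Statistics

* **Rank-sum test**: two-sided Mann–Whitney; exact enumeration when the
  pooled sample is ≤ 12 and tie-free, otherwise the normal approximation
  with tie correction. The switch keeps small worked examples exact while
  scaling to cohort sizes where the two methods are indistinguishable.
* **Fisher exact test**: two-sided, summing hypergeometric probabilities
  no larger than the observed table's. The reported odds ratio is the
  sample (a·d)/(b·c); zero denominators give inf (or nan for 0/0) and are
  logged, not raised.
* **Welch t-test** for the hydropathy comparison; the degenerate
  zero-variance-equal-means case returns t = 0, p = 1.
* **Equal-frequency bins**: values are ranked after a seeded shuffle
  (stable sort), so tied values are assigned reproducibly, then cut into k
  contiguous bins whose sizes differ by at most one (larger bins first).
  Default k = 20, i.e. 5% of the cohort per bin. The per-bin toxic
  percentage is fit by least squares with degree 1 (positive count,
  length) or degree 2 (pI); the fits are descriptive plot aids and carry
  no inference.
* **Enrichment scan**: every class with at least `min_size` members inside
  the cohort (default 200) gets a Fisher test of (in-class vs out) ×
  (toxic vs non-toxic), sorted by p. p-values are reported raw, matching
  the screen-analysis convention; Benjamini–Hochberg q-values are attached
  separately for modern hygiene. A class covering the whole cohort has an
  undefined odds ratio and p = 1. The regulatory-excluding-transcription-
  factor class is formed by set difference and scanned alongside.

## Classification protocol

Toxic proteins are the minority class. Each of `n_repetitions` (default
10) rounds draws all minority proteins plus an equal-size uniform sample
of the majority without replacement, fits a 500-tree random forest, and
scores every balanced-set protein by its out-of-bag positive-vote
fraction — the internal error estimate of bagging, which needs no held-out
split (`holdout="split"` offers a 70/30 alternative). The per-round
ROC-AUC (ties counting ½) is averaged arithmetically. Repetition r uses
seed + r for subsampling and seed + 10000 + r for the forest, so different
feature subsets evaluated at the same seed see identical balanced sets and
their AUCs are paired, not merely comparable. The learner is pluggable
(`learner_factory`); the protocol, not the forest, is the contract. The
canonical ablation subsets are SEQUENCE = {positive_count, pI, length},
FUNCTION = {is_tf, is_regulatory, is_catalytic}, COMBINED = their union;
custom subsets (e.g. adding `in_complex`) are supported.

## Synthetic proteome generator

The generator emulates the statistical landscape the analysis assumes, so
that parameter recovery — not numeric reproduction of any published
value — is the test surface.

* Lengths are log-normal (log-mean 5.6 ≈ 270 aa, log-sd 0.45, floor 30);
  sequences are i.i.d. draws from an E. coli-like residue composition.
* Functional classes are Bernoulli memberships: TF 5%, regulatory 15%
  (plus 80% of TFs, mirroring the overlap of the real classes), catalytic
  50%, complex 25%, and two inert decoy classes (12%, 10%) so the
  enrichment scan always has null classes to reject.
* 38% of proteins are secretory: a TM count is drawn from
  {0: .30, 1: .30, 2: .20, 3: .12, 4: .08}; TM ≥ 1 records get the
  membrane tag, TM = 0 secretory records split between periplasmic and
  outer membrane.
* The toxicity probability is logistic in the *realized* features of the
  generated sequence — logit p = −3.22 + 0.03·positive_count +
  0.002·length + 0.05·(pI−7)² + 1.2·TF + 0.8·regulatory − 0.6·catalytic +
  3.2·secretory — so the measurement chain (sequence → features →
  statistics) is exercised end to end rather than short-circuited through
  latent variables. The label is a Bernoulli draw from p.
* The intercept and secretory coefficient were calibrated once so the
  defaults echo the screen's landscape: ≈ 42% toxic overall, ≈ 19% of the
  cytoplasmic cohort, ≈ 80% of secretory proteins, ≈ 29% of TM-0 proteins
  versus ≈ 80% of TM-bearing ones. This is qualitative mimicry of the
  published marginal rates, not a claim of numeric reproduction.
* Screen categories are back-filled so the label rule recovers the drawn
  label exactly: toxic → (almost no growth, no fluorescence); non-toxic →
  a 60/25/15 mix over (slow growth, fluorescence), (normal growth, high
  fluorescence), (almost no growth, fluorescence). The mix is arbitrary
  but configurable and logged.
* One master seed; each stream (lengths, sequences, classes, secretory,
  TM, labels, back-fill) derives from it by a fixed small offset.

What the generator does **not** emulate: real GO-term correlation
structure (class memberships are independent given the TF–regulatory
overlap), residue-order structure (sequences are i.i.d., so there are no
charge runs or domains), operon/genome context, fusion-tag sequences, or
continuous fluorescence. Passing recovery tests therefore shows the
pipeline correctly measures effects of the kind assumed; it does not show
the features capture everything that matters in real proteomes.

## Problem sizes in the test suite

The acceptance-style tests run the full pipeline at the cohort sizes the
analysis targets (3,956-protein proteome, ≈ 2,400 cytoplasmic) but with a
150-tree forest and 5 repetitions, and null calibration over 20 seeds —
sizes chosen so the whole suite completes in a few minutes on one CPU.
Null AUC calibration and effect-direction recovery are insensitive to tree
count and repetition number well below these values; the package defaults
(500 trees, 10 repetitions) remain what `run_pipeline` uses.

## Known limitations

* The hydropathy comparison on synthetic data is near-null by
  construction (hydropathy never enters the label model), which mirrors
  the negligible real-data difference but means the Welch test mostly
  exercises plumbing.
* The exact rank-sum path declines to handle ties (falls back to the
  tie-corrected normal approximation even below the n = 12 switch), a
  deliberate simplification since the exact-with-ties null is expensive
  and the analysis never needs it at those sizes.
* Absolute pI values depend on the pKa table; only table-consistent
  comparisons are meaningful.
* The enrichment scan treats classes as flat sets; hierarchically nested
  GO terms will produce correlated, partially redundant rows.
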