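# Methods

## Binding models and match scoring

A TF binding model is a position frequency matrix (PFM): one probability
column per motif position, in A,C,G,T row order, each column summing to 1
(validated to 1e-6).  Models are used as *additive scaled frequencies*, not
background-corrected log-odds: every field is multiplied by a scaling factor
(default 100) and a window's match score is the sum of the weights selected
by its bases.  The theoretical maximum score is the sum of the per-column
maxima, and hits are reported relative to it (percent score), with a default
reporting threshold of 20 % chosen to retain weak candidate sites.  A
log-odds mode is deliberately a non-goal: the additive form is the scoring
convention this benchmark is built around, and percent scores are invariant
under any positive rescaling of the matrix.

Scanning is dual-strand: the reverse strand is scanned as the forward scan
of the reverse complement, and hit positions are mapped back to the forward
coordinate frame (`pos_fwd = L − w − pos_rev`).  `best_hit` returns the
single maximum over both strands; ties prefer the + strand, then the
smaller forward position, so output order is deterministic.

**Ambiguous bases.**  The sources this pipeline emulates do not specify a
treatment for N.  Here an N contributes exactly 0 at its position (no
reward, no penalty), windows consisting only of N are skipped, and a
sequence shorter than the matrix yields no hits plus a logged warning
rather than an error (length-matched negatives can be shorter than wide
matrices).  Zero probabilities stay zero — no pseudocount is applied — but
the synthetic generator floors column entries at 0.001 so score quotients
can never reach 0/0.

## Benchmarking protocol

Positives are confirmed binding events (peaks with an integer binding
score); negatives are length-matched sequences drawn from a
binding-depleted pool (exonic sequence with each transcript's first exon
excluded, since 5' exons can harbour functional sites).  Matching is
without replacement while eligible pool sequences last, then with
replacement (logged); trim offsets are uniform.  The "high-confidence"
subset keeps peaks reaching at least 80 % of the TF's maximum binding score
and drops TFs with fewer than 100 such peaks.  Because an externally
published score ceiling is not generally available, the per-TF maximum
defaults to the maximum observed in the input peak set (overridable).

Each matrix scores every pair by dual-strand best hit; discrimination is
summarised by the ROC curve over all distinct score thresholds and its
trapezoid AUC, which equals the Mann–Whitney probability that a random
positive outscores a random negative with ties counted half (scikit-learn's
`roc_curve`/`roc_auc_score` provide exactly this; an O(n²) pair-counting
oracle in the test suite pins the identity).  Per-source summaries report
the mean AUC and the fraction of matrices with AUC ≥ 0.7, plus a per-TF
table in which multiple matrices of one TF are averaged.

## Variant-impact classifier

The classification feature for a variant is the quotient
`q = max(S_wt, floor) / max(S_var, floor)` of the best-hit scores of the
wild-type and variant windows (20 bp flank on each side of the variant by
default); `floor` defaults to 1 % of the matrix maximum.  Training pairs
for one matrix are all positive/negative score pairs — the "binding lost"
class gets pos/neg quotients, the "binding gained" class their elementwise
reciprocals — capped at 1,000,000 pairs per matrix by uniform seeded
sampling when the cross-product is larger.  The two-outcome reading
(loss trained on pos/neg, gain on neg/pos) is the symmetric construction
consistent with "gain or loss of a binding site" and is surfaced as the
explicit pairing in `make_training_pairs`, not hard-wired deeper.

Class-conditional densities are Gaussian kernel density estimates on
`log q`: quotients are ratio-scaled and strongly non-normal, and log-space
makes the two classes exact mirror images, which in turn makes the
posterior antisymmetric under swapping wild-type and variant (q → 1/q
swaps the two posterior probabilities).  Bandwidths follow the
rule-of-thumb of the R `density()` default (nrd0: `0.9·min(sd, IQR/1.34)·
n^(−1/5)`), computed per class and floored at 1e-3 for degenerate samples
(warned).  Densities are evaluated as exact sums over all kernels with a
chunked max-shift log-sum-exp — no gridding or truncation — so far-tail
posteriors stay finite and the implementation agrees with a direct
sum-of-kernels oracle to rounding error.  Priors default to ½/½.  If both
class log-densities are non-finite at a query the priors are returned with
a warning.

**Calibration.**  Because many matrices discriminate weakly, a posterior
alone overstates reliability.  After an 80/20 held-out split of the
training pairs (seeded; resubstitution available by setting the held-out
fraction to 0), predictions on the held-out pairs are binned by posterior
confidence over [0.5, 1.0] (10 bins) and each bin records the empirical
positive predictive value (fraction of loss-calls that were truly lost) and
negative predictive value (gain-calls truly gained).  Empty bins are
undefined rather than imputed.  The held-out set is subsampled to at most
20,000 pairs per class: binned proportions gain nothing beyond that, and
posterior evaluation is linear in both training and held-out size.

**Aggregation.**  Each matrix of a TF contributes its direction (loss/gain;
an exact posterior tie declines), its confidence, the matching PPV or NPV,
and an ordinal reliability grade 1–5 (machine output uses the ordinal, not
colours).  Only matrices whose predictive value reaches 0.70 enter the
aggregate call, decided by majority direction; a tie yields "uncertain" and
no qualifying matrix yields "no reliable prediction".  The 0.70 threshold
is a protocol constant; the majority rule and the held-out calibration are
this package's concretisation of an underspecified step and are exposed as
configuration.  When the variant has a genomic position and a peak database
is supplied, the verdict also flags whether a catalogued binding event for
the TF overlaps the position.

`direction_agreement` compares predicted against experimentally observed
gain/loss directions, ignoring declined predictions; raw score-change
directions can be derived with an explicit minimum-relative-change
parameter (default 0, i.e. any change counts).

## Conservation summaries

Score tracks are per-base arrays (fixed-step wiggle or bedGraph, step 1);
bigWig input is out of scope so the module stays download-free.  Missing
bases are excluded from both the per-interval maximum and mean — never
imputed as 0 — and a fully uncovered interval is reported missing.  Groups
(binding-site intervals vs length-matched random controls drawn uniformly
over a restricted chromosome set) are compared on the average of
per-interval maxima and of per-interval means, with standard deviations and
the standard error of the group difference reported alongside; intervals
are weighted equally, not by length.

## Synthetic data generator

The generator emulates the study's inputs with controllable signal:

* **Motif**: per-column maximum probability maps linearly from the
  information level (0 → uniform 0.25, 1 → 0.97), jittered within ±0.02
  with the residual mass split unevenly (Dirichlet, floored at 0.001).
  The jitter/uneven split matters: two-valued columns would make every
  match score a lattice point, collapsing KDE bandwidths to the floor and
  saturating posteriors — an artifact real frequency matrices do not show.
* **Peaks**: i.i.d. background of configurable GC (0.41 by default,
  human-like) with one motif instance embedded per sequence at a recorded
  offset on a random strand; lengths uniform in 100–300 bp.  Instances are
  drawn from the *sharpened* (squared, renormalised) columns, reflecting
  that experimentally confirmed sites are enriched for strong matches; at
  full information ≥ 99 % of instances are the consensus.  Binding scores
  are integers in [0, 1000], a monotone map of the instance's percent
  score with optional noise.
* **Negatives**: background sequences rejection-sampled so no window on
  either strand reaches 80 % of the matrix maximum; lengths cover the
  positive range (a few pinned at the maximum so every positive finds an
  eligible length match).
* **Variants**: motif-destroying variants replace the consensus base at
  the strongest column carried by the instance with that column's weakest
  base (ground truth: loss).  Flank variants sit at least one motif width
  from the embed — so no scan window spans both — while keeping the embed
  fully inside the 20-bp-flank classification context, which makes the
  null ground truth provable: the window's best hit is the unchanged
  embed.  (A variant placed far from the motif would genuinely change the
  best match of its own context window, so "no effect" would be the wrong
  label for what the method is asked to judge.)  This placement requires
  `flank ≥ 2·width − 1`.
* **Conservation**: Gaussian baseline noise (sd 0.1) elevated by +0.5 over
  embedded motifs on the simulated chromosome, plus a baseline-only
  background chromosome hosting the random controls; the expected
  sites-minus-controls difference of per-interval means is
  `elevation · width / length`, averaged over intervals.

Defaults are the study conditions used throughout the tests: 500 positives,
500 negatives, information level 1, motif width 10 (the middle of the
realistic 5–19 bp range), 200 motif-destroying plus 200 flank variants.
All randomness flows through one integer-seeded NumPy generator; outputs
are bit-reproducible and free of hash-order dependence.

What the generator does *not* emulate: Markov or repeat structure in
background DNA, read-level ChIP-seq artefacts, peak-caller behaviour,
soft-masking, cross-cell-line peak redundancy, or realistic score overlap
between bound and unbound sequence.  Passing recovery tests therefore
demonstrates the correctness of the machinery under clean, well-separated
conditions, not the field performance of any particular matrix source on
real data — on real inputs, AUCs and predictive values are expected to be
substantially lower and more variable.

## Numerical and design notes

* Pair-quotient training sets are cross-products, so nrd0's `n^(−1/5)`
  uses the (dependent) pair count; with well-separated synthetic classes
  this undersmooths the tails and posteriors saturate quickly.  This
  mirrors the reference ecosystem's behaviour (R `density()` inside a
  kernel naive Bayes) and is left as-is.
* Training with the pair cap engaged versus the full cross-product shifts
  posteriors by well under 0.05 on a log-spaced quotient grid (tested).
* The classifier bundle is versioned JSON carrying the PFMs, per-class
  log-quotient points (rounded to 1e-9), bandwidths, priors, calibration
  tables, floors and seeds; probabilities are renormalised on load so PFM
  invariants hold exactly after rounding.
* CLI subcommand runs with the same seed are byte-identical in their
  primary outputs; logs go to stderr, never mixed into primary outputs.
* Benchmarks in the test suite use 500 + 500 sequences and a 50,000-pair
  training cap — sizes at which every recovery property is stable across
  seeds while the whole suite stays fast.
* Genome builds are opaque labels carried through metadata; coordinates
  are 0-based half-open internally (BED convention), with VCF's 1-based
  positions converted at the boundary.
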