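# Methods

## Model

`tiscan` treats the complex of a transcription factor and its DNA binding
site as a closed system in which binding transfers information from the
site to the factor. A candidate L-base window `seq` carries information
IS1 before binding, measured against the genome background, and IS2 after
binding, measured against the factor's motif model; the transferred
information is

    TI = IS1 - IS2.

A window is called a binding site when TI is at least the **minimum
transferred information** (MTI), defined as the smallest TI among the
factor's known sites. The threshold is therefore derived from the training
data itself rather than tuned: by construction every training site is
recovered, and anything transferring less information than the weakest
known site is rejected.

### Position interdependence via r-tuples

The classic PWM treats motif columns as independent. `tiscan` instead
estimates, for every subset of r distinct columns (i1 < … < ir) of the
aligned known sites, the joint probability p̃(seq_i1, …, seq_ir) of the
ordered base tuple read at those columns. The order-r information estimate
averages the per-base sub-sequence information over all C(L, r) subsets and
rescales to length L:

    I_r(seq) = -(L / (r·C(L,r))) · Σ_subsets log2 p̃(tuple).

The same construction against background tuple probabilities q gives IS1,
and

    TI_r(seq) = (L / (r·C(L,r))) · Σ_subsets log2 [p̃(tuple) / q(tuple)].

At r = 1 this reduces exactly to the PWM log-odds sum. For r ≥ 2 the
estimate responds to column correlations: if the joint tuple probability
exceeds the product of its split probabilities (positive correlation) the
independent estimate overstates the information and I_r decreases strictly
with r; negative correlation reverses the order; independent columns make
all I_r equal (the prefactor satisfies L·C(L-1, r-1)/(r·C(L,r)) = 1, so
product-form tables give I_r = I_1 identically). `correlation_tendency`
exploits this: it classifies a site as positive / negative / independent /
mixed from the empirical trend of I_1..I_rmax, with ties decided by a
tolerance of 1e-6 bits (the trend differences of genuinely correlated data
are orders of magnitude larger; the tolerance only absorbs floating-point
noise in exactly-independent constructions).

### Background model

Background tuple probabilities are counted by sliding an L-base window
along reference sequences; every window contributes all C(L, r) of its
position subsets. Counts are pooled over subset shapes — q depends on the
bases only, not on the spacing — yielding 4^r probabilities. Overlapping
windows recount shared tuples; this literal windowed counting (rather than
a span-weighted closed form) is retained because it is the defining
procedure, and a test verifies the two agree on toy references. Windows
containing ambiguity codes are skipped whole and tallied. Only the given
strand is counted by default; an option adds the reverse complement.
`stride` and a seeded `sampling_fraction` subsample window starts for large
references; with defaults (1, 1.0) counting is exhaustive. Once computed,
a background table is serialised to JSON and reused across scans.

## Numerical choices

- **Pseudocount** defaults to 0. Tuples never observed in training then
  have probability exactly 0, and a window containing one is unscorable in
  the motif direction: its TI is set to the -inf sentinel and it is
  rejected. This is deliberate — an unobserved combination is treated as
  disqualifying, which is what makes r ≥ 2 sharply selective against
  uncorrelated pseudo-sites. A small pseudocount (e.g. 0.01) can be passed
  to smooth the tables when training sets are tiny.
- A zero **background** probability with positive motif probability gives
  TI = +inf: the transferred information is unbounded, so the window is
  accepted but flagged with a warning, signalling an undertrained
  background rather than silently erroring. A training site triggering
  this condition makes the MTI undefined and raises.
- Threshold comparison is inclusive (TI ≥ MTI); scores decompose as
  TI = IS1 - IS2 whenever both are finite (asserted to 1e-9 bits).
- Positions are 1-based inside the model domain; all coordinates in BED
  output are 0-based half-open. Reverse-strand windows are scored on the
  reverse complement and reported in forward coordinates.
- Subset order r is capped at 4 by default (cost grows as C(L,r)·4^r);
  higher orders need an explicit override.
- Gap resolution of input alignments drops any column containing a gap
  (default) or rejects gapped input; the model is defined on gapless
  columns only.

## Hit merging and evaluation

Overlapping above-threshold windows on one strand can be collapsed with
the `greedy-local-max` policy: transitively overlapping hit windows form a
cluster represented by its maximal-TI window (leftmost on ties). For
evaluation the package defaults to treating each above-threshold window as
a prediction (policy `none`): at permissive thresholds hit windows can
chain across hundreds of bases, and collapsing such a chain to one
representative would misplace predictions relative to ground truth.
Reported metrics are site-level: FP = (|P|-TP)/|P| (0, flagged, when no
predictions are made), FN = (|K|-TP)/|K|, perf = TP/(|P|+|K|-TP) (the
Jaccard index of the matched sets), and PT/RT = |P|/|K|. Matching is
greedy one-to-one by descending overlap; a pair is eligible when the
overlap covers at least half the known site's length (configurable), and
matching ignores strand by default since genuine sites produce signal on
both strands.

## Synthetic data

The generator emulates artificial benchmark material: i.i.d. random
background sequences at a target GC fraction (0.38 documented as the
S. cerevisiae-like default), each harbouring a uniform-random 0–3
occurrences of each motif, with sites sampled column-independently from a
PWM, embedded without overlap (forward strand by default), and recorded as
ground truth. Three built-in demo factor site sets (gcn4-, gal4- and
mcb-like; L = 10, 17, 8) provide PWMs via their column marginals; each set
includes degenerate outlier sites, as curated collections do, so the MTI is
permissive the way thresholds derived from real site collections are.

Because PWM-sampled pseudo-sites carry *no* column correlations, this
material probes one specific contrast: the independent r = 1 detector
accepts them (low FN, high FP), while r ≥ 2 detectors reject most of them
— the gal4-like factor, whose 11-bp spacer is nearly random, loses
essentially all pseudo-sites at r = 2. Passing tests on this material
therefore demonstrates threshold correctness, selectivity and the
correlation machinery; it does not demonstrate recovery of *correlated*
real sites, which synthetic PWM draws cannot represent. Default problem
sizes (10 sequences × 450 bp, 30 kb background reference, N = 9–20
training sites) keep every check comfortably interactive while leaving the
binomial sampling bounds used in tests tight.

## Known limitations

- The background is a pooled tuple model, not a Markov chain; spacing
  between tuple positions is ignored by design.
- No p-value or FDR calibration: MTI is the only threshold.
- Training alignments are consumed as given; the package does not align
  sites.
- With pseudocount 0 and small N, scanning rejects any window containing
  an unobserved tuple, which is conservative for under-sampled motifs.
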