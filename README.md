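# tiscan

Information-transmission scanning of transcription-factor binding sites
(TFBSs).

`tiscan` scores candidate DNA windows by the information transferred from
the site to the factor during binding. Known binding sites of a factor
(aligned, length L) define joint probabilities p̃ of the base r-tuples read
at every subset of r columns; a sliding L-base window over reference
chromosomes defines the background tuple probabilities q. A candidate
window `seq` is scored by

    TI_r(seq) = (L / (r·C(L,r))) · Σ_{i1<…<ir} log2 [ p̃(seq_i1,…,seq_ir) / q(seq_i1,…,seq_ir) ]

and accepted when TI_r ≥ MTI, the minimum TI over the factor's known
sites. At r = 1 this is exactly the PWM log-odds score; at r ≥ 2 the score
uses column interdependencies, which sharply suppresses false positives
from uncorrelated look-alikes. The trend of the information estimate I_r
over r also diagnoses whether a motif's columns are positively correlated
(I_r strictly decreasing), negatively correlated (increasing) or
independent (constant).

The package is aimed at regulatory-genomics analyses where a set of
experimentally mapped sites for a factor exists and unknown occurrences
are to be found in promoter or genomic sequence. It ships a synthetic-data
generator (GC-matched random sequences with 0–3 PWM-sampled sites per
motif and recorded ground truth) and site-level evaluation metrics, so the
whole workflow runs without external downloads.

## Worked example

```python
import tiscan as t
from tiscan import SiteInterval

al = t.demo_factor_alignments()["gcn4"]          # 20 aligned sites, L=10
bgseq = t.generate_background_sequence(30000, 0.38, rng=1)
bg = t.count_background([bgseq], L=al.L, r=2)
det, _ = t.train_detector(al, bg, r=2)
print(f"MTI({al.factor_name}, r=2) = {det.mti:.3f} bits")

sset = t.build_test_set(10, 450, {"gcn4": t.pwm_from_alignment(al)},
                        gc_content=0.38, seed=42)
windows = []
for sid, seq in sset.sequences.items():
    windows += t.scan(det, seq, sequence_id=sid)
hits = [w for w in windows if w.is_hit]
print(f"{len(hits)} hit windows out of {len(windows)} scored")

pred = [SiteInterval(w.sequence_id, w.start, w.end, "gcn4", w.strand) for w in hits]
known = [SiteInterval(x.sequence_id, x.start, x.end, x.factor, x.strand)
         for x in sset.truth]
rep = t.evaluate_predictions(pred, known)
print(f"FP = {rep.fp_rate:.3f}  FN = {rep.fn_rate:.3f}  "
      f"perf = {rep.perf:.3f}  PT/RT = {rep.pt_rt:.3f}")
```

Output:

```
MTI(gcn4, r=2) = 1.865 bits
15 hit windows out of 8820 scored
FP = 0.267  FN = 0.083  perf = 0.688  PT/RT = 1.250
```

The detector trained on the gcn4-like sites accepts 15 of 8,820 windows
(both strands of ten 450-bp sequences). Of the 12 embedded pseudo-sites it
recovers 11 (FN = 0.083) with 4 spurious calls (FP = 0.267); perf is the
site-level Jaccard index between known and predicted site sets, and PT/RT
the ratio of predicted to real sites. The correlation diagnostic on the
same alignment reports `I_1=1.391  I_2=1.298  I_3=1.244 -> positive`.

## Command line

The same workflow as a console tool:

```
tiscan background refs.fasta -o bg.json -L 10 -r 2
tiscan train sites.fasta bg.json -o det.json -r 2 --factor gcn4
tiscan scan det.json queries.fasta -o hits.bed --spectrum spectrum.tsv
tiscan simulate --pwm gcn4.tsv --out-fasta set.fasta --out-truth truth.bed --seed 5
tiscan evaluate hits.bed truth.bed -o report.tsv
tiscan diagnose sites.fasta --r-max 3
```

Models are human-inspectable JSON; hits are BED6; spectra and reports are
TSV. All randomised steps take `--seed` and are bit-reproducible.

See `docs/methods.md` for the model, estimation details, sentinel
conventions for unobserved tuples, and what the synthetic benchmark does
and does not demonstrate.

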