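# spliceharmony

Harmonization of differential alternative-splicing calls from **rMATS**,
**LeafCutter** and **MAJIQ** into a single junction-centric, event-typed
table — plus a splicing simulator with ground truth and a benchmarking
framework for evaluating callers against it.

## The problem

The three most widely used differential-splicing tools quantify
different things: rMATS scores predefined exon-centric events,
LeafCutter scores intron junctions inside overlapping clusters, and
MAJIQ scores junctions inside local splicing variations (LSVs).  Their
outputs cannot be compared row-for-row, and studies that need a
consensus view (e.g. profiling the on- and off-target effects of
small-molecule splicing modulators) are left reconciling three
incompatible tables by hand.

spliceharmony converts every record into canonical intron coordinates,
rebuilds a splice graph per structural group, and decomposes it into
simplified **event graphs** — three anchor nodes and two alternative
splice paths — typed as one of eight outcomes:

| family | types | ΔΨ > 0 means |
| --- | --- | --- |
| cassette exon | ESin / ESout | exon more included under treatment |
| alternative 5′ splice site | A5SSlong / A5SSshort | long-exon variant more used |
| alternative 3′ splice site | A3SSlong / A3SSshort | long-exon variant more used |
| intron retention | IRin / IRout | intron more retained |

Here Ψ ∈ [0, 1] is percent spliced in, ΔΨ = Ψalt − Ψref, and the
confidence score is 1 − FDR (rMATS, LeafCutter) or the posterior
changing probability P (MAJIQ).  Events are labeled purely by junction
anchor coordinates (`chr1:200-301-400-501:+`; intron retention as a
single junction `chr1:200-301:+`), so the same local splicing decision
gets the same key from every tool and the union across methods — with
per-method statistics preserved, consensus ΔΨ as their mean and
consensus confidence as their maximum — falls out naturally.
Mutually-exclusive-exon candidates (adjacent ESin/ESout pairs sharing
flanking anchors) are flagged in an advisory table, never simplified.

Because genome-wide true negatives do not exist for real data, the
package also ships a simulator: ground-truth events drawn on a
synthetic annotation (default composition: 128 events — 69 ESin, 28
ESout, 10 A5SSlong, 5 A5SSshort, 2 A3SSlong, 4 A3SSshort, 6 IRin, 4
IRout; 23 of the ESin events use cryptic exons), a coverage × mixing
grid (200–50 000 reads per transcript; alt:control ratios 100:0, 80:20,
50:50, 20:80), an emulator that writes the three tools' table dialects
with a tunable noise model, and a benchmark module (identification %,
precision/recall/accuracy, AUROC over a ΔΨ threshold grid, cross-method
Jaccard overlap) with honest handling of modes where TN is undefined.

## Worked example

A complete loop on the packaged synthetic genome — simulate truth,
emulate tool outputs at 5000 reads with an 80:20 alt:control mix
(alternative coverage 4000), harmonize, benchmark:

```bash
spliceharmony simulate --seed 1 -o sim
spliceharmony emulate --truth sim/TrueEvent.csv \
    --gtf sim/toy_annotation.gtf --seed 1 --reads 5000 --ratio 80 20 -o emu
spliceharmony harmonize \
    --rmats emu/rmats \
    --leafcutter emu/leafcutter_effect_sizes.txt emu/leafcutter_cluster_significance.txt \
    --majiq emu/majiq_voila.tsv \
    --gtf sim/toy_annotation.gtf -o harmonized.tsv
spliceharmony benchmark --truth sim/TrueEvent.csv \
    --harmonized harmonized.tsv -o report.tsv
```

The harmonize step logs its stage counts (700 rMATS junctions from 247
exploded events, 970 junctions each from LeafCutter and MAJIQ, 247
integrated events = 128 truth + 119 non-changing background), and
`report.tsv` reads:

```
method      dpsi_cutoff  tp   fp  tn   fn  identification_pct  recall  precision  accuracy  auroc
harmonized  0.2          128  0   119  0   100.00              1.0000  1.0000     1.0000    1.0000
rmats       0.2          128  0   119  0   100.00              1.0000  1.0000     1.0000    1.0000
leafcutter  0.2          118  0   119  10  92.19               0.9219  1.0000     0.9595    0.9219
majiq       0.2          128  0   119  0   100.00              1.0000  1.0000     1.0000    1.0000
```

The LeafCutter column is the interesting one: junction-only evidence
cannot type intron retention, so exactly the 10 IR events are missing
from its recall — while the harmonized union recovers them from the
other methods.  Each harmonized row carries the event label, type,
consensus Ψref/Ψalt/ΔΨ/confidence and the per-method values, e.g.

```
gene    chrom  strand  label                            event_type  psi_ref   psi_alt   dpsi       confidence
G0105   chr1   +       chr1:101643-101853-101920:+      A3SSlong    0.000000  0.732722  0.732711   1.000000
```

Library use mirrors the CLI: `splice_sim.generate_truth_events`,
`splice_sim.emulate_condition`, `harmonize.harmonize`,
`benchmark.match_to_truth` / `confusion_counts` / `compute_auroc`.

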