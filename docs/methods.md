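# Methods

## Problem and approach

Differential-splicing tools disagree not only in their statistics but in
their *units of analysis*: rMATS reports predefined exon-centric events,
LeafCutter reports intron junctions grouped into overlapping clusters,
and MAJIQ reports junctions grouped into local splicing variations
(LSVs).  spliceharmony converts all three into one junction-centric
representation, rebuilds a splice graph per structural group, truncates
it into simplified *event graphs* — three anchor nodes and two
alternative splice paths — and types each as one of eight outcomes:
cassette exon in/out (ESin/ESout), alternative 5′/3′ splice site
long/short (A5SSlong/short, A3SSlong/short), and intron retention in/out
(IRin/IRout).  Events from different tools that describe the same local
decision then share a canonical label and can be merged.

## Coordinate conventions

A junction is stored as the intron it spans: a 1-based closed interval
`[start, end]` over intronic bases.  The exonic anchors are `start − 1`
(upstream exon end, "R") and `end + 1` (downstream exon start, "L").
Tool dialects convert as:

| source | raw convention | to canonical |
| --- | --- | --- |
| rMATS | exon coords, 0-based starts / 1-based ends | intron = `(upstreamEE + 1, exonStart_0base)` |
| LeafCutter (`regtools`, default) | last/first exonic base | `(raw_start + 1, raw_end − 1)` |
| LeafCutter (`bed`) | half-open 0-based intron | `(raw_start + 1, raw_end)` |
| MAJIQ (`intronic`, default) | first/last intronic base | identity |
| MAJIQ (`exonic`) | like regtools | `(raw + 1, raw − 1)` |

Dialects are configurable per tool; every conversion is exactly
invertible (round-trip tested on random junctions).  Cross-method event
labels are `chrom:b1-b2[-b3[-b4]]:strand` with anchor boundaries in
ascending genomic order (four boundaries for ES, three for A5SS/A3SS,
two for IR).  Junction equality across methods is exact by default; a
`junction_slop` of ±N bp can be enabled to absorb the few-bp coordinate
shifts occasionally seen between aligners, but the default is 0 because
such shifts are a discrepancy worth surfacing, not hiding.

## Event-graph decomposition

Within one group (rMATS event, LeafCutter cluster, MAJIQ LSV),
duplicate-coordinate junctions are merged keeping the
higher-confidence statistics, then:

* **ES** — every junction `(a, b)` bridged by `(a, x)` and `(y, b)` with
  room for a non-empty exon `[x+1, y−1]`.  The existence of the two
  inclusion junctions in the same group is itself taken as exon
  evidence, so cryptic (unannotated) exons still form ES events; the
  annotation only sets the `annotated` flag.
* **A5SS / A3SS** — every remaining pair sharing exactly one anchor.
  ES takes priority: a pair already serving as (skip, inclusion) inside
  an ES is not re-emitted, so a junction pair is never reported twice.
  The family is strand-aware: a shared downstream anchor on `+` (or a
  shared upstream anchor on `−`) leaves the donor side varying → A5SS;
  the mirror case → A3SS.  Pairs on unresolvable strand are dropped
  (counted), since donor/acceptor cannot be assigned.
* **IR** — every retention-flagged junction (rMATS RI rows; VOILA
  junctions whose coordinates equal the `ir_coords` column).

The enumeration is verified against an independent brute-force
enumerator (all pairs and bridged triples straight from the geometric
definition) on hundreds of random groups, with exact set equality.

Two symmetry properties pin the strand logic down.  Mirroring all
coordinates about a point while keeping the strand annotation swaps
A5SS↔A3SS counts exactly and preserves ES/IR counts.  Mirroring *and*
flipping strand is a reverse-complement: it preserves transcript-relative
geometry, so every family count is invariant (a 5′ splice-site choice
stays a 5′ choice).  Both are asserted in the suite.

rMATS mutually-exclusive-exon (MXE) rows are deliberately never
simplified into event graphs; they pass through unchanged.  Separately,
any (ESin, ESout) pair within one gene whose cassette exons are adjacent
and share outer anchors is flagged as a *potential* MXE in an advisory
table, without modifying the events themselves.

## Statistics

Ψ (percent spliced in) is the inclusion fraction of a junction in
[0, 1]; ΔΨ = Ψalt − Ψref between treated and control groups.  The
confidence score is 1 − FDR for rMATS and LeafCutter and the posterior
changing probability P for MAJIQ.  When an rMATS event is exploded, the
inclusion-path junctions carry the event's Ψ/ΔΨ and the skip junction is
complemented (Ψ → 1 − Ψ, ΔΨ → −ΔΨ) so all junctions of one event share
an inclusion orientation; the complement preserves the
ΔΨ = Ψalt − Ψref identity exactly.

rMATS group order: the reader treats `IncLevel1`/SAMPLE_1 as the treated
(alt) group so that `IncLevelDifference` equals ΔΨ as defined above; a
`swap_groups` flag covers runs configured the other way around.

Event-level statistics are the arithmetic mean over the
alternative-path junctions (ES: the two inclusion junctions; A5SS/A3SS:
the long-exon variant, i.e. the shorter intron; IR: the retention
junction).  Because the mean is linear, the ΔΨ identity survives
aggregation exactly.  The direction suffix comes from the sign of the
aggregated ΔΨ (positive → ESin/A5SSlong/A3SSlong/IRin); ΔΨ = 0 resolves
deterministically to the positive form with a `zero_change` flag.

Cross-method integration unions events by (label, family).  Consensus
ΔΨ/Ψ are the mean over reporting methods, consensus confidence the
maximum, and the direction suffix is recomputed from the consensus ΔΨ
(not by majority vote) so type and sign can never disagree.  All
per-method values are retained in the output, so the consensus destroys
no information.  Same-key events with conflicting strands are kept
per-method rather than force-merged.  Significance calling uses strict
inequalities, |ΔΨ| > cutoff AND confidence > cutoff (defaults 0.2 and
0.95), and is monotone in both cutoffs by construction.

Junction annotation against one or two GTFs (reference plus an optional
assembled annotation) yields three statuses: `annotated` (both anchors
are exon boundaries of one gene *and* the intron exists in some
transcript), `novel_combination` (both anchors known, pairing unseen —
e.g. a skip junction over an annotated exon), and `novel_boundary` (at
least one anchor unknown).  Gene assignment is by boundary ownership,
falling back to unique span containment; anchors owned by two different
genes leave the gene blank rather than guessing.

## Simulator

`toy_genome` builds a deterministic synthetic genome: by default 140
genes on 4 chromosomes, alternating strands, 5–8 exons of 120–200 bp
separated by introns of 250–450 bp, one annotated transcript per gene.
These sizes give every event type room (boundary shifts of 30–80 bp,
cryptic exons of 50–150 bp with ≥20 bp intronic margins) while keeping a
full simulation under a second.

`generate_truth_events` draws one event per selected gene following the
default composition — ESin 69, ESout 28, A5SSlong 10, A5SSshort 5,
A3SSlong 2, A3SSshort 4, IRin 6, IRout 4 (128 events) — with 23 of the
ESin events using cryptic exons.  Cryptic exons are synthesized by
*exonizing an unannotated intronic interval* of the existing genome
rather than inserting foreign sequence: the observable consequences are
identical (an unannotated, labelable cassette) and the genome FASTA and
all other coordinates stay fixed.  Each event defines a control and an
alternative transcript; the treated group mixes them at the configured
alt:control ratios (100:0, 80:20, 50:50, 20:80) while the control group
is pure control transcript, so the expected |ΔΨ| equals the alternative
fraction and the alternative coverage is reads × alt% (5000 reads at
80:20 → 4000).

Read simulation (for workflows that need FASTQ) is single-end,
error-free, uniform start positions, default length 100, 3 replicates
per group — conventional defaults, all configurable; every read is an
exact transcript substring and output is byte-deterministic per seed.

## Tool-output emulator

The emulator stands in for running rMATS, LeafCutter and MAJIQ on
simulated reads; it writes each tool's table dialect directly from the
truth and a noise model, and makes no claim about the real tools' error
profiles.  Per condition:

* **Units** are the 128 truth events plus non-changing background from
  the same genes: one near-constitutive cassette per gene (inclusion
  0.95 in both groups) and every remaining constitutive intron
  (Ψ = 1, ΔΨ = 0).  Background units give every tool honest negative
  rows, which is what makes TN — and hence accuracy and AUROC —
  computable for the event-based modes.
* **Detection** requires expected supporting reads
  (reads × alt-fraction for truth units, full depth for background) to
  reach `detection_min_reads` (default 10).
* **Ψ̂** per group and replicate is Beta-distributed around the true Ψ
  with concentration κ = c0 × supporting reads (c0 default 0.01/read,
  floor 2); `c0 = None` is the noiseless limit Ψ̂ ≡ Ψ.  One Ψ̂ is drawn
  per unit and group; member junctions derive theirs by the inclusion
  complement, keeping each emulated row internally consistent.
* **p-values** come from a two-proportion chi-square on rounded
  junction counts, BH-adjusted within each emulated tool; MAJIQ's
  changing probability P(|ΔΨ| > 0.2) uses a normal approximation with
  the Beta sampling variance (exactly 0/1 in the noiseless limit).
* Optional coordinate jitter (off by default) shifts emitted junction
  coordinates to model inter-aligner shifts.

One emulator simplification matters for interpretation: each unit is
emitted as a single LSV containing *all* of its junctions, whereas real
MAJIQ splits a cassette across source- and target-exon LSVs.  Emulated
MAJIQ therefore recovers ES events slightly more directly than the real
tool would.  LeafCutter receives only the spliced junction for IR
events (a single-junction cluster), which is why LeafCutter alone
cannot type IR — visible in benchmarks as exactly the 10 IR events
missing from its recall while the harmonized union recovers them.

At coverage 4000 (5000 reads, 80:20) the Beta model gives a per-group
standard error of roughly √(0.16/41)/√3 ≈ 0.036, so ΔΨ̂ is unbiased
with mean absolute error ≈ 0.03 — the basis of the parameter-recovery
test (|mean bias| < 0.01, mean |error| < 0.05 over 20 seeds).

## Benchmarking

Matching to truth is by (label, family) in event mode, or by constituent
junction intervals in junction mode — the coarser definition used for
baseline tools without event typing, keeping the maximum |ΔΨ̂| per truth
event.  Each truth event matches at most once; predictions matching no
truth event are background calls.  At a cutoff: TP = truth matched with
|ΔΨ̂| ≥ cutoff, FN = truth missed or sub-threshold (so TP + FN always
equals the number of truth events, and identification % = TP/n_true),
FP/TN = background calls above/below cutoff.  For
LeafCutter-Baseline and MAJIQ-Baseline modes TN is undefined
(`tn_defined = False`): TN is reported as 0 and accuracy and AUROC are
withheld rather than computed misleadingly.

ROC curves use |ΔΨ̂| as the score over the threshold grid
(0, 0.01, 0.1, 0.2, 0.4, 0.6, 0.8, 0.9, 0.95), closed with (0,0) and
(1,1) and integrated by trapezoid after sorting by FPR.  A
`continuous=True` flag uses every distinct score as a threshold instead;
the continuous AUROC equals the Mann–Whitney pairwise statistic and is
invariant under monotone score transforms, while the fixed grid can
miss operating points between adjacent thresholds (on the worked
4-score example the grid integrates to 0.625 where the brute-force
value is 0.75 — both frozen in the tests from hand enumeration).

Overlap analysis intersects per-method significant sets over a grid of
per-method cutoffs (0.1–0.9 in steps of 0.1), at event level or gene
level (a gene counts as differentially spliced if it has ≥1 significant
event), reporting intersection counts, Jaccard indices, and the top
cutoff combinations by shared-set size.

## Problem sizes and determinism

The shipped study conditions are the 140-gene synthetic genome, 128
truth events, ~390 background units, six read depths × four ratios, 3
replicates; a full simulate → emulate → harmonize → benchmark loop for
one condition takes a few seconds, and the whole test suite under ten.
All randomness flows from explicit seeds through `numpy` generators;
the full emulation is byte-identical given (config, seed), and
harmonization output is invariant under input row order.

## Limitations

* The emulator's noise model (Beta Ψ̂, chi-square p-values) is a
  plausibility device, not a calibrated model of rMATS/LeafCutter/MAJIQ
  error; benchmark numbers on emulated outputs validate the
  harmonization and accounting machinery, not the upstream tools.
  Headline performance checks in the suite are therefore emulator-based;
  running the real tools is out of scope.
* The synthetic annotation has one transcript per gene and
  non-overlapping genes; real annotations add ambiguity (shared
  boundaries between isoforms, overlapping genes) that only surfaces
  here as the documented gene-assignment fallbacks.
* Complex multi-junction patterns (tandem cassettes, transcript-level
  isoform shifts) are outside the simplified three-node event
  definition; MXE candidates are flagged, never resolved.
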