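"""Benchmarking against simulated ground truth.

Predictions are matched to truth events either by canonical event label
and family (event mode) or by constituent junction coordinates (junction
mode, the coarser definition used for baseline methods that lack event
typing; per truth event the maximum |ΔΨ̂| among matching junctions is
kept).  Confusion counts follow the simulation's accounting: TP are truth
events called at or above the |ΔΨ| cutoff, FN truth events missed or
called below it, FP non-changing (true ΔΨ = 0) calls at or above it, and
TN non-changing calls below it — with TN (and hence accuracy and AUROC)
withheld for modes that cannot observe non-changing events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    ConfusionCounts,
    EventType,
    Family,
    MetricSet,
    ParameterError,
    SplicingEvent,
    SpliceHarmonyError,
    ThresholdCurve,
    TruthEvent,
)

DEFAULT_DPSI_GRID = (0.0, 0.01, 0.1, 0.2, 0.4, 0.6, 0.8, 0.9, 0.95)


@dataclass
class MatchTable:
    """Outcome of matching predictions to ground truth."""

    n_true: int
    truth_scores: dict[str, Optional[float]]  # truth label -> best |ΔΨ̂| or None
    background_scores: list[float]  # |ΔΨ̂| of calls matching no truth event


def _method_dpsi(ev: SplicingEvent, method: Optional[str]) -> Optional[float]:
    if method is None:
        return ev.dpsi
    st = ev.method_stats.get(method)
    return None if st is None else st.dpsi


def match_to_truth(
    predicted: Sequence[SplicingEvent],
    truth: Sequence[TruthEvent],
    mode: str = "event",
    method: Optional[str] = None,
    slop: int = 0,
) -> MatchTable:
    """Match predicted events to truth events.

    Event mode matches on (label, family); junction mode matches any
    constituent junction interval (within ``slop`` bp per coordinate) and
    keeps the maximum |ΔΨ̂| per truth event.  Each truth event is matched
    at most once; predictions matching no truth event become background
    calls.  Duplicate truth labels are an input error.
    """
    if mode not in ("event", "junction"):
        raise ParameterError(f"unknown match mode {mode!r}")
    labels = [t.label for t in truth]
    if len(set(labels)) != len(labels):
        raise SpliceHarmonyError("duplicate truth labels")

    truth_scores: dict[str, Optional[float]] = {t.label: None for t in truth}
    background: list[float] = []

    if mode == "event":
        by_key = {(t.label, t.family): t for t in truth}
        for ev in predicted:
            dpsi = _method_dpsi(ev, method)
            if dpsi is None:
                continue
            t = by_key.get((ev.label, ev.family))
            if t is None:
                background.append(abs(dpsi))
                continue
            cur = truth_scores[t.label]
            if cur is None or abs(dpsi) > cur:
                truth_scores[t.label] = abs(dpsi)
    else:
        junction_owner: dict[tuple[str, int, int], str] = {}
        for t in truth:
            for (s, e) in t.junctions.values():
                junction_owner[(t.chrom, s, e)] = t.label

        def _owner(chrom: str, s: int, e: int) -> Optional[str]:
            if slop == 0:
                return junction_owner.get((chrom, s, e))
            for ds in range(-slop, slop + 1):
                for de in range(-slop, slop + 1):
                    hit = junction_owner.get((chrom, s + ds, e + de))
                    if hit is not None:
                        return hit
            return None

        for ev in predicted:
            dpsi = _method_dpsi(ev, method)
            if dpsi is None:
                continue
            hits = set()
            for (s, e) in _event_junctions(ev):
                owner = _owner(ev.chrom, s, e)
                if owner is not None:
                    hits.add(owner)
            if not hits:
                background.append(abs(dpsi))
                continue
            for label in hits:
                cur = truth_scores[label]
                if cur is None or abs(dpsi) > cur:
                    truth_scores[label] = abs(dpsi)
    return MatchTable(
        n_true=len(truth), truth_scores=truth_scores, background_scores=background
    )


def _event_junctions(ev: SplicingEvent) -> list[tuple[int, int]]:
    """Constituent canonical intron intervals recovered from the label."""
    b = [int(x) for x in ev.label.split(":")[1].split("-")]
    if ev.family is Family.ES and len(b) == 4:
        return [(b[0] + 1, b[1] - 1), (b[2] + 1, b[3] - 1), (b[0] + 1, b[3] - 1)]
    if ev.family in (Family.A5SS, Family.A3SS) and len(b) == 3:
        # three boundaries: two variant ends sharing one anchor; both
        # orientations are enumerated since the label alone does not say
        # which side is shared
        return [
            (b[0] + 1, b[2] - 1), (b[1] + 1, b[2] - 1),
            (b[0] + 1, b[1] - 1),
        ]
    if ev.family is Family.IR and len(b) == 2:
        return [(b[0] + 1, b[1] - 1)]
    return []


def junction_predictions_to_events(
    junctions: Iterable,
) -> list[SplicingEvent]:
    """Wrap normalized per-junction records as label-only pseudo-events.

    Used for the baseline modes (no event typing): each junction becomes
    an IR-shaped single-junction record so junction-mode matching can
    consume tool outputs directly.
    """
    out = []
    for j in junctions:
        out.append(
            SplicingEvent(
                label=f"{j.chrom}:{j.left_anchor}-{j.right_anchor}:{j.strand}",
                family=Family.IR,
                event_type=EventType.IRIN,
                chrom=j.chrom,
                strand=j.strand,
                method_stats={j.source.value: j.stats} if j.stats else {},
                dpsi=j.stats.dpsi if j.stats else 0.0,
                confidence=j.stats.confidence if j.stats else 0.0,
            )
        )
    return out


def confusion_counts(
    matches: MatchTable,
    dpsi_cutoff: float,
    tn_defined: bool = True,
) -> ConfusionCounts:
    """Confusion accounting at one |ΔΨ| cutoff (calls use ≥ cutoff)."""
    if not 0.0 <= dpsi_cutoff <= 1.0:
        raise ParameterError(f"dpsi cutoff {dpsi_cutoff} outside [0, 1]")
    tp = sum(
        1 for s in matches.truth_scores.values() if s is not None and s >= dpsi_cutoff
    )
    fn = matches.n_true - tp
    fp = sum(1 for s in matches.background_scores if s >= dpsi_cutoff)
    tn = (
        sum(1 for s in matches.background_scores if s < dpsi_cutoff)
        if tn_defined
        else 0
    )
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, tn_defined=tn_defined)


def compute_metrics(c: ConfusionCounts, n_true: int) -> MetricSet:
    """Identification %, recall, precision, accuracy from counts.

    Undefined denominators (and accuracy whenever TN is undefined) yield
    explicit ``None``, never a silent zero.
    """
    if n_true <= 0:
        raise ParameterError("n_true must be positive")
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    accuracy = (
        (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
        if c.tn_defined and (c.tp + c.tn + c.fp + c.fn)
        else None
    )
    return MetricSet(
        identification_pct=100.0 * c.tp / n_true,
        n_true=n_true,
        recall=recall,
        precision=precision,
        accuracy=accuracy,
    )


def compute_auroc(
    matches: MatchTable,
    grid: Sequence[float] = DEFAULT_DPSI_GRID,
    tn_defined: bool = True,
    continuous: bool = False,
) -> ThresholdCurve:
    """ROC over the |ΔΨ| threshold grid (trapezoidal integral).

    Truth events are positives scored by their best matching |ΔΨ̂|
    (unmatched → score 0, never called); background calls are negatives.
    The curve is closed with (0,0) and (1,1) and integrated after sorting
    by FPR.  With ``continuous=True`` every distinct score is used as a
    threshold instead of the printed grid.  AUROC is withheld (None) when
    TN is undefined or either class is empty.
    """
    if list(grid) != sorted(set(grid)):
        raise ParameterError("threshold grid must be strictly increasing")
    scores = list(matches.truth_scores.values())  # None = never called
    called = [s for s in scores if s is not None]
    neg = list(matches.background_scores)
    if not tn_defined or not scores or not neg:
        return ThresholdCurve(grid=tuple(grid), fpr=[], tpr=[], auroc=None)
    thresholds = sorted({*called, *neg, 0.0}) if continuous else list(grid)
    points = []
    for t in thresholds:
        tpr = sum(1 for s in called if s >= t) / len(scores)
        fpr = sum(1 for s in neg if s >= t) / len(neg)
        points.append((fpr, tpr))
    points += [(0.0, 0.0), (1.0, 1.0)]
    points = sorted(set(points))
    fprs = [p[0] for p in points]
    tprs = [p[1] for p in points]
    auroc = float(np.trapezoid(tprs, fprs))
    return ThresholdCurve(
        grid=tuple(grid),
        fpr=[p[0] for p in points],
        tpr=[p[1] for p in points],
        auroc=auroc,
    )


# ---------------------------------------------------------------------------
# Cross-method overlap


@dataclass
class OverlapReport:
    pairwise: dict[tuple[str, str], dict]  # (m1, m2) -> counts + jaccard
    three_way: Optional[dict]
    per_cutoff: list[dict] = field(default_factory=list)


def jaccard(sets: Sequence[set]) -> float:
    union = set().union(*sets)
    if not union:
        return 1.0
    inter = set(sets[0]).intersection(*sets[1:])
    return len(inter) / len(union)


def overlap_analysis(
    event_sets: dict[str, Sequence[SplicingEvent]],
    cutoff_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    level: str = "event",
    top_k: int = 10,
) -> OverlapReport:
    """Pairwise and three-way agreement between methods.

    For every combination of per-method |ΔΨ| cutoffs from the grid, the
    significant sets are intersected at event level (label, family) or
    gene level (a gene is differentially spliced if it has ≥1 significant
    event); agreement is reported as intersection counts and the Jaccard
    index, with the ``top_k`` cutoff combinations ranked by shared-set
    size.
    """
    if len(event_sets) < 2:
        raise ParameterError("overlap analysis needs at least two methods")

    def keys_at(events: Sequence[SplicingEvent], cutoff: float) -> set:
        sig = [e for e in events if abs(e.dpsi) > cutoff]
        if level == "gene":
            return {e.gene_id for e in sig if e.gene_id}
        return {e.key for e in sig}

    methods = sorted(event_sets)
    base_sets = {m: keys_at(event_sets[m], 0.0) for m in methods}
    pairwise = {}
    for m1, m2 in combinations(methods, 2):
        s1, s2 = base_sets[m1], base_sets[m2]
        pairwise[(m1, m2)] = {
            "n_intersection": len(s1 & s2),
            "n_union": len(s1 | s2),
            "jaccard": jaccard([s1, s2]),
        }
    three = None
    if len(methods) >= 3:
        sets3 = [base_sets[m] for m in methods[:3]]
        three = {
            "methods": tuple(methods[:3]),
            "n_intersection": len(set.intersection(*sets3)),
            "n_union": len(set.union(*sets3)),
            "jaccard": jaccard(sets3),
        }
    per_cutoff = []
    from itertools import product

    for combo in product(cutoff_grid, repeat=len(methods)):
        sets = [keys_at(event_sets[m], c) for m, c in zip(methods, combo)]
        inter = set.intersection(*sets) if sets else set()
        per_cutoff.append(
            {
                "cutoffs": dict(zip(methods, combo)),
                "n_shared": len(inter),
                "jaccard": jaccard(sets),
            }
        )
    per_cutoff.sort(key=lambda r: (-r["n_shared"], tuple(r["cutoffs"].values())))
    return OverlapReport(pairwise=pairwise, three_way=three, per_cutoff=per_cutoff[:top_k])
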