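"""Event-level aggregation and cross-method harmonization.

Junction statistics are averaged to the event level over the
alternative-path junction(s); events sharing a canonical label and family
across methods are merged into one harmonized record that keeps every
per-method value.  Consensus ΔΨ/Ψ are the mean over reporting methods and
consensus confidence the maximum, with the direction suffix recomputed
from the consensus ΔΨ so the type is always consistent with the sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .event_graph import build_splice_graph, enumerate_event_graphs
from .junction_space import (
    AnchorIndex,
    annotate_junction,
    group_junctions,
    normalize_junction,
    resolve_strand,
    rmats_event_to_junctions,
)
from .model import (
    AggregationError,
    EventGraph,
    EventType,
    Family,
    GeometryError,
    MethodStats,
    ParameterError,
    SplicingEvent,
    Source,
    event_type_for,
)
from .tool_io import LeafcutterRecord, MajiqRecord, RmatsRecord

log = logging.getLogger(__name__)


def aggregate_event_stats(e: EventGraph) -> MethodStats:
    """Arithmetic mean of the alternative-path junction statistics.

    ES averages the two inclusion junctions; A5SS/A3SS take the long-exon
    variant junction; IR the retention junction.  Because the mean is
    linear, ΔΨ = Ψalt − Ψref is preserved exactly whenever both Ψ values
    are present on every member.
    """
    members = [j for j in e.path_alt if j.stats is not None]
    if not members:
        raise AggregationError(f"event {e.label} has no junction statistics")
    n = len(members)
    dpsi = sum(j.stats.dpsi for j in members) / n
    conf = sum(j.stats.confidence for j in members) / n

    def _mean_opt(attr: str) -> Optional[float]:
        vals = [getattr(j.stats, attr) for j in members]
        if any(v is None for v in vals):
            return None
        return sum(vals) / n

    return MethodStats(
        dpsi=dpsi,
        confidence=conf,
        psi_ref=_mean_opt("psi_ref"),
        psi_alt=_mean_opt("psi_alt"),
    )


def event_from_graph(
    e: EventGraph,
    idx: Optional[AnchorIndex] = None,
) -> SplicingEvent:
    """Type and label one simplified event graph as a SplicingEvent."""
    stats = aggregate_event_stats(e)
    etype = event_type_for(e.family, stats.dpsi)
    gene_id = ""
    annotated = e.annotated
    if idx is not None:
        statuses = [annotate_junction(j, idx) for j in (e.path_alt + e.path_ref)]
        genes = {s.gene_id for s in statuses if s.gene_id}
        gene_id = next(iter(genes)) if len(genes) == 1 else ""
        if e.family is Family.IR:
            annotated = annotated or any(s.status == "annotated" for s in statuses)
        else:
            annotated = annotated and all(s.status == "annotated" for s in statuses)
    return SplicingEvent(
        label=e.label,
        family=e.family,
        event_type=etype,
        chrom=e.chrom,
        strand=e.strand,
        gene_id=gene_id,
        annotated=annotated,
        zero_change=stats.dpsi == 0.0,
        method_stats={e.source.value: stats},
        psi_ref=stats.psi_ref,
        psi_alt=stats.psi_alt,
        dpsi=stats.dpsi,
        confidence=stats.confidence,
    )


def integrate_methods(
    events_per_method: dict[str, Sequence[SplicingEvent]],
) -> list[SplicingEvent]:
    """Union events across methods, keyed by (label, family).

    Consensus ΔΨ and Ψ are means over the methods reporting the event;
    consensus confidence is the maximum; the direction suffix is
    recomputed from the consensus ΔΨ.  Events unique to one method are
    retained.  Same-key events with conflicting strands are not merged
    (kept per-method, logged).
    """
    merged: dict[tuple, SplicingEvent] = {}
    conflicts: list[SplicingEvent] = []
    for method, events in events_per_method.items():
        for ev in events:
            key = ev.key
            cur = merged.get(key)
            if cur is None:
                merged[key] = SplicingEvent(
                    label=ev.label,
                    family=ev.family,
                    event_type=ev.event_type,
                    chrom=ev.chrom,
                    strand=ev.strand,
                    gene_id=ev.gene_id,
                    annotated=ev.annotated,
                    zero_change=ev.zero_change,
                    method_stats=dict(ev.method_stats),
                )
                continue
            if cur.strand != ev.strand:
                log.warning("strand conflict for %s; kept unmerged", ev.label)
                conflicts.append(ev)
                continue
            cur.method_stats.update(ev.method_stats)
            cur.gene_id = cur.gene_id or ev.gene_id
            cur.annotated = cur.annotated or ev.annotated

    out = list(merged.values()) + conflicts
    for ev in out:
        stats = list(ev.method_stats.values())
        n = len(stats)
        ev.dpsi = sum(s.dpsi for s in stats) / n
        ev.confidence = max(s.confidence for s in stats)
        refs = [s.psi_ref for s in stats if s.psi_ref is not None]
        alts = [s.psi_alt for s in stats if s.psi_alt is not None]
        ev.psi_ref = sum(refs) / len(refs) if refs else None
        ev.psi_alt = sum(alts) / len(alts) if alts else None
        ev.event_type = event_type_for(ev.family, ev.dpsi)
        ev.zero_change = ev.dpsi == 0.0
    out.sort(key=lambda e: (e.chrom, e.label, e.family.value))
    return out


@dataclass
class MxeCandidate:
    gene_id: str
    label_in: str
    label_out: str
    exon_in: tuple[int, int]
    exon_out: tuple[int, int]


def flag_mxe_candidates(
    events: Iterable[SplicingEvent],
    idx: Optional[AnchorIndex] = None,
) -> list[MxeCandidate]:
    """Advisory flags for potential mutually-exclusive-exon pairs.

    Any (ESin, ESout) pair within one gene whose cassette exons are
    adjacent (no annotated exon strictly between them) and which share
    their outer anchors is a theoretical MXE candidate.  Events are left
    unchanged; this is a separate advisory table.
    """
    es_events = [
        e for e in events
        if e.family is Family.ES and e.gene_id
    ]
    by_gene: dict[str, list[SplicingEvent]] = {}
    for e in es_events:
        by_gene.setdefault(e.gene_id, []).append(e)

    def _parse(e: SplicingEvent) -> tuple[int, int, int, int]:
        body = e.label.split(":")[1]
        b = tuple(int(x) for x in body.split("-"))
        return b  # (1R, 2L, 2R, 3L)

    candidates = []
    for gene_id, evs in sorted(by_gene.items()):
        ins = [e for e in evs if e.event_type is EventType.ESIN]
        outs = [e for e in evs if e.event_type is EventType.ESOUT]
        for ei in ins:
            b_in = _parse(ei)
            for eo in outs:
                b_out = _parse(eo)
                if (b_in[0], b_in[3]) != (b_out[0], b_out[3]):
                    continue  # outer anchors must be shared
                exon_in, exon_out = (b_in[1], b_in[2]), (b_out[1], b_out[2])
                lo, hi = sorted((exon_in, exon_out))
                if lo[1] >= hi[0]:
                    continue  # overlapping exons are not an MXE geometry
                if idx is not None and _exon_between(ei.chrom, ei.strand, lo[1], hi[0], idx):
                    continue
                candidates.append(
                    MxeCandidate(gene_id, ei.label, eo.label, exon_in, exon_out)
                )
    return candidates


def _exon_between(chrom: str, strand: str, lo_end: int, hi_start: int, idx: AnchorIndex) -> bool:
    for (c, s, es, ee) in idx.exon_set:
        if c == chrom and s == strand and es > lo_end and ee < hi_start:
            return True
    return False


def call_significant(
    events: Iterable[SplicingEvent],
    dpsi_cutoff: float = 0.2,
    confidence_cutoff: float = 0.95,
    method: Optional[str] = None,
) -> list[SplicingEvent]:
    """Filter events by |ΔΨ| and confidence, both strictly greater-than.

    With ``method`` set, that method's own statistics are used (events the
    method did not report are dropped) — the per-method calling mode used
    for benchmarking.  Cutoffs must lie in [0, 1].
    """
    for name, v in (("dpsi_cutoff", dpsi_cutoff), ("confidence_cutoff", confidence_cutoff)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} {v} outside [0, 1]")
    out = []
    for ev in events:
        if method is None:
            dpsi, conf = ev.dpsi, ev.confidence
        else:
            st = ev.method_stats.get(method)
            if st is None:
                continue
            dpsi, conf = st.dpsi, st.confidence
        if abs(dpsi) > dpsi_cutoff and conf > confidence_cutoff:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Full per-method pipeline


@dataclass
class HarmonizeResult:
    events: list[SplicingEvent]
    per_method: dict[str, list[SplicingEvent]]
    mxe_candidates: list[MxeCandidate]
    mxe_passthrough: list[RmatsRecord]
    counts: dict[str, int]


def events_from_junction_groups(
    junctions, idx: Optional[AnchorIndex]
) -> list[SplicingEvent]:
    """Group → splice graph → event graphs → typed events, one method."""
    out = []
    for _, group in group_junctions(junctions).items():
        g = build_splice_graph(group)
        for eg in enumerate_event_graphs(g, idx):
            try:
                out.append(event_from_graph(eg, idx))
            except AggregationError:
                continue
    return out


def harmonize(
    rmats_records: Sequence[RmatsRecord] = (),
    leafcutter_records: Sequence[LeafcutterRecord] = (),
    majiq_records: Sequence[MajiqRecord] = (),
    idx: Optional[AnchorIndex] = None,
    leafcutter_dialect: str = "regtools",
    majiq_dialect: str = "intronic",
) -> HarmonizeResult:
    """Run the full junction-centric harmonization across methods."""
    counts: dict[str, int] = {}
    per_method: dict[str, list[SplicingEvent]] = {}

    rmats_junctions = []
    mxe_passthrough = []
    for rec in rmats_records:
        if rec.event_kind == "MXE":
            mxe_passthrough.append(rec)
            continue
        try:
            rmats_junctions.extend(rmats_event_to_junctions(rec))
        except GeometryError as exc:
            log.warning("skipping rMATS record: %s", exc)
    counts["rmats_junctions"] = len(rmats_junctions)

    lc_junctions = []
    for rec in leafcutter_records:
        j = normalize_junction(rec, Source.LEAFCUTTER, leafcutter_dialect)
        if j.strand == "?" and idx is not None:
            j.strand = resolve_strand(j, idx)
        lc_junctions.append(j)
    counts["leafcutter_junctions"] = len(lc_junctions)

    mj_junctions = [
        normalize_junction(rec, Source.MAJIQ, majiq_dialect)
        for rec in majiq_records
    ]
    counts["majiq_junctions"] = len(mj_junctions)

    for name, juncs in (
        ("rmats", rmats_junctions),
        ("leafcutter", lc_junctions),
        ("majiq", mj_junctions),
    ):
        if juncs:
            per_method[name] = events_from_junction_groups(juncs, idx)
            counts[f"{name}_events"] = len(per_method[name])

    events = integrate_methods(per_method)
    counts["integrated_events"] = len(events)
    mxe = flag_mxe_candidates(events, idx)
    counts["mxe_candidates"] = len(mxe)
    return HarmonizeResult(
        events=events,
        per_method=per_method,
        mxe_candidates=mxe,
        mxe_passthrough=mxe_passthrough,
        counts=counts,
    )
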