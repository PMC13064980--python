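"""Splice graphs and their decomposition into simplified event graphs.

A splice graph is built per structural group (one rMATS event, one
LeafCutter cluster, or one MAJIQ LSV): its nodes are the exonic anchor
boundaries adjacent to the member junctions, its edges the junctions
themselves.  Each graph is then decomposed into simplified event graphs —
three anchor nodes and two alternative splice paths — and every candidate
event is classified into one of the four families (ES, A5SS, A3SS, IR).

The direction suffix (in/out, long/short) is assigned later from the
aggregated alternative-path ΔΨ; see :mod:`spliceharmony.harmonize`.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import networkx as nx

from .junction_space import AnchorIndex
from .model import (
    EventGraph,
    Family,
    GeometryError,
    Junction,
    Role,
    format_label,
)

log = logging.getLogger(__name__)


def build_splice_graph(group: Iterable[Junction]) -> nx.Graph:
    """Anchor-boundary graph of one junction group.

    Nodes are exonic boundary coordinates (``start − 1`` and ``end + 1``
    of each intron); edges carry the junction.  Duplicate-coordinate
    junctions are merged keeping the higher-confidence statistics.
    """
    g = nx.Graph()
    for j in group:
        u, v = j.left_anchor, j.right_anchor
        if g.has_edge(u, v):
            old: Junction = g.edges[u, v]["junction"]
            old_conf = old.stats.confidence if old.stats else -1.0
            new_conf = j.stats.confidence if j.stats else -1.0
            if new_conf <= old_conf:
                continue
        g.add_edge(u, v, junction=j)
    return g


def graph_junctions(g: nx.Graph) -> list[Junction]:
    return sorted(
        (data["junction"] for _, _, data in g.edges(data=True)),
        key=lambda j: (j.start, j.end),
    )


def splice_graph_dot(g: nx.Graph) -> str:
    """Debug dump of a splice graph as DOT text."""
    lines = ["graph splice {"]
    for u, v, data in sorted(g.edges(data=True)):
        j: Junction = data["junction"]
        dpsi = f"{j.stats.dpsi:+.3f}" if j.stats else "?"
        lines.append(f'  "{u}" -- "{v}" [label="{j.start}-{j.end} dpsi={dpsi}"];')
    lines.append("}")
    return "\n".join(lines)


def _exon_evidenced(
    chrom: str, strand: str, exon_start: int, exon_end: int,
    idx: Optional[AnchorIndex],
) -> bool:
    """An intervening exon is evidenced by annotation (either GTF).

    Group-internal evidence (both boundary anchors supplied by junctions
    of the same group) is handled by the caller: the existence of the two
    inclusion junctions is itself that evidence, so cryptic exons still
    form ES events.
    """
    if idx is None:
        return False
    for s in ([strand] if strand in "+-" else ["+", "-"]):
        if idx.has_exon(chrom, s, exon_start, exon_end):
            return True
    return False


def enumerate_event_graphs(
    g: nx.Graph,
    idx: Optional[AnchorIndex] = None,
) -> list[EventGraph]:
    """Decompose one splice graph into candidate simplified events.

    Emits (i) an ES event for every junction ``(a, b)`` bridged by two
    junctions ``(a, x)`` and ``(y, b)`` that leave room for an intervening
    exon ``[x+1, y−1]``; (ii) an A5SS/A3SS event for every junction pair
    sharing exactly one anchor and not consumed by an ES (ES takes
    priority so one junction pair is never reported twice); (iii) an IR
    event for every retention-flagged junction.  Pairs on unknown strand
    cannot be split into donor/acceptor sharing and are dropped with a
    logged count.  Duplicates are removed by (family, anchors).
    """
    junctions = graph_junctions(g)
    if not junctions:
        return []
    chrom = junctions[0].chrom
    events: list[EventGraph] = []
    consumed_pairs: set[frozenset[tuple[int, int]]] = set()
    seen: set[tuple[Family, tuple[int, ...]]] = set()

    by_start: dict[int, list[Junction]] = {}
    by_end: dict[int, list[Junction]] = {}
    for j in junctions:
        by_start.setdefault(j.start, []).append(j)
        by_end.setdefault(j.end, []).append(j)

    # --- ES: skip junction bridged by two inclusion junctions
    for skip in junctions:
        for j1 in by_start.get(skip.start, []):
            if j1.end >= skip.end:
                continue
            for j2 in by_end.get(skip.end, []):
                if j2.start <= j1.end + 1:
                    continue  # no room for an exon between the inclusion introns
                exon = (j1.end + 1, j2.start - 1)
                annotated_exon = _exon_evidenced(
                    chrom, skip.strand, exon[0], exon[1], idx
                )
                anchors = (skip.left_anchor, exon[0], exon[1], skip.right_anchor)
                key = (Family.ES, anchors)
                if key in seen:
                    continue
                seen.add(key)
                events.append(
                    EventGraph(
                        family=Family.ES,
                        chrom=chrom,
                        strand=skip.strand,
                        anchors=anchors,
                        path_alt=[j1, j2],
                        path_ref=[skip],
                        source=skip.source,
                        group_id=skip.group_id,
                        annotated=annotated_exon,
                    )
                )
                consumed_pairs.add(frozenset({(skip.start, skip.end), (j1.start, j1.end)}))
                consumed_pairs.add(frozenset({(skip.start, skip.end), (j2.start, j2.end)}))

    # --- A5SS / A3SS: pairs sharing exactly one anchor
    n_unknown_strand = 0
    for i, ja in enumerate(junctions):
        for jb in junctions[i + 1:]:
            share_start = ja.start == jb.start and ja.end != jb.end
            share_end = ja.end == jb.end and ja.start != jb.start
            if not (share_start or share_end):
                continue
            if frozenset({(ja.start, ja.end), (jb.start, jb.end)}) in consumed_pairs:
                continue
            strand = ja.strand
            if strand not in "+-":
                n_unknown_strand += 1
                continue
            # shared left anchor = shared upstream exon end: donor on '+',
            # acceptor on '-'; varying boundary defines the family
            if share_start:
                family = Family.A3SS if strand == "+" else Family.A5SS
                anchors = (
                    ja.left_anchor,
                    min(ja.end, jb.end) + 1,
                    max(ja.end, jb.end) + 1,
                )
            else:
                family = Family.A5SS if strand == "+" else Family.A3SS
                anchors = (
                    min(ja.start, jb.start) - 1,
                    max(ja.start, jb.start) - 1,
                    ja.right_anchor,
                )
            key = (family, anchors)
            if key in seen:
                continue
            seen.add(key)
            # long-exon variant = the junction with the shorter intron
            long_j, short_j = sorted(
                (ja, jb), key=lambda j: j.end - j.start
            )
            events.append(
                EventGraph(
                    family=family,
                    chrom=chrom,
                    strand=strand,
                    anchors=anchors,
                    path_alt=[long_j],
                    path_ref=[short_j],
                    source=ja.source,
                    group_id=ja.group_id,
                    annotated=_pair_annotated(ja, jb, idx),
                )
            )
    if n_unknown_strand:
        log.info(
            "enumerate_event_graphs: dropped %d unknown-strand splice-site pairs",
            n_unknown_strand,
        )

    # --- IR: retention-flagged junctions
    for j in junctions:
        if j.role is Role.RETENTION or j.is_retention:
            anchors = (j.left_anchor, j.right_anchor)
            key = (Family.IR, anchors)
            if key in seen:
                continue
            seen.add(key)
            events.append(
                EventGraph(
                    family=Family.IR,
                    chrom=chrom,
                    strand=j.strand,
                    anchors=anchors,
                    path_alt=[j],
                    path_ref=[],
                    source=j.source,
                    group_id=j.group_id,
                    annotated=_junction_annotated(j, idx),
                )
            )
    events.sort(key=lambda e: (e.anchors, e.family.value))
    return events


def _junction_annotated(j: Junction, idx: Optional[AnchorIndex]) -> bool:
    if idx is None:
        return False
    strands = [j.strand] if j.strand in "+-" else ["+", "-"]
    return any((j.chrom, s, j.start, j.end) in idx.introns for s in strands)


def _pair_annotated(ja: Junction, jb: Junction, idx: Optional[AnchorIndex]) -> bool:
    return _junction_annotated(ja, idx) and _junction_annotated(jb, idx)


def classify_family_direction(e: EventGraph, alt_dpsi: float) -> tuple[str, bool]:
    """Direction suffix from the alternative-path ΔΨ sign.

    Returns ``(suffix, zero_change)``; ΔΨ == 0 resolves to the positive
    form with the zero-change flag set.  A5SS/A3SS events on unknown
    strand never reach this point (dropped during enumeration).
    """
    if e.family in (Family.A5SS, Family.A3SS) and e.strand not in "+-":
        raise GeometryError("cannot classify splice-site event on unknown strand")
    zero = alt_dpsi == 0.0
    return ("pos" if alt_dpsi >= 0 else "neg"), zero


def label_event(e: EventGraph) -> str:
    """Canonical cross-method label: chrom:boundaries:strand ascending."""
    return format_label(e.chrom, e.anchors, e.strand)
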