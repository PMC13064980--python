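"""Canonical junction space: one coordinate system for all three tools.

Dialect conversions to the canonical 1-based closed intronic interval:

* rMATS: exon coordinates are 0-based starts / 1-based inclusive ends, so
  an intron between an upstream exon ending at ``EE`` and a downstream
  exon with 0-based start ``ES0`` is ``(EE + 1, ES0)``.
* LeafCutter (regtools dialect, default): raw start is the last exonic
  base of the upstream exon and raw end the first exonic base of the
  downstream exon → ``(raw_start + 1, raw_end − 1)``.  The bed dialect
  stores the intron half-open 0-based → ``(raw_start + 1, raw_end)``.
* MAJIQ (intronic dialect, default): raw coordinates already are the first
  and last intronic base → identity.  The exonic dialect mirrors
  regtools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    CoordinateError,
    GeometryError,
    Junction,
    MethodStats,
    Role,
    Source,
)
from .tool_io import (
    AnnotationModel,
    LeafcutterRecord,
    MajiqRecord,
    RmatsRecord,
)

log = logging.getLogger(__name__)

LEAFCUTTER_DIALECTS = ("regtools", "bed")
MAJIQ_DIALECTS = ("intronic", "exonic")


def leafcutter_to_canonical(start_raw: int, end_raw: int, dialect: str = "regtools") -> tuple[int, int]:
    if dialect == "regtools":
        return start_raw + 1, end_raw - 1
    if dialect == "bed":
        return start_raw + 1, end_raw
    raise CoordinateError(f"unknown LeafCutter dialect {dialect!r}")


def canonical_to_leafcutter(start: int, end: int, dialect: str = "regtools") -> tuple[int, int]:
    if dialect == "regtools":
        return start - 1, end + 1
    if dialect == "bed":
        return start - 1, end
    raise CoordinateError(f"unknown LeafCutter dialect {dialect!r}")


def majiq_to_canonical(start_raw: int, end_raw: int, dialect: str = "intronic") -> tuple[int, int]:
    if dialect == "intronic":
        return start_raw, end_raw
    if dialect == "exonic":
        return start_raw + 1, end_raw - 1
    raise CoordinateError(f"unknown MAJIQ dialect {dialect!r}")


def canonical_to_majiq(start: int, end: int, dialect: str = "intronic") -> tuple[int, int]:
    if dialect == "intronic":
        return start, end
    if dialect == "exonic":
        return start - 1, end + 1
    raise CoordinateError(f"unknown MAJIQ dialect {dialect!r}")


def normalize_junction(
    record: LeafcutterRecord | MajiqRecord,
    source: Source | str,
    dialect: Optional[str] = None,
) -> Junction:
    """Convert one per-junction tool record into a canonical Junction."""
    source = Source(source)
    if source is Source.LEAFCUTTER:
        assert isinstance(record, LeafcutterRecord)
        start, end = leafcutter_to_canonical(
            record.intron_start_raw, record.intron_end_raw, dialect or "regtools"
        )
        if start > end:
            raise CoordinateError(
                f"LeafCutter dialect conversion inverted interval "
                f"{record.intron_start_raw}:{record.intron_end_raw}"
            )
        return Junction(
            chrom=record.chrom,
            strand=record.strand if record.strand in "+-" else "?",
            start=start,
            end=end,
            source=source,
            group_id=record.cluster_id,
            role=Role.PLAIN,
            stats=MethodStats(
                dpsi=record.dpsi,
                confidence=max(0.0, 1.0 - record.fdr),
                psi_ref=record.psi_ref,
                psi_alt=record.psi_alt,
            ),
        )
    if source is Source.MAJIQ:
        assert isinstance(record, MajiqRecord)
        start, end = majiq_to_canonical(
            record.junc_start_raw, record.junc_end_raw, dialect or "intronic"
        )
        if start > end:
            raise CoordinateError(
                f"MAJIQ dialect conversion inverted interval "
                f"{record.junc_start_raw}:{record.junc_end_raw}"
            )
        return Junction(
            chrom=record.chrom,
            strand=record.strand if record.strand in "+-" else "?",
            start=start,
            end=end,
            source=source,
            group_id=record.lsv_id,
            role=Role.RETENTION if record.is_intron_retention else Role.PLAIN,
            is_retention=record.is_intron_retention,
            stats=MethodStats(
                dpsi=record.dpsi,
                confidence=record.changing_prob,
                psi_ref=record.psi_ref,
                psi_alt=record.psi_alt,
            ),
        )
    raise CoordinateError(f"normalize_junction does not handle source {source}")


def rmats_event_to_junctions(record: RmatsRecord) -> list[Junction]:
    """Explode one rMATS event row into canonical junctions.

    SE yields the two inclusion junctions plus the skip junction; the skip
    junction's Ψ values are complemented (1 − Ψ) and its ΔΨ negated so all
    junctions of the event share one inclusion orientation.  A5SS/A3SS
    yield the long- and short-exon variant junctions; RI yields a single
    retention junction spanning the intron.  MXE rows are not exploded
    (handled separately as flagged candidates).
    """
    c = record.coords
    stats = MethodStats(
        dpsi=record.inc_level_difference,
        confidence=max(0.0, 1.0 - record.fdr),
        psi_ref=record.inc_level_ref,
        psi_alt=record.inc_level_alt,
    )
    base = dict(
        chrom=record.chrom,
        strand=record.strand,
        source=Source.RMATS,
        group_id=record.event_id,
    )
    kind = record.event_kind
    if kind == "SE":
        up_ee, ex_s0, ex_ee, dn_s0 = (
            c["upstreamEE"], c["exonStart_0base"], c["exonEnd"], c["downstreamES"]
        )
        if not (c["upstreamES"] < up_ee <= ex_s0 < ex_ee <= dn_s0):
            raise GeometryError(f"{record.event_id}: inconsistent SE exon ordering")
        return [
            Junction(start=up_ee + 1, end=ex_s0, role=Role.INCLUSION_UPSTREAM,
                     stats=stats, **base),
            Junction(start=ex_ee + 1, end=dn_s0, role=Role.INCLUSION_DOWNSTREAM,
                     stats=stats, **base),
            Junction(start=up_ee + 1, end=dn_s0, role=Role.SKIP,
                     stats=stats.complemented(), **base),
        ]
    if kind in ("A5SS", "A3SS"):
        long_s0, long_e = c["longExonStart_0base"], c["longExonEnd"]
        short_s0, short_e = c["shortES"], c["shortEE"]
        flank_s0, flank_e = c["flankingES"], c["flankingEE"]
        # variant exons sit left of the flanking exon iff they end before it starts
        if long_e <= flank_s0:
            long_j = (long_e + 1, flank_s0)
            short_j = (short_e + 1, flank_s0)
        elif flank_e <= long_s0:
            long_j = (flank_e + 1, long_s0)
            short_j = (flank_e + 1, short_s0)
        else:
            raise GeometryError(f"{record.event_id}: variant/flanking exons overlap")
        # rMATS Ψ is inclusion of the long form; short variant is its complement
        return [
            Junction(start=long_j[0], end=long_j[1], role=Role.LONG_VARIANT,
                     stats=stats, **base),
            Junction(start=short_j[0], end=short_j[1], role=Role.SHORT_VARIANT,
                     stats=stats.complemented(), **base),
        ]
    if kind == "RI":
        up_ee, dn_s0 = c["upstreamEE"], c["downstreamES"]
        if not up_ee < dn_s0:
            raise GeometryError(f"{record.event_id}: inconsistent RI exon ordering")
        return [
            Junction(start=up_ee + 1, end=dn_s0, role=Role.RETENTION,
                     is_retention=True, stats=stats, **base),
        ]
    if kind == "MXE":
        return []
    raise GeometryError(f"unknown rMATS event kind {kind!r}")


# ---------------------------------------------------------------------------
# Annotation index


@dataclass
class AnchorIndex:
    """Fast lookup over one or two annotation models.

    Combines a reference GTF and an optional assembled (de novo) GTF so
    that junctions can be annotated against both, and genes can be
    assigned by boundary ownership or span containment.
    """

    boundary_genes: dict[tuple[str, str, int, str], set[str]] = field(default_factory=dict)
    introns: set[tuple[str, str, int, int]] = field(default_factory=set)
    exon_set: set[tuple[str, str, int, int]] = field(default_factory=set)
    gene_trees: dict[str, IntervalTree] = field(default_factory=dict)
    gene_strand: dict[str, str] = field(default_factory=dict)
    models: tuple[AnnotationModel, ...] = ()

    @classmethod
    def build(cls, *models: AnnotationModel) -> "AnchorIndex":
        idx = cls(models=models)
        for model in models:
            for key, genes in model.boundary_index.items():
                idx.boundary_genes.setdefault(key, set()).update(genes)
            idx.introns |= model.introns
            idx.exon_set |= model.exon_set
            for gene in model.genes.values():
                lo, hi = gene.span
                idx.gene_trees.setdefault(gene.chrom, IntervalTree()).addi(
                    lo, hi + 1, gene.gene_id
                )
                idx.gene_strand[gene.gene_id] = gene.strand
        return idx

    def has_exon(self, chrom: str, strand: str, start: int, end: int) -> bool:
        return (chrom, strand, start, end) in self.exon_set

    def genes_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self.gene_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end + 1)}


@dataclass
class AnnotationStatus:
    status: str  # annotated | novel_boundary | novel_combination
    gene_id: str = ""


def annotate_junction(j: Junction, idx: AnchorIndex) -> AnnotationStatus:
    """Classify a junction against the annotation boundary index.

    * ``annotated``: both anchor boundaries are exon boundaries of one
      common gene and the intron itself appears in some transcript;
    * ``novel_combination``: both boundaries are known but never paired;
    * ``novel_boundary``: at least one boundary is not an exon boundary.

    Gene assignment falls back to unique span containment; boundaries
    owned by two different genes leave ``gene_id`` empty (logged).
    """
    strands = [j.strand] if j.strand in "+-" else ["+", "-"]
    for strand in strands:
        left = idx.boundary_genes.get((j.chrom, strand, j.left_anchor, "R"))
        right = idx.boundary_genes.get((j.chrom, strand, j.right_anchor, "L"))
        if left and right:
            common = left & right
            if common:
                gene_id = next(iter(common)) if len(common) == 1 else ""
            else:
                log.debug(
                    "junction %s:%d-%d boundaries owned by different genes",
                    j.chrom, j.start, j.end,
                )
                gene_id = ""
            if (j.chrom, strand, j.start, j.end) in idx.introns:
                return AnnotationStatus("annotated", gene_id)
            return AnnotationStatus("novel_combination", gene_id)
    # >=1 boundary unmatched on any compatible strand
    genes = idx.genes_overlapping(j.chrom, j.left_anchor, j.right_anchor)
    if j.strand in "+-":
        genes = {g for g in genes if idx.gene_strand.get(g) == j.strand}
    gene_id = next(iter(genes)) if len(genes) == 1 else ""
    return AnnotationStatus("novel_boundary", gene_id)


def resolve_strand(j: Junction, idx: AnchorIndex) -> str:
    """Resolve strand '?' by unique overlapping gene; else keep '?'."""
    if j.strand in "+-":
        return j.strand
    genes = idx.genes_overlapping(j.chrom, j.left_anchor, j.right_anchor)
    strands = {idx.gene_strand[g] for g in genes}
    if len(strands) == 1:
        return next(iter(strands))
    return "?"


def group_junctions(
    junctions: Iterable[Junction],
) -> dict[tuple[Source, str], list[Junction]]:
    """Group junctions by (source, group id), sorted by coordinates."""
    groups: dict[tuple[Source, str], list[Junction]] = {}
    for j in junctions:
        groups.setdefault((j.source, j.group_id), []).append(j)
    for key in groups:
        groups[key].sort(key=lambda j: (j.start, j.end))
    return dict(sorted(groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1])))
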