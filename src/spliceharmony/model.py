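"""Shared domain types for splicing-event harmonization.

Coordinate convention used everywhere in this package: a junction is the
intron it spans, stored as a 1-based closed interval ``[start, end]`` over
the *intronic* bases (``start`` = first intronic base, ``end`` = last
intronic base).  The exonic anchor boundaries are then ``start - 1`` (last
base of the upstream exon, an "R" boundary) and ``end + 1`` (first base of
the downstream exon, an "L" boundary).  All tool dialects are converted to
this system on input and back on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class SpliceHarmonyError(Exception):
    """Base class for all package errors."""


class SchemaError(SpliceHarmonyError):
    """An input table is missing a required column or has a bad layout."""


class RowError(SpliceHarmonyError):
    """A single input row could not be parsed; carries row context."""


class EmptyAnnotationError(SpliceHarmonyError):
    """A GTF contained no usable exon lines."""


class CoordinateError(SpliceHarmonyError):
    """Dialect conversion produced an inverted or negative interval."""


class GeometryError(SpliceHarmonyError):
    """Event geometry is inconsistent (exon ordering, missing anchors)."""


class AggregationError(SpliceHarmonyError):
    """An event graph had no member junction carrying statistics."""


class ParameterError(SpliceHarmonyError):
    """A user-supplied parameter is outside its valid range."""


class CapacityError(SpliceHarmonyError):
    """The annotation cannot host the requested number of truth events."""


class Source(str, Enum):
    RMATS = "rmats"
    LEAFCUTTER = "leafcutter"
    MAJIQ = "majiq"


class Role(str, Enum):
    """Role a junction plays inside its originating structure."""

    INCLUSION_UPSTREAM = "inclusion_upstream"
    INCLUSION_DOWNSTREAM = "inclusion_downstream"
    SKIP = "skip"
    LONG_VARIANT = "long_variant"
    SHORT_VARIANT = "short_variant"
    RETENTION = "retention"
    PLAIN = "plain"


class Family(str, Enum):
    ES = "ES"
    A5SS = "A5SS"
    A3SS = "A3SS"
    IR = "IR"


class EventType(str, Enum):
    """The eight typed outcomes: four families x two ΔΨ directions."""

    ESIN = "ESin"
    ESOUT = "ESout"
    A5SS_LONG = "A5SSlong"
    A5SS_SHORT = "A5SSshort"
    A3SS_LONG = "A3SSlong"
    A3SS_SHORT = "A3SSshort"
    IRIN = "IRin"
    IROUT = "IRout"

    @property
    def family(self) -> Family:
        return _TYPE_FAMILY[self]

    @property
    def positive(self) -> bool:
        """True for the direction associated with ΔΨ > 0 on the alt path."""
        return self in (
            EventType.ESIN,
            EventType.A5SS_LONG,
            EventType.A3SS_LONG,
            EventType.IRIN,
        )


_TYPE_FAMILY = {
    EventType.ESIN: Family.ES,
    EventType.ESOUT: Family.ES,
    EventType.A5SS_LONG: Family.A5SS,
    EventType.A5SS_SHORT: Family.A5SS,
    EventType.A3SS_LONG: Family.A3SS,
    EventType.A3SS_SHORT: Family.A3SS,
    EventType.IRIN: Family.IR,
    EventType.IROUT: Family.IR,
}


def event_type_for(family: Family, dpsi: float) -> EventType:
    """Direction suffix from the sign of the alternative-path ΔΨ.

    ΔΨ == 0 resolves to the positive form; callers carry a zero-change
    flag alongside.
    """
    positive = dpsi >= 0
    table = {
        (Family.ES, True): EventType.ESIN,
        (Family.ES, False): EventType.ESOUT,
        (Family.A5SS, True): EventType.A5SS_LONG,
        (Family.A5SS, False): EventType.A5SS_SHORT,
        (Family.A3SS, True): EventType.A3SS_LONG,
        (Family.A3SS, False): EventType.A3SS_SHORT,
        (Family.IR, True): EventType.IRIN,
        (Family.IR, False): EventType.IROUT,
    }
    return table[(family, positive)]


@dataclass
class MethodStats:
    """Per-method Ψ/ΔΨ statistics for one junction or event.

    ``confidence`` is 1 − FDR for rMATS and LeafCutter and the posterior
    changing probability P for MAJIQ; either way it lives in [0, 1].
    """

    dpsi: float
    confidence: float
    psi_ref: Optional[float] = None
    psi_alt: Optional[float] = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.dpsi <= 1.0 + 1e-9:
            raise ParameterError(f"dpsi {self.dpsi} outside [-1, 1]")
        if not 0.0 - 1e-9 <= self.confidence <= 1.0 + 1e-9:
            raise ParameterError(f"confidence {self.confidence} outside [0, 1]")
        for name in ("psi_ref", "psi_alt"):
            v = getattr(self, name)
            if v is not None and not 0.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ParameterError(f"{name} {v} outside [0, 1]")

    def complemented(self) -> "MethodStats":
        """Flip inclusion orientation: Ψ → 1 − Ψ, ΔΨ → −ΔΨ."""
        return MethodStats(
            dpsi=-self.dpsi,
            confidence=self.confidence,
            psi_ref=None if self.psi_ref is None else 1.0 - self.psi_ref,
            psi_alt=None if self.psi_alt is None else 1.0 - self.psi_alt,
        )


@dataclass
class Junction:
    """A canonical intron interval with per-tool statistics."""

    chrom: str
    strand: str  # "+", "-" or "?"
    start: int  # 1-based first intronic base
    end: int  # 1-based last intronic base
    source: Source
    group_id: str
    role: Role = Role.PLAIN
    stats: Optional[MethodStats] = None
    is_retention: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(
                f"junction start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise CoordinateError(f"junction start {self.start} < 1")

    @property
    def coords(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)

    @property
    def left_anchor(self) -> int:
        """Exonic boundary upstream of the intron (an 'R' exon end)."""
        return self.start - 1

    @property
    def right_anchor(self) -> int:
        """Exonic boundary downstream of the intron (an 'L' exon start)."""
        return self.end + 1

    def with_stats(self, stats: MethodStats) -> "Junction":
        return replace(self, stats=stats)


@dataclass
class EventGraph:
    """Simplified local splice decision: shared anchors, two paths.

    ``path_alt`` holds the alternative-path junction(s) whose inclusion
    defines the event's ΔΨ orientation (ES: the two inclusion junctions;
    A5SS/A3SS: the long-exon variant junction; IR: the retention junction).
    ``path_ref`` holds the competing path (ES: skip; A5SS/A3SS: the short
    variant; IR: empty — splicing is the implicit reference).
    """

    family: Family
    chrom: str
    strand: str
    anchors: tuple[int, ...]
    path_alt: list[Junction]
    path_ref: list[Junction]
    source: Source
    group_id: str
    annotated: bool = False

    @property
    def label(self) -> str:
        return format_label(self.chrom, self.anchors, self.strand)

    @property
    def key(self) -> tuple[str, Family]:
        return (self.label, self.family)


def format_label(chrom: str, anchors: tuple[int, ...], strand: str) -> str:
    """Canonical cross-method event label from anchor boundaries.

    Boundaries are exonic coordinates in ascending genomic order; ES events
    carry four, alternative splice-site events three, intron retention two.
    """
    body = "-".join(str(b) for b in sorted(anchors))
    return f"{chrom}:{body}:{strand}"


@dataclass
class SplicingEvent:
    """A typed, labeled, harmonized splicing event."""

    label: str
    family: Family
    event_type: EventType
    chrom: str
    strand: str
    gene_id: str = ""
    annotated: bool = False
    zero_change: bool = False
    method_stats: dict[str, MethodStats] = field(default_factory=dict)
    psi_ref: Optional[float] = None
    psi_alt: Optional[float] = None
    dpsi: float = 0.0
    confidence: float = 0.0

    @property
    def n_methods(self) -> int:
        return len(self.method_stats)

    @property
    def key(self) -> tuple[str, Family]:
        return (self.label, self.family)


@dataclass
class TruthEvent:
    """Ground-truth simulated event with its expected ΔΨ per condition."""

    gene_id: str
    event_type: EventType
    chrom: str
    strand: str
    anchors: tuple[int, ...]
    cryptic: bool
    # canonical intron intervals participating in the event, keyed by role
    junctions: dict[Role, tuple[int, int]]
    control_exons: list[tuple[int, int]]
    alt_exons: list[tuple[int, int]]

    @property
    def family(self) -> Family:
        return self.event_type.family

    @property
    def label(self) -> str:
        return format_label(self.chrom, self.anchors, self.strand)

    def expected_dpsi(self, alt_fraction: float) -> float:
        """Signed expected ΔΨ of the alternative path under a mixing ratio."""
        return alt_fraction if self.event_type.positive else -alt_fraction


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    tn_defined: bool = True

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")
        if not self.tn_defined and self.tn != 0:
            raise ParameterError("tn must be 0 when tn_defined is False")


@dataclass
class MetricSet:
    identification_pct: float
    n_true: int
    recall: Optional[float]
    precision: Optional[float]
    accuracy: Optional[float]


@dataclass
class ThresholdCurve:
    grid: tuple[float, ...]
    fpr: list[float]
    tpr: list[float]
    auroc: Optional[float]
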