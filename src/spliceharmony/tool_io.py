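"""Readers and writers for the three splicing tools' output dialects.

rMATS writes one row per predefined event with exon coordinates
(0-based starts, 1-based inclusive ends); LeafCutter writes one row per
intron junction keyed ``chrom:start:end:cluster`` joined to cluster-level
adjusted p-values; VOILA (MAJIQ) writes one row per LSV with
semicolon-separated per-junction fields.  Each reader normalizes into a
typed record list; coordinate-system conversion happens later in
:mod:`spliceharmony.junction_space`.

All readers are dialect-versioned behind keyword arguments so new tool
versions add a dialect rather than a fork.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .model import (
    EmptyAnnotationError,
    EventType,
    Family,
    MethodStats,
    RowError,
    SchemaError,
    SplicingEvent,
    TruthEvent,
    Role,
)

log = logging.getLogger(__name__)

RMATS_EVENT_KINDS = ("SE", "A5SS", "A3SS", "RI", "MXE")

# Coordinate columns per rMATS event kind (real rMATS *.MATS.*.txt naming).
RMATS_COORD_COLUMNS = {
    "SE": [
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    "A5SS": [
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
    "A3SS": [
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
    "RI": [
        "riExonStart_0base", "riExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    "MXE": [
        "1stExonStart_0base", "1stExonEnd",
        "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
}

RMATS_STAT_COLUMNS = ["IncLevel1", "IncLevel2", "IncLevelDifference", "FDR"]


# ---------------------------------------------------------------------------
# Annotation


@dataclass
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted, non-overlapping

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Canonical intronic intervals between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for t in self.transcripts.values() for e in t.exons]
        ends = [e[1] for t in self.transcripts.values() for e in t.exons]
        return (min(starts), max(ends))

    @property
    def exons(self) -> set[tuple[int, int]]:
        return {e for t in self.transcripts.values() for e in t.exons}


@dataclass
class AnnotationModel:
    """Genes → transcripts → ordered exon intervals, plus boundary index.

    ``boundary_index`` maps ``(chrom, strand, position, side)`` to the set
    of owning gene ids, where side ``"L"`` marks exon starts and ``"R"``
    exon ends.  ``introns`` holds every annotated intron in canonical
    intronic coordinates.
    """

    genes: dict[str, Gene] = field(default_factory=dict)
    boundary_index: dict[tuple[str, str, int, str], set[str]] = field(
        default_factory=dict
    )
    introns: set[tuple[str, str, int, int]] = field(default_factory=set)
    exon_set: set[tuple[str, str, int, int]] = field(default_factory=set)

    def add_exon(
        self, gene_id: str, tx_id: str, chrom: str, strand: str,
        start: int, end: int,
    ) -> None:
        gene = self.genes.setdefault(gene_id, Gene(gene_id, chrom, strand))
        tx = gene.transcripts.setdefault(
            tx_id, Transcript(tx_id, gene_id, chrom, strand, [])
        )
        tx.exons.append((start, end))

    def finalize(self) -> None:
        for gene in self.genes.values():
            for tx in gene.transcripts.values():
                tx.exons.sort()
                for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
                    if s2 <= e1:
                        raise RowError(
                            f"overlapping exons {s1}-{e1} and {s2}-{e2} "
                            f"in transcript {tx.tx_id}"
                        )
                for s, e in tx.exons:
                    self.boundary_index.setdefault(
                        (gene.chrom, gene.strand, s, "L"), set()
                    ).add(gene.gene_id)
                    self.boundary_index.setdefault(
                        (gene.chrom, gene.strand, e, "R"), set()
                    ).add(gene.gene_id)
                    self.exon_set.add((gene.chrom, gene.strand, s, e))
                for s, e in tx.introns:
                    self.introns.add((gene.chrom, gene.strand, s, e))


def _validate_gtf_lines(path: str | os.PathLike) -> int:
    """Cheap pre-scan for malformed exon lines; returns exon line count."""
    n_exons = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise RowError(f"line {lineno}: expected 9 GTF columns, got {len(fields)}")
            if fields[2] != "exon":
                continue
            attrs = fields[8]
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise RowError(
                    f"line {lineno}: exon line missing gene_id/transcript_id attributes"
                )
            n_exons += 1
    return n_exons


def read_gtf(path: str | os.PathLike) -> AnnotationModel:
    """Parse a GTF into an :class:`AnnotationModel`.

    Only ``exon`` features are consumed; single-exon transcripts are
    retained.  Raises :class:`EmptyAnnotationError` when no exon lines are
    present and :class:`RowError` (with line number) on malformed lines.
    """
    if _validate_gtf_lines(path) == 0:
        raise EmptyAnnotationError(f"{path}: no exon lines in GTF")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise RowError(f"{path}: GTF parse failure: {exc}") from exc
    model = AnnotationModel()
    for feat in db.features_of_type("exon"):
        gene_id = feat.attributes["gene_id"][0]
        tx_id = feat.attributes["transcript_id"][0]
        model.add_exon(gene_id, tx_id, feat.seqid, feat.strand, feat.start, feat.end)
    model.finalize()
    return model


# ---------------------------------------------------------------------------
# rMATS


@dataclass
class RmatsRecord:
    """One rMATS event row, coordinates kept in the source's own system."""

    event_kind: str
    event_id: str
    gene_id: str
    chrom: str
    strand: str
    coords: dict[str, int]
    inc_level_ref: Optional[float]
    inc_level_alt: Optional[float]
    inc_level_difference: float
    fdr: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.inc_level_difference <= 1.0 + 1e-9:
            raise RowError(
                f"IncLevelDifference {self.inc_level_difference} outside [-1, 1]"
            )
        for name, v in self.coords.items():
            if v < 0:
                raise RowError(f"negative coordinate {name}={v}")


def _mean_inc_level(text: str) -> Optional[float]:
    vals = [v for v in str(text).split(",") if v.strip() not in ("NA", "", "nan")]
    if not vals:
        return None
    return float(np.mean([float(v) for v in vals]))


def read_rmats(
    dir_or_files: str | os.PathLike | Sequence[str | os.PathLike],
    junction_count_variant: str = "JC",
    swap_groups: bool = False,
) -> list[RmatsRecord]:
    """Read rMATS ``*.MATS.JC.txt`` / ``*.MATS.JCEC.txt`` tables.

    By default SAMPLE_1 / IncLevel1 is treated as the treated (alt) group
    and SAMPLE_2 / IncLevel2 as the control (ref) group, so that
    ``IncLevelDifference = IncLevel1 − IncLevel2`` equals ΔΨ = Ψalt − Ψref;
    pass ``swap_groups=True`` for the opposite layout.  Rows whose
    replicate Ψ strings are all-NA in a group are dropped with a logged
    count.
    """
    if junction_count_variant not in ("JC", "JCEC"):
        raise SchemaError(f"unknown junction count variant {junction_count_variant!r}")
    if isinstance(dir_or_files, (str, os.PathLike)) and Path(dir_or_files).is_dir():
        files = sorted(
            Path(dir_or_files).glob(f"*.MATS.{junction_count_variant}.txt")
        )
    elif isinstance(dir_or_files, (str, os.PathLike)):
        files = [Path(dir_or_files)]
    else:
        files = [Path(f) for f in dir_or_files]

    records: list[RmatsRecord] = []
    n_dropped = 0
    for path in files:
        kind = path.name.split(".")[0]
        if kind not in RMATS_EVENT_KINDS:
            raise SchemaError(f"{path}: cannot infer rMATS event kind from filename")
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = (
            ["ID", "GeneID", "chr", "strand"]
            + RMATS_COORD_COLUMNS[kind]
            + RMATS_STAT_COLUMNS
        )
        for col in required:
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column {col!r}")
        for i, row in df.iterrows():
            try:
                fdr = float(row["FDR"])
            except ValueError as exc:
                raise RowError(f"{path} row {i}: non-numeric FDR {row['FDR']!r}") from exc
            lvl1 = _mean_inc_level(row["IncLevel1"])
            lvl2 = _mean_inc_level(row["IncLevel2"])
            if lvl1 is None or lvl2 is None:
                n_dropped += 1
                continue
            alt, ref = (lvl2, lvl1) if swap_groups else (lvl1, lvl2)
            dpsi = float(row["IncLevelDifference"])
            if swap_groups:
                dpsi = -dpsi
            coords = {c: int(row[c]) for c in RMATS_COORD_COLUMNS[kind]}
            records.append(
                RmatsRecord(
                    event_kind=kind,
                    event_id=f"{kind}:{row['ID']}",
                    gene_id=str(row["GeneID"]).strip('"'),
                    chrom=str(row["chr"]),
                    strand=str(row["strand"]),
                    coords=coords,
                    inc_level_ref=ref,
                    inc_level_alt=alt,
                    inc_level_difference=dpsi,
                    fdr=fdr,
                )
            )
    if n_dropped:
        log.info("read_rmats: dropped %d rows with all-NA IncLevel", n_dropped)
    return records


# ---------------------------------------------------------------------------
# LeafCutter


@dataclass
class LeafcutterRecord:
    chrom: str
    intron_start_raw: int
    intron_end_raw: int
    cluster_id: str
    strand: str
    dpsi: float
    fdr: float
    psi_ref: Optional[float] = None
    psi_alt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.intron_start_raw >= self.intron_end_raw:
            raise RowError(
                f"intron start {self.intron_start_raw} >= end {self.intron_end_raw}"
            )
        if not -1.0 - 1e-9 <= self.dpsi <= 1.0 + 1e-9:
            raise RowError(f"deltapsi {self.dpsi} outside [-1, 1]")


def _split_leafcutter_intron(key: str) -> tuple[str, int, int, str]:
    parts = key.split(":")
    if len(parts) != 4:
        raise RowError(f"cannot parse LeafCutter intron key {key!r}")
    chrom, start, end, cluster = parts
    try:
        return chrom, int(start), int(end), cluster
    except ValueError as exc:
        raise RowError(f"non-integer coordinates in intron key {key!r}") from exc


def _cluster_strand(cluster_id: str) -> str:
    if cluster_id.endswith(("_+", "_-")):
        return cluster_id[-1]
    return "."


def read_leafcutter(
    effect_sizes_file: str | os.PathLike,
    significance_file: str | os.PathLike,
) -> list[LeafcutterRecord]:
    """Join LeafCutter per-junction effect sizes to cluster significance.

    Junction rows inherit their cluster's BH-adjusted p; clusters whose
    status is not ``Success`` — and junctions whose cluster is absent from
    the significance table — are dropped with a logged count.
    """
    es = pd.read_csv(effect_sizes_file, sep="\t", dtype=str)
    sig = pd.read_csv(significance_file, sep="\t", dtype=str)
    for col in ("intron", "deltapsi"):
        if col not in es.columns:
            raise SchemaError(f"{effect_sizes_file}: missing column {col!r}")
    for col in ("cluster", "status", "p.adjust"):
        if col not in sig.columns:
            raise SchemaError(f"{significance_file}: missing column {col!r}")

    sig_by_cluster: dict[tuple[str, str], tuple[str, float]] = {}
    for _, row in sig.iterrows():
        parts = str(row["cluster"]).split(":")
        if len(parts) != 2:
            raise RowError(f"cannot parse cluster key {row['cluster']!r}")
        padj = float(row["p.adjust"]) if row["p.adjust"] not in ("NA", None) else math.nan
        sig_by_cluster[(parts[0], parts[1])] = (str(row["status"]), padj)

    # the two per-group Ψ columns, when present, sit between logef and deltapsi
    known = {"intron", "logef", "deltapsi"}
    psi_cols = [c for c in es.columns if c not in known]

    records: list[LeafcutterRecord] = []
    n_dropped = 0
    for _, row in es.iterrows():
        chrom, start, end, cluster = _split_leafcutter_intron(row["intron"])
        entry = sig_by_cluster.get((chrom, cluster))
        if entry is None or entry[0] != "Success" or math.isnan(entry[1]):
            n_dropped += 1
            continue
        psi_ref = psi_alt = None
        if len(psi_cols) >= 2:
            try:
                psi_ref = float(row[psi_cols[0]])
                psi_alt = float(row[psi_cols[1]])
            except (TypeError, ValueError):
                psi_ref = psi_alt = None
        records.append(
            LeafcutterRecord(
                chrom=chrom,
                intron_start_raw=start,
                intron_end_raw=end,
                cluster_id=cluster,
                strand=_cluster_strand(cluster),
                dpsi=float(row["deltapsi"]),
                fdr=entry[1],
                psi_ref=psi_ref,
                psi_alt=psi_alt,
            )
        )
    if n_dropped:
        log.info("read_leafcutter: dropped %d junction rows (cluster not Success)", n_dropped)
    return records


# ---------------------------------------------------------------------------
# MAJIQ / VOILA


@dataclass
class MajiqRecord:
    chrom: str
    strand: str
    junc_start_raw: int
    junc_end_raw: int
    lsv_id: str
    gene_id: str
    is_intron_retention: bool
    dpsi: float
    changing_prob: float
    psi_ref: Optional[float] = None
    psi_alt: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 - 1e-9 <= self.changing_prob <= 1.0 + 1e-9:
            raise RowError(f"changing probability {self.changing_prob} outside [0, 1]")
        if not -1.0 - 1e-9 <= self.dpsi <= 1.0 + 1e-9:
            raise RowError(f"dpsi {self.dpsi} outside [-1, 1]")


VOILA_COLUMNS = {
    "gene_id": "gene_id",
    "lsv_id": "lsv_id",
    "dpsi": "mean_dpsi_per_lsv_junction",
    "prob": "probability_changing",
    "psi_ref": "ref_mean_psi",
    "psi_alt": "alt_mean_psi",
    "junctions": "junctions_coords",
    "ir": "ir_coords",
    "chrom": "chr",
    "strand": "strand",
}


def _split_semicolon(text, cast=float) -> list:
    if text is None or (isinstance(text, float) and math.isnan(text)) or text == "":
        return []
    return [cast(v) for v in str(text).split(";")]


def read_majiq(voila_tsv: str | os.PathLike) -> list[MajiqRecord]:
    """Explode a VOILA deltapsi TSV into one record per LSV junction.

    Per-junction fields are semicolon-separated within each LSV row; a row
    whose per-junction fields disagree in length raises :class:`RowError`.
    The junction whose coordinates equal the ``ir_coords`` column is
    flagged as intron retention.
    """
    df = pd.read_csv(voila_tsv, sep="\t", dtype=str, comment="#")
    if df.empty and len(df.columns) <= 1:
        return []
    for col in VOILA_COLUMNS.values():
        if col not in df.columns:
            raise SchemaError(f"{voila_tsv}: missing column {col!r}")
    records: list[MajiqRecord] = []
    for i, row in df.iterrows():
        coords = _split_semicolon(row[VOILA_COLUMNS["junctions"]], str)
        dpsis = _split_semicolon(row[VOILA_COLUMNS["dpsi"]])
        probs = _split_semicolon(row[VOILA_COLUMNS["prob"]])
        refs = _split_semicolon(row[VOILA_COLUMNS["psi_ref"]])
        alts = _split_semicolon(row[VOILA_COLUMNS["psi_alt"]])
        lengths = {len(coords), len(dpsis), len(probs)}
        if len(lengths) != 1:
            raise RowError(f"{voila_tsv} row {i}: ragged per-junction field lengths")
        ir_raw = row[VOILA_COLUMNS["ir"]]
        ir_coord = None
        if isinstance(ir_raw, str) and ir_raw.strip():
            ir_coord = ir_raw.strip()
        for k, coord in enumerate(coords):
            lo, hi = coord.split("-")
            records.append(
                MajiqRecord(
                    chrom=str(row[VOILA_COLUMNS["chrom"]]),
                    strand=str(row[VOILA_COLUMNS["strand"]]),
                    junc_start_raw=int(lo),
                    junc_end_raw=int(hi),
                    lsv_id=str(row[VOILA_COLUMNS["lsv_id"]]),
                    gene_id=str(row[VOILA_COLUMNS["gene_id"]]),
                    is_intron_retention=(ir_coord == coord),
                    dpsi=dpsis[k],
                    changing_prob=probs[k],
                    psi_ref=refs[k] if len(refs) == len(coords) else None,
                    psi_alt=alts[k] if len(alts) == len(coords) else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Harmonized output


HARMONIZED_METHODS = ("rmats", "leafcutter", "majiq")

_HARMONIZED_BASE = [
    "gene", "chrom", "strand", "label", "event_type",
    "psi_ref", "psi_alt", "dpsi", "confidence",
]
_HARMONIZED_TAIL = ["n_methods", "annotated_flag", "zero_change"]


def harmonized_columns() -> list[str]:
    cols = list(_HARMONIZED_BASE)
    for m in HARMONIZED_METHODS:
        cols += [f"{m}_psi_ref", f"{m}_psi_alt", f"{m}_dpsi", f"{m}_confidence"]
    return cols + _HARMONIZED_TAIL


def _fmt(v: Optional[float]) -> str:
    return "" if v is None else f"{v:.6f}"


def write_harmonized(events: Iterable[SplicingEvent], path: str | os.PathLike) -> None:
    """Write the harmonized event table (fixed column order, TSV)."""
    rows = []
    for ev in sorted(events, key=lambda e: (e.chrom, e.label, e.family.value)):
        row: dict[str, object] = {
            "gene": ev.gene_id,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "label": ev.label,
            "event_type": ev.event_type.value,
            "psi_ref": _fmt(ev.psi_ref),
            "psi_alt": _fmt(ev.psi_alt),
            "dpsi": _fmt(ev.dpsi),
            "confidence": _fmt(ev.confidence),
            "n_methods": ev.n_methods,
            "annotated_flag": int(ev.annotated),
            "zero_change": int(ev.zero_change),
        }
        for m in HARMONIZED_METHODS:
            st = ev.method_stats.get(m)
            row[f"{m}_psi_ref"] = _fmt(st.psi_ref) if st else ""
            row[f"{m}_psi_alt"] = _fmt(st.psi_alt) if st else ""
            row[f"{m}_dpsi"] = _fmt(st.dpsi) if st else ""
            row[f"{m}_confidence"] = _fmt(st.confidence) if st else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=harmonized_columns())
    df.to_csv(path, sep="\t", index=False)


def read_harmonized(path: str | os.PathLike) -> list[SplicingEvent]:
    """Read a harmonized TSV back into :class:`SplicingEvent` objects."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    events = []
    for _, row in df.iterrows():
        etype = EventType(row["event_type"])
        method_stats = {}
        for m in HARMONIZED_METHODS:
            if row[f"{m}_dpsi"] != "":
                method_stats[m] = MethodStats(
                    dpsi=float(row[f"{m}_dpsi"]),
                    confidence=float(row[f"{m}_confidence"]),
                    psi_ref=float(row[f"{m}_psi_ref"]) if row[f"{m}_psi_ref"] != "" else None,
                    psi_alt=float(row[f"{m}_psi_alt"]) if row[f"{m}_psi_alt"] != "" else None,
                )
        events.append(
            SplicingEvent(
                label=row["label"],
                family=etype.family,
                event_type=etype,
                chrom=row["chrom"],
                strand=row["strand"],
                gene_id=row["gene"],
                annotated=bool(int(row["annotated_flag"])),
                zero_change=bool(int(row["zero_change"])),
                method_stats=method_stats,
                psi_ref=float(row["psi_ref"]) if row["psi_ref"] != "" else None,
                psi_alt=float(row["psi_alt"]) if row["psi_alt"] != "" else None,
                dpsi=float(row["dpsi"]),
                confidence=float(row["confidence"]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Truth table


def write_truth(
    truth: Sequence[TruthEvent],
    alt_fractions: Sequence[float],
    path: str | os.PathLike,
) -> None:
    """Write the ground-truth event table (TrueEvent-style CSV).

    One expected-ΔΨ column is emitted per alternative-transcript fraction,
    e.g. ``expected_dpsi_80`` for an 80:20 alt:control mix.
    """
    rows = []
    for ev in truth:
        row = {
            "gene_id": ev.gene_id,
            "event_type": ev.event_type.value,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "label": ev.label,
            "anchors": "|".join(str(a) for a in ev.anchors),
            "cryptic": int(ev.cryptic),
            "junctions": ";".join(
                f"{role.value}={s}-{e}" for role, (s, e) in sorted(
                    ev.junctions.items(), key=lambda kv: kv[0].value
                )
            ),
            "control_exons": "|".join(f"{s}-{e}" for s, e in ev.control_exons),
            "alt_exons": "|".join(f"{s}-{e}" for s, e in ev.alt_exons),
        }
        for f in alt_fractions:
            row[f"expected_dpsi_{int(round(100 * f))}"] = f"{ev.expected_dpsi(f):.6f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_chain(text: str) -> list[tuple[int, int]]:
    if not text:
        return []
    out = []
    for part in text.split("|"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def read_truth(path: str | os.PathLike) -> list[TruthEvent]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    truth = []
    for _, row in df.iterrows():
        junctions = {}
        if row["junctions"]:
            for part in row["junctions"].split(";"):
                role_name, interval = part.split("=")
                s, e = interval.split("-")
                junctions[Role(role_name)] = (int(s), int(e))
        truth.append(
            TruthEvent(
                gene_id=row["gene_id"],
                event_type=EventType(row["event_type"]),
                chrom=row["chrom"],
                strand=row["strand"],
                anchors=tuple(int(a) for a in row["anchors"].split("|")),
                cryptic=bool(int(row["cryptic"])),
                junctions=junctions,
                control_exons=_parse_chain(row.get("control_exons", "")),
                alt_exons=_parse_chain(row.get("alt_exons", "")),
            )
        )
    return truth
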