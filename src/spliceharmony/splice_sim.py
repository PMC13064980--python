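"""Splicing simulator with ground truth, and an emulator of tool outputs.

The simulator draws alternative-splicing events on a synthetic annotation:
each selected gene receives exactly one event (cassette exon in/out,
alternative 5'/3' splice site long/short, or intron retention in/out),
with a configurable fraction of cassette-inclusion events using cryptic
(unannotated) exons.  For every event a control and an alternative
transcript are defined; mixtures of the two at the configured
alt:control ratios, sequenced at the configured read depths, constitute
the study conditions.

The emulator is an honest stand-in for running rMATS, LeafCutter and
MAJIQ on those reads: it writes tables in each tool's own dialect, with
per-group Ψ estimates drawn from a Beta distribution whose concentration
grows with the supporting read depth, detection gated on expected
supporting reads, p-values from a two-proportion test on simulated
junction counts (BH-adjusted within each tool), and a posterior changing
probability for MAJIQ from a normal approximation.  It makes no claim
about the real tools' error profiles.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import (
    CapacityError,
    EventType,
    Family,
    GeometryError,
    ParameterError,
    Role,
    TruthEvent,
)
from .tool_io import AnnotationModel, RMATS_COORD_COLUMNS

# Default ground-truth composition: the simulated event-type distribution
# (128 events total, 23 of the cassette-inclusion events using cryptic exons).
DEFAULT_COMPOSITION: dict[EventType, int] = {
    EventType.ESIN: 69,
    EventType.ESOUT: 28,
    EventType.A5SS_LONG: 10,
    EventType.A5SS_SHORT: 5,
    EventType.A3SS_LONG: 2,
    EventType.A3SS_SHORT: 4,
    EventType.IRIN: 6,
    EventType.IROUT: 4,
}
DEFAULT_CRYPTIC_FRACTION = 23 / 128

DEFAULT_READ_LEVELS = (200, 500, 2000, 5000, 20000, 50000)
DEFAULT_RATIOS = ((100, 0), (80, 20), (50, 50), (20, 80))


@dataclass
class SimConfig:
    """Study-condition grid: read depths x alt:control mixing ratios."""

    reads_per_transcript: tuple[int, ...] = DEFAULT_READ_LEVELS
    ratios: tuple[tuple[int, int], ...] = DEFAULT_RATIOS
    n_replicates: int = 3
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for a, c in self.ratios:
            if a + c != 100:
                raise ParameterError(f"ratio {a}:{c} does not sum to 100")


@dataclass
class EmulatorNoise:
    """Noise model of the tool-output emulator.

    ``psi_concentration_per_read`` (c0) scales the Beta concentration
    κ = c0 × supporting reads (floored); ``None`` means noiseless
    (κ → ∞, Ψ̂ ≡ Ψ).  Detection requires the expected supporting reads to
    reach ``detection_min_reads``.  Coordinate jitter (default off)
    shifts emitted junction coordinates to model the few-bp alignment
    shifts seen between real tools.
    """

    psi_concentration_per_read: Optional[float] = 0.01
    concentration_floor: float = 2.0
    detection_min_reads: int = 10
    coordinate_jitter_prob: float = 0.0
    coordinate_jitter_mag: int = 0

    @classmethod
    def noiseless(cls) -> "EmulatorNoise":
        return cls(
            psi_concentration_per_read=None,
            detection_min_reads=0,
            coordinate_jitter_prob=0.0,
        )


# ---------------------------------------------------------------------------
# Toy genome


BASES = np.array(list("ACGT"))


def toy_genome(
    n_genes: int = 140,
    seed: int = 0,
    n_chroms: int = 4,
    exons_per_gene: tuple[int, int] = (5, 8),
    exon_length: tuple[int, int] = (120, 200),
    intron_length: tuple[int, int] = (250, 450),
    intergenic: int = 500,
) -> tuple[dict[str, str], AnnotationModel]:
    """Deterministic synthetic genome + annotation for simulation and tests.

    Genes are laid out back-to-back on ``n_chroms`` chromosomes with
    alternating strands; each gene has one annotated transcript containing
    all of its exons.
    """
    rng = np.random.default_rng(seed)
    model = AnnotationModel()
    chrom_len: dict[str, int] = {f"chr{i + 1}": 0 for i in range(n_chroms)}
    for gi in range(n_genes):
        chrom = f"chr{gi % n_chroms + 1}"
        strand = "+" if (gi // n_chroms) % 2 == 0 else "-"
        gene_id = f"G{gi + 1:04d}"
        tx_id = f"{gene_id}.t1"
        pos = chrom_len[chrom] + intergenic + 1
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        for _ in range(n_ex):
            elen = int(rng.integers(exon_length[0], exon_length[1] + 1))
            model.add_exon(gene_id, tx_id, chrom, strand, pos, pos + elen - 1)
            pos += elen + int(rng.integers(intron_length[0], intron_length[1] + 1))
        chrom_len[chrom] = pos
    model.finalize()
    genome = {
        chrom: "".join(rng.choice(BASES, size=length + intergenic))
        for chrom, length in chrom_len.items()
    }
    return genome, model


def write_genome_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="synthetic toy chromosome")
        for chrom, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gtf(model: AnnotationModel, path: str | os.PathLike) -> None:
    """Write an AnnotationModel back out as a 9-column GTF."""
    with open(path, "w") as fh:
        for gene in sorted(model.genes.values(), key=lambda g: (g.chrom, g.span)):
            lo, hi = gene.span
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\ttoy\tgene\t{lo}\t{hi}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for tx in sorted(gene.transcripts.values(), key=lambda t: t.tx_id):
                t_attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.tx_id}";'
                fh.write(
                    f"{gene.chrom}\ttoy\ttranscript\t{tx.exons[0][0]}\t{tx.exons[-1][1]}"
                    f"\t.\t{gene.strand}\t.\t{t_attrs}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{gene.chrom}\ttoy\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t{t_attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Truth events


def _intron(exons: list[tuple[int, int]], m: int) -> tuple[int, int]:
    return (exons[m][1] + 1, exons[m + 1][0] - 1)


def _build_event(
    event_type: EventType,
    gene_id: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    rng: np.random.Generator,
    cryptic: bool,
) -> TruthEvent:
    n = len(exons)
    family = event_type.family

    if family is Family.ES:
        if cryptic:
            # exonize a random unannotated interval inside an internal intron
            m = int(rng.integers(1, n - 2))
            intron = _intron(exons, m)
            ilen = intron[1] - intron[0] + 1
            elen = int(rng.integers(50, min(151, ilen - 40)))
            offset = int(rng.integers(20, ilen - elen - 20 + 1))
            cassette = (intron[0] + offset, intron[0] + offset + elen - 1)
            flank_left, flank_right = exons[m], exons[m + 1]
            control, alt = list(exons), sorted(exons + [cassette])
        else:
            k = int(rng.integers(1, n - 1))
            cassette = exons[k]
            flank_left, flank_right = exons[k - 1], exons[k + 1]
            without = [e for e in exons if e != cassette]
            if event_type is EventType.ESIN:
                control, alt = without, list(exons)
            else:
                control, alt = list(exons), without
        iu = (flank_left[1] + 1, cassette[0] - 1)
        idn = (cassette[1] + 1, flank_right[0] - 1)
        skip = (flank_left[1] + 1, flank_right[0] - 1)
        anchors = (skip[0] - 1, cassette[0], cassette[1], skip[1] + 1)
        junctions = {
            Role.INCLUSION_UPSTREAM: iu,
            Role.INCLUSION_DOWNSTREAM: idn,
            Role.SKIP: skip,
        }
        return TruthEvent(
            gene_id=gene_id, event_type=event_type, chrom=chrom, strand=strand,
            anchors=anchors, cryptic=cryptic, junctions=junctions,
            control_exons=control, alt_exons=alt,
        )

    if family in (Family.A5SS, Family.A3SS):
        m = int(rng.integers(1, n - 2))
        delta = int(rng.integers(30, 81))
        annotated_intron = _intron(exons, m)
        # which exon boundary moves: donor side for A5SS, acceptor for A3SS
        donor_side_left = strand == "+"  # donor exon is genomically left on '+'
        moves_left_exon = donor_side_left if family is Family.A5SS else not donor_side_left
        long_form = event_type in (EventType.A5SS_LONG, EventType.A3SS_LONG)
        ex = list(exons)
        if moves_left_exon:
            s, e = ex[m]
            new_end = e + delta if long_form else e - delta
            variant_exon = (s, new_end)
            variant_intron = (new_end + 1, ex[m + 1][0] - 1)
        else:
            s, e = ex[m + 1]
            new_start = s - delta if long_form else s + delta
            variant_exon = (new_start, e)
            variant_intron = (ex[m][1] + 1, new_start - 1)
        alt = list(exons)
        alt[m if moves_left_exon else m + 1] = variant_exon
        control = list(exons)
        if long_form:
            long_j, short_j = variant_intron, annotated_intron
        else:
            long_j, short_j = annotated_intron, variant_intron
        if moves_left_exon:
            shared = annotated_intron[1] + 1  # downstream exon start boundary
            anchors = tuple(sorted((long_j[0] - 1, short_j[0] - 1, shared)))
        else:
            shared = annotated_intron[0] - 1  # upstream exon end boundary
            anchors = tuple(sorted((shared, long_j[1] + 1, short_j[1] + 1)))
        junctions = {Role.LONG_VARIANT: long_j, Role.SHORT_VARIANT: short_j}
        return TruthEvent(
            gene_id=gene_id, event_type=event_type, chrom=chrom, strand=strand,
            anchors=anchors, cryptic=False, junctions=junctions,
            control_exons=control, alt_exons=alt,
        )

    if family is Family.IR:
        m = int(rng.integers(1, n - 2))
        intron = _intron(exons, m)
        merged = (exons[m][0], exons[m + 1][1])
        retained = [e for i, e in enumerate(exons) if i not in (m, m + 1)]
        retained = sorted(retained + [merged])
        if event_type is EventType.IRIN:
            control, alt = list(exons), retained
        else:
            control, alt = retained, list(exons)
        anchors = (intron[0] - 1, intron[1] + 1)
        return TruthEvent(
            gene_id=gene_id, event_type=event_type, chrom=chrom, strand=strand,
            anchors=anchors, cryptic=False,
            junctions={Role.RETENTION: intron},
            control_exons=control, alt_exons=alt,
        )

    raise GeometryError(f"unsupported event type {event_type}")


def generate_truth_events(
    annotation: AnnotationModel,
    composition: Optional[dict[EventType, int]] = None,
    cryptic_fraction: float = DEFAULT_CRYPTIC_FRACTION,
    seed: int = 0,
) -> list[TruthEvent]:
    """Draw one ground-truth event per selected gene, per the composition.

    Deterministic for a fixed seed.  Cryptic events (unannotated cassette
    exons) are assigned among the ESin events; raises
    :class:`CapacityError` when the annotation has fewer eligible genes
    than the composition requires, or fewer ESin slots than cryptic
    events.
    """
    composition = dict(DEFAULT_COMPOSITION if composition is None else composition)
    total = sum(composition.values())
    if total == 0:
        return []
    n_cryptic = int(round(cryptic_fraction * total))
    if n_cryptic > composition.get(EventType.ESIN, 0):
        raise CapacityError(
            f"{n_cryptic} cryptic events requested but only "
            f"{composition.get(EventType.ESIN, 0)} ESin slots"
        )
    rng = np.random.default_rng(seed)
    eligible = [
        g for g in sorted(annotation.genes.values(), key=lambda g: g.gene_id)
        if len(g.transcripts) == 1
        and len(next(iter(g.transcripts.values())).exons) >= 4
    ]
    if len(eligible) < total:
        raise CapacityError(
            f"annotation has {len(eligible)} eligible genes, need {total}"
        )
    order = rng.permutation(len(eligible))[:total]
    type_list: list[EventType] = []
    for etype in DEFAULT_COMPOSITION:  # fixed enum order for determinism
        type_list += [etype] * composition.get(etype, 0)
    rng.shuffle(type_list)  # which gene gets which type
    cryptic_slots = set(
        rng.choice(
            [i for i, t in enumerate(type_list) if t is EventType.ESIN],
            size=n_cryptic,
            replace=False,
        ).tolist()
        if n_cryptic
        else []
    )
    truth = []
    for i, (gene_pos, etype) in enumerate(zip(order, type_list)):
        gene = eligible[gene_pos]
        tx = next(iter(gene.transcripts.values()))
        truth.append(
            _build_event(
                etype, gene.gene_id, gene.chrom, gene.strand,
                list(tx.exons), rng, cryptic=i in cryptic_slots,
            )
        )
    truth.sort(key=lambda t: t.gene_id)
    return truth


def make_alternative_transcript(
    exons: Sequence[tuple[int, int]],
    event: TruthEvent,
) -> list[tuple[int, int]]:
    """Exon chain of the alternative transcript for one truth event.

    Validates that the event is anchored on the given (control) chain and
    returns the sorted, non-overlapping alternative chain.
    """
    if list(exons) != list(event.control_exons):
        raise GeometryError(
            f"event {event.label} is not anchored on the supplied exon chain"
        )
    alt = sorted(event.alt_exons)
    for (s1, e1), (s2, e2) in zip(alt, alt[1:]):
        if s2 <= e1:
            raise GeometryError(f"alternative chain overlaps at {s2} <= {e1}")
    return alt


def transcript_sequence(
    genome: dict[str, str], chrom: str, exons: Sequence[tuple[int, int]],
    strand: str,
) -> str:
    """Spliced transcript sequence (reverse-complemented on '-')."""
    seq = "".join(genome[chrom][s - 1:e] for s, e in sorted(exons))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def expected_coverage_and_dpsi(
    reads_per_transcript: int, ratio: tuple[int, int]
) -> tuple[float, float]:
    """Alternative-transcript coverage and expected |ΔΨ| for a condition.

    Coverage is reads x alternative-transcript percentage (e.g.
    5000 reads at 80:20 → 4000); the expected ΔΨ magnitude equals the
    alternative fraction because the control group is pure control
    transcript.
    """
    alt_pct, ctrl_pct = ratio
    if alt_pct + ctrl_pct != 100:
        raise ParameterError(f"ratio {ratio} does not sum to 100")
    alt_frac = alt_pct / 100.0
    return reads_per_transcript * alt_frac, alt_frac


def simulate_reads(
    sequence: str,
    count: int,
    read_length: int = 100,
    seed: int = 0,
    name_prefix: str = "read",
) -> list[SeqRecord]:
    """Error-free single-end reads, uniform start positions, fixed seed."""
    if count and len(sequence) < read_length:
        raise ParameterError(
            f"sequence length {len(sequence)} < read length {read_length}"
        )
    rng = np.random.default_rng(seed)
    records = []
    starts = rng.integers(0, len(sequence) - read_length + 1, size=count)
    for i, s in enumerate(starts):
        rec = SeqRecord(
            Seq(sequence[s:s + read_length]),
            id=f"{name_prefix}_{i}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [40] * read_length
        records.append(rec)
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    SeqIO.write(list(records), str(path), "fastq")


def simulate_condition_reads(
    genome: dict[str, str],
    truth: Sequence[TruthEvent],
    reads_per_transcript: int,
    ratio: tuple[int, int],
    n_replicates: int = 3,
    read_length: int = 100,
    seed: int = 0,
    outdir: str | os.PathLike = ".",
) -> list[Path]:
    """Write per-replicate FASTQ files for one coverage x ratio condition.

    The control group carries pure control transcripts; the treated group
    mixes alternative and control transcripts at the given ratio.
    """
    alt_frac = ratio[0] / 100.0
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for group, frac in (("ctrl", 0.0), ("alt", alt_frac)):
        for rep in range(1, n_replicates + 1):
            records: list[SeqRecord] = []
            for t_i, ev in enumerate(truth):
                ctrl_seq = transcript_sequence(genome, ev.chrom, ev.control_exons, ev.strand)
                alt_seq = transcript_sequence(genome, ev.chrom, ev.alt_exons, ev.strand)
                n_alt = int(round(reads_per_transcript * frac))
                rep_seed = (seed * 1000003 + t_i * 101 + rep * 7 + (group == "alt")) % (2**31)
                records += simulate_reads(
                    alt_seq, n_alt, read_length, rep_seed,
                    name_prefix=f"{ev.gene_id}_alt_{group}{rep}",
                )
                records += simulate_reads(
                    ctrl_seq, reads_per_transcript - n_alt, read_length, rep_seed + 1,
                    name_prefix=f"{ev.gene_id}_ctrl_{group}{rep}",
                )
            path = outdir / f"{group}_rep{rep}.fastq"
            write_fastq(records, path)
            paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Tool-output emulation


@dataclass
class _UnitJunction:
    role: Role
    start: int
    end: int
    inclusion_sign: int  # +1: junction Ψ follows event Ψ; −1: complement


@dataclass
class SimUnit:
    """One emission unit: a truth event or a non-changing background unit."""

    unit_id: str
    gene_id: str
    chrom: str
    strand: str
    kind: str  # truth | background_es | background_junction
    junctions: list[_UnitJunction]
    psi_ref_true: float
    psi_alt_true: float  # at alt fraction 1.0; scaled per condition
    rmats_kind: Optional[str] = None
    rmats_coords: dict[str, int] = field(default_factory=dict)
    truth: Optional[TruthEvent] = None

    def true_psis(self, alt_frac: float) -> tuple[float, float]:
        if self.kind != "truth":
            return self.psi_ref_true, self.psi_alt_true
        # treated group mixes alt and control transcripts
        psi_alt = self.psi_ref_true + alt_frac * (self.psi_alt_true - self.psi_ref_true)
        return self.psi_ref_true, psi_alt


def _truth_unit(ev: TruthEvent, index: int) -> SimUnit:
    positive = ev.event_type.positive
    psi_ref, psi_alt = (0.0, 1.0) if positive else (1.0, 0.0)
    family = ev.family
    juncs: list[_UnitJunction] = []
    rmats_kind = None
    coords: dict[str, int] = {}
    if family is Family.ES:
        iu = ev.junctions[Role.INCLUSION_UPSTREAM]
        idn = ev.junctions[Role.INCLUSION_DOWNSTREAM]
        skip = ev.junctions[Role.SKIP]
        juncs = [
            _UnitJunction(Role.INCLUSION_UPSTREAM, *iu, +1),
            _UnitJunction(Role.INCLUSION_DOWNSTREAM, *idn, +1),
            _UnitJunction(Role.SKIP, *skip, -1),
        ]
        rmats_kind = "SE"
        cassette = (ev.anchors[1], ev.anchors[2])
        exons = sorted(ev.alt_exons if ev.event_type is EventType.ESIN else ev.control_exons)
        ci = exons.index(cassette)
        up_exon, dn_exon = exons[ci - 1], exons[ci + 1]
        coords = {
            "exonStart_0base": cassette[0] - 1, "exonEnd": cassette[1],
            "upstreamES": up_exon[0] - 1, "upstreamEE": up_exon[1],
            "downstreamES": dn_exon[0] - 1, "downstreamEE": dn_exon[1],
        }
    elif family in (Family.A5SS, Family.A3SS):
        long_j = ev.junctions[Role.LONG_VARIANT]
        short_j = ev.junctions[Role.SHORT_VARIANT]
        juncs = [
            _UnitJunction(Role.LONG_VARIANT, *long_j, +1),
            _UnitJunction(Role.SHORT_VARIANT, *short_j, -1),
        ]
        rmats_kind = family.value
        # reconstruct the long/short/flanking exons from the two chains
        long_chain = ev.alt_exons if ev.event_type in (EventType.A5SS_LONG, EventType.A3SS_LONG) else ev.control_exons
        short_chain = ev.control_exons if long_chain is ev.alt_exons else ev.alt_exons
        long_exon = next(e for e in long_chain if e not in short_chain)
        short_exon = next(e for e in short_chain if e not in long_chain)
        if long_j[1] == short_j[1]:  # shared downstream exon start
            flank = next(e for e in long_chain if e[0] == long_j[1] + 1)
        else:  # shared upstream exon end
            flank = next(e for e in long_chain if e[1] == long_j[0] - 1)
        coords = {
            "longExonStart_0base": long_exon[0] - 1, "longExonEnd": long_exon[1],
            "shortES": short_exon[0] - 1, "shortEE": short_exon[1],
            "flankingES": flank[0] - 1, "flankingEE": flank[1],
        }
    elif family is Family.IR:
        intron = ev.junctions[Role.RETENTION]
        juncs = [_UnitJunction(Role.RETENTION, *intron, +1)]
        rmats_kind = "RI"
        spliced_chain = ev.control_exons if ev.event_type is EventType.IRIN else ev.alt_exons
        up_exon = next(e for e in spliced_chain if e[1] == intron[0] - 1)
        dn_exon = next(e for e in spliced_chain if e[0] == intron[1] + 1)
        coords = {
            "riExonStart_0base": up_exon[0] - 1, "riExonEnd": dn_exon[1],
            "upstreamES": up_exon[0] - 1, "upstreamEE": up_exon[1],
            "downstreamES": dn_exon[0] - 1, "downstreamEE": dn_exon[1],
        }
    return SimUnit(
        unit_id=f"T{index:04d}",
        gene_id=ev.gene_id,
        chrom=ev.chrom,
        strand=ev.strand,
        kind="truth",
        junctions=juncs,
        psi_ref_true=psi_ref,
        psi_alt_true=psi_alt,
        rmats_kind=rmats_kind,
        rmats_coords=coords,
        truth=ev,
    )


def background_units(
    annotation: AnnotationModel,
    truth: Sequence[TruthEvent],
    max_se_per_gene: int = 1,
    background_inclusion: float = 0.95,
) -> list[SimUnit]:
    """Non-changing units from the unused structure of selected genes.

    For each gene carrying a truth event, internal exons whose flanking
    introns do not touch the event become near-constitutive cassette
    units (inclusion ~0.95 in both groups, true ΔΨ = 0), giving every
    emulated tool honest negative rows; remaining constitutive introns
    are emitted as plain non-changing junctions.
    """
    truth_by_gene = {t.gene_id: t for t in truth}
    units: list[SimUnit] = []
    counter = 0
    for gene_id, ev in sorted(truth_by_gene.items()):
        gene = annotation.genes[gene_id]
        tx = next(iter(gene.transcripts.values()))
        exons = list(tx.exons)
        touched = set()
        for (s, e) in ev.junctions.values():
            touched |= {s - 1, e + 1}
        used_intervals = [(s, e) for (s, e) in ev.junctions.values()]
        n = len(exons)
        n_se = 0
        se_junctions: set[tuple[int, int]] = set()
        for k in range(1, n - 1):
            if n_se >= max_se_per_gene:
                break
            iu = (exons[k - 1][1] + 1, exons[k][0] - 1)
            idn = (exons[k][1] + 1, exons[k + 1][0] - 1)
            skip = (iu[0], idn[1])
            anchors = {iu[0] - 1, iu[1] + 1, idn[0] - 1, idn[1] + 1}
            if anchors & touched:
                continue
            if any(_overlaps(j, u) for j in (iu, idn, skip) for u in used_intervals):
                continue
            counter += 1
            units.append(
                SimUnit(
                    unit_id=f"B{counter:04d}",
                    gene_id=gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    kind="background_es",
                    junctions=[
                        _UnitJunction(Role.INCLUSION_UPSTREAM, *iu, +1),
                        _UnitJunction(Role.INCLUSION_DOWNSTREAM, *idn, +1),
                        _UnitJunction(Role.SKIP, *skip, -1),
                    ],
                    psi_ref_true=background_inclusion,
                    psi_alt_true=background_inclusion,
                    rmats_kind="SE",
                    rmats_coords={
                        "exonStart_0base": exons[k][0] - 1, "exonEnd": exons[k][1],
                        "upstreamES": exons[k - 1][0] - 1, "upstreamEE": exons[k - 1][1],
                        "downstreamES": exons[k + 1][0] - 1, "downstreamEE": exons[k + 1][1],
                    },
                )
            )
            se_junctions |= {iu, idn, skip}
            n_se += 1
        for intron in tx.introns:
            if any(_overlaps(intron, u) for u in used_intervals):
                continue
            if intron in se_junctions:
                continue
            counter += 1
            units.append(
                SimUnit(
                    unit_id=f"B{counter:04d}",
                    gene_id=gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    kind="background_junction",
                    junctions=[_UnitJunction(Role.PLAIN, *intron, +1)],
                    psi_ref_true=1.0,
                    psi_alt_true=1.0,
                )
            )
    return units


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


@dataclass
class EmulatedTables:
    """One condition's emulated tool outputs plus unit bookkeeping."""

    condition: tuple[int, tuple[int, int]]
    rmats: dict[str, pd.DataFrame]
    leafcutter_effect_sizes: pd.DataFrame
    leafcutter_significance: pd.DataFrame
    majiq: pd.DataFrame
    unit_index: pd.DataFrame

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        (outdir / "rmats").mkdir(parents=True, exist_ok=True)
        for kind, df in self.rmats.items():
            df.to_csv(outdir / "rmats" / f"{kind}.MATS.JC.txt", sep="\t", index=False)
        self.leafcutter_effect_sizes.to_csv(
            outdir / "leafcutter_effect_sizes.txt", sep="\t", index=False
        )
        self.leafcutter_significance.to_csv(
            outdir / "leafcutter_cluster_significance.txt", sep="\t", index=False
        )
        self.majiq.to_csv(outdir / "majiq_voila.tsv", sep="\t", index=False)
        self.unit_index.to_csv(outdir / "unit_index.tsv", sep="\t", index=False)


def _two_prop_p(k1: int, n1: int, k2: int, n2: int) -> float:
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.min() < 0 or table.sum(axis=1).min() <= 0:
        return 1.0
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    try:
        return float(sps.chi2_contingency(table)[1])
    except ValueError:
        return 1.0


def emulate_condition(
    units: Sequence[SimUnit],
    reads_per_transcript: int,
    ratio: tuple[int, int],
    noise: EmulatorNoise,
    n_replicates: int = 3,
    seed: int = 0,
) -> EmulatedTables:
    """Emulate the three tools' output tables for one study condition."""
    rng = np.random.default_rng(seed)
    alt_frac = ratio[0] / 100.0
    eps = 1e-4

    rows_rmats: dict[str, list[dict]] = {k: [] for k in RMATS_COORD_COLUMNS}
    rows_lc_es: list[dict] = []
    rows_lc_sig: list[dict] = []
    rows_majiq: list[dict] = []
    rows_index: list[dict] = []
    pvalues: list[float] = []
    detected_units: list[tuple[SimUnit, dict]] = []

    for unit in units:
        support = (
            reads_per_transcript * alt_frac
            if unit.kind == "truth"
            else float(reads_per_transcript)
        )
        psi_ref, psi_alt = unit.true_psis(alt_frac)
        if support < noise.detection_min_reads:
            continue
        c0 = noise.psi_concentration_per_read
        if c0 is None:
            ref_reps = np.full(n_replicates, psi_ref)
            alt_reps = np.full(n_replicates, psi_alt)
        else:
            kappa = max(c0 * support, noise.concentration_floor)
            draws = []
            for mean in (psi_ref, psi_alt):
                m = min(max(mean, eps), 1 - eps)
                draws.append(rng.beta(m * kappa, (1 - m) * kappa, size=n_replicates))
            ref_reps, alt_reps = draws
        ref_hat = float(np.mean(ref_reps))
        alt_hat = float(np.mean(alt_reps))
        dpsi_hat = alt_hat - ref_hat
        n_count = max(2, int(round(support)))
        p = _two_prop_p(
            int(round(ref_hat * n_count)), n_count,
            int(round(alt_hat * n_count)), n_count,
        )
        if c0 is None:
            se = 0.0
        else:
            kappa = max(c0 * support, noise.concentration_floor)
            var = sum(
                min(max(m, eps), 1 - eps) * (1 - min(max(m, eps), 1 - eps))
                / (kappa + 1) / n_replicates
                for m in (ref_hat, alt_hat)
            )
            se = math.sqrt(var)
        if se == 0.0:
            prob_changing = 1.0 if abs(dpsi_hat) > 0.2 else 0.0
        else:
            prob_changing = float(sps.norm.cdf((abs(dpsi_hat) - 0.2) / se))
        pvalues.append(p)
        detected_units.append(
            (unit, dict(
                ref_reps=ref_reps, alt_reps=alt_reps,
                ref_hat=ref_hat, alt_hat=alt_hat,
                dpsi_hat=dpsi_hat, p=p, prob=prob_changing,
            ))
        )

    fdrs = (
        multipletests(pvalues, method="fdr_bh")[1] if pvalues else np.array([])
    )

    def _maybe_jitter(s: int, e: int) -> tuple[int, int]:
        if noise.coordinate_jitter_prob <= 0 or noise.coordinate_jitter_mag <= 0:
            return s, e
        if rng.random() < noise.coordinate_jitter_prob:
            shift = int(rng.integers(1, noise.coordinate_jitter_mag + 1))
            shift *= -1 if rng.random() < 0.5 else 1
            return s + shift, e + shift
        return s, e

    for idx, ((unit, d), fdr) in enumerate(zip(detected_units, fdrs)):
        fdr = float(fdr)
        # --- rMATS
        if unit.rmats_kind is not None:
            row = {
                "ID": idx, "GeneID": f'"{unit.gene_id}"', "geneSymbol": f'"{unit.gene_id}"',
                "chr": unit.chrom, "strand": unit.strand,
            }
            row.update(unit.rmats_coords)
            row.update({
                "PValue": f"{d['p']:.6g}",
                "FDR": f"{fdr:.6g}",
                "IncLevel1": ",".join(f"{v:.4f}" for v in d["alt_reps"]),
                "IncLevel2": ",".join(f"{v:.4f}" for v in d["ref_reps"]),
                "IncLevelDifference": f"{d['dpsi_hat']:.4f}",
            })
            rows_rmats[unit.rmats_kind].append(row)
        # --- LeafCutter: per junction rows in one cluster per unit
        cluster = f"clu_{unit.unit_id}_{unit.strand if unit.strand in '+-' else 'NA'}"
        for uj in unit.junctions:
            s, e = _maybe_jitter(uj.start, uj.end)
            raw_s, raw_e = s - 1, e + 1  # regtools dialect
            jpsi_ref = d["ref_hat"] if uj.inclusion_sign > 0 else 1 - d["ref_hat"]
            jpsi_alt = d["alt_hat"] if uj.inclusion_sign > 0 else 1 - d["alt_hat"]
            rows_lc_es.append({
                "intron": f"{unit.chrom}:{raw_s}:{raw_e}:{cluster}",
                "logef": f"{0.0:.4f}",
                "ctrl": f"{jpsi_ref:.6f}",
                "case": f"{jpsi_alt:.6f}",
                "deltapsi": f"{jpsi_alt - jpsi_ref:.6f}",
            })
        rows_lc_sig.append({
            "cluster": f"{unit.chrom}:{cluster}",
            "status": "Success",
            "loglr": f"{1.0:.4f}",
            "df": 1,
            "p": f"{d['p']:.6g}",
            "p.adjust": f"{fdr:.6g}",
        })
        # --- MAJIQ / VOILA: one LSV per unit
        coords, dpsis, probs, refs, alts = [], [], [], [], []
        ir_coords = ""
        for uj in unit.junctions:
            s, e = _maybe_jitter(uj.start, uj.end)
            coord = f"{s}-{e}"
            coords.append(coord)
            sign = uj.inclusion_sign
            dpsis.append(f"{sign * d['dpsi_hat']:.6f}")
            probs.append(f"{d['prob']:.6f}")
            refs.append(f"{d['ref_hat'] if sign > 0 else 1 - d['ref_hat']:.6f}")
            alts.append(f"{d['alt_hat'] if sign > 0 else 1 - d['alt_hat']:.6f}")
            if uj.role is Role.RETENTION:
                ir_coords = coord
        rows_majiq.append({
            "gene_id": unit.gene_id,
            "lsv_id": f"{unit.gene_id}:{unit.unit_id}",
            "mean_dpsi_per_lsv_junction": ";".join(dpsis),
            "probability_changing": ";".join(probs),
            "ref_mean_psi": ";".join(refs),
            "alt_mean_psi": ";".join(alts),
            "junctions_coords": ";".join(coords),
            "ir_coords": ir_coords,
            "chr": unit.chrom,
            "strand": unit.strand,
        })
        rows_index.append({
            "unit_id": unit.unit_id,
            "kind": unit.kind,
            "gene_id": unit.gene_id,
            "true_dpsi": f"{(unit.true_psis(alt_frac)[1] - unit.true_psis(alt_frac)[0]):.6f}",
            "dpsi_hat": f"{d['dpsi_hat']:.6f}",
            "fdr": f"{fdr:.6g}",
        })

    rmats_frames = {}
    for kind, rows in rows_rmats.items():
        cols = (
            ["ID", "GeneID", "geneSymbol", "chr", "strand"]
            + RMATS_COORD_COLUMNS[kind]
            + ["PValue", "FDR", "IncLevel1", "IncLevel2", "IncLevelDifference"]
        )
        rmats_frames[kind] = pd.DataFrame(rows, columns=cols)
    lc_cols = ["intron", "logef", "ctrl", "case", "deltapsi"]
    sig_cols = ["cluster", "status", "loglr", "df", "p", "p.adjust"]
    mj_cols = list(rows_majiq[0].keys()) if rows_majiq else [
        "gene_id", "lsv_id", "mean_dpsi_per_lsv_junction", "probability_changing",
        "ref_mean_psi", "alt_mean_psi", "junctions_coords", "ir_coords", "chr", "strand",
    ]
    idx_cols = ["unit_id", "kind", "gene_id", "true_dpsi", "dpsi_hat", "fdr"]
    return EmulatedTables(
        condition=(reads_per_transcript, ratio),
        rmats=rmats_frames,
        leafcutter_effect_sizes=pd.DataFrame(rows_lc_es, columns=lc_cols),
        leafcutter_significance=pd.DataFrame(rows_lc_sig, columns=sig_cols),
        majiq=pd.DataFrame(rows_majiq, columns=mj_cols),
        unit_index=pd.DataFrame(rows_index, columns=idx_cols),
    )


def emulate_tool_outputs(
    truth: Sequence[TruthEvent],
    annotation: AnnotationModel,
    sim_config: SimConfig,
    noise: Optional[EmulatorNoise] = None,
    seed: int = 0,
) -> dict[tuple[int, tuple[int, int]], EmulatedTables]:
    """Emulated tool tables for every coverage x ratio condition."""
    noise = noise or EmulatorNoise()
    units = sim_units(truth, annotation)
    out = {}
    for ci, reads in enumerate(sim_config.reads_per_transcript):
        for ri, ratio in enumerate(sim_config.ratios):
            cond_seed = (seed * 131071 + ci * 251 + ri * 17) % (2**31)
            out[(reads, ratio)] = emulate_condition(
                units, reads, ratio, noise,
                n_replicates=sim_config.n_replicates,
                seed=cond_seed,
            )
    return out


def sim_units(
    truth: Sequence[TruthEvent], annotation: AnnotationModel
) -> list[SimUnit]:
    """Truth + background units in emission order (exposed for benchmarks)."""
    units = [_truth_unit(ev, i + 1) for i, ev in enumerate(truth)]
    units += background_units(annotation, truth)
    return units
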