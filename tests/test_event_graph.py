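"""Splice-graph decomposition, event typing and labeling.

The enumeration is checked against an independent brute-force oracle that
enumerates all anchor-sharing junction pairs and bridged triples directly
from the geometric definition.
"""

from __future__ import annotations

import numpy as np
import pytest

from spliceharmony import event_graph as eg
from spliceharmony import junction_space as js
from spliceharmony.model import Family, Junction, MethodStats, Role, Source
from spliceharmony.tool_io import RmatsRecord


def J(start, end, strand="+", role=Role.PLAIN, dpsi=0.1, conf=0.9,
      group="g1", source=Source.LEAFCUTTER, retention=False):
    return Junction(
        chrom="chr1", strand=strand, start=start, end=end, source=source,
        group_id=group, role=role, is_retention=retention,
        stats=MethodStats(dpsi=dpsi, confidence=conf),
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle


def brute_force_events(junctions) -> set[tuple[str, tuple[int, ...]]]:
    """All simplified events of a group, enumerated naively.

    ES: every triple (skip, left, right) with skip = (a, b), left = (a, x),
    right = (y, b), x < y - 1 (a non-empty exon fits between them).
    A5SS/A3SS: every remaining pair sharing exactly one coordinate, family
    by which side is shared and by strand.  IR: every retention junction.
    """
    coords = sorted({(j.start, j.end) for j in junctions})
    strand = junctions[0].strand
    out: set[tuple[str, tuple[int, ...]]] = set()
    in_es: set[frozenset] = set()
    for a, b in coords:
        for a1, x in coords:
            for y, b2 in coords:
                if a1 != a or b2 != b:
                    continue
                if (a1, x) == (a, b) or (y, b2) == (a, b):
                    continue
                if not (x < b and y > a and x + 1 <= y - 1):
                    continue
                out.add(("ES", (a - 1, x + 1, y - 1, b + 1)))
                in_es.add(frozenset({(a, b), (a1, x)}))
                in_es.add(frozenset({(a, b), (y, b2)}))
    for i, (s1, e1) in enumerate(coords):
        for s2, e2 in coords[i + 1:]:
            pair = frozenset({(s1, e1), (s2, e2)})
            if pair in in_es or strand not in "+-":
                continue
            if s1 == s2 and e1 != e2:
                family = "A3SS" if strand == "+" else "A5SS"
                out.add((family, (s1 - 1, min(e1, e2) + 1, max(e1, e2) + 1)))
            elif e1 == e2 and s1 != s2:
                family = "A5SS" if strand == "+" else "A3SS"
                out.add((family, (min(s1, s2) - 1, max(s1, s2) - 1, e1 + 1)))
    for j in junctions:
        if j.is_retention or j.role is Role.RETENTION:
            out.add(("IR", (j.start - 1, j.end + 1)))
    return out


def enumerated(junctions) -> set[tuple[str, tuple[int, ...]]]:
    g = eg.build_splice_graph(junctions)
    return {
        (ev.family.value, ev.anchors) for ev in eg.enumerate_event_graphs(g)
    }


def random_group(rng, strand="+", max_junctions=6):
    """Random junction group over a small anchor pool (collisions likely)."""
    n = int(rng.integers(1, max_junctions + 1))
    anchors = sorted(rng.choice(np.arange(100, 1000, 50), size=8, replace=False))
    juncs = []
    seen = set()
    for _ in range(n):
        s, e = sorted(rng.choice(anchors, size=2, replace=False))
        if (s + 1, e - 1) in seen or e - s < 2:
            continue
        seen.add((s + 1, e - 1))
        retention = rng.random() < 0.15
        juncs.append(J(s + 1, e - 1, strand=strand, retention=retention,
                       role=Role.RETENTION if retention else Role.PLAIN,
                       dpsi=float(rng.uniform(-1, 1))))
    return juncs


class TestBuildSpliceGraph:
    def test_nodes_and_edges(self):
        g = eg.build_splice_graph([J(201, 300), J(401, 500), J(201, 500)])
        assert set(g.nodes) == {200, 301, 400, 501}
        assert g.number_of_edges() == 3

    def test_duplicate_junctions_keep_higher_confidence(self):
        g = eg.build_splice_graph([J(201, 300, conf=0.9), J(201, 300, conf=0.5)])
        (junction,) = eg.graph_junctions(g)
        assert junction.stats.confidence == pytest.approx(0.9)

    def test_single_junction(self):
        g = eg.build_splice_graph([J(201, 300)])
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_dot_dump_contains_edges(self):
        dot = eg.splice_graph_dot(eg.build_splice_graph([J(201, 300)]))
        assert dot.startswith("graph splice") and "201-300" in dot


class TestEnumeration:
    def test_cassette_triple_gives_single_es(self):
        juncs = [J(201, 300), J(401, 500), J(201, 500)]
        events = enumerated(juncs)
        assert events == {("ES", (200, 301, 400, 501))}

    def test_shared_acceptor_pair_is_a5ss_on_plus(self):
        events = enumerated([J(201, 500), J(251, 500)])
        assert events == {("A5SS", (200, 250, 501))}

    def test_shared_donor_pair_is_a3ss_on_plus(self):
        events = enumerated([J(201, 500), J(201, 450)])
        assert events == {("A3SS", (200, 451, 501))}

    def test_retention_junction_gives_ir(self):
        events = enumerated([J(201, 300, retention=True, role=Role.RETENTION)])
        assert events == {("IR", (200, 301))}

    def test_unknown_strand_pairs_dropped(self):
        events = enumerated([J(201, 500, strand="?"), J(251, 500, strand="?")])
        assert events == set()

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_on_random_groups(self, strand):
        rng = np.random.default_rng(42 if strand == "+" else 43)
        for _ in range(200):
            juncs = random_group(rng, strand=strand)
            if not juncs:
                continue
            assert enumerated(juncs) == brute_force_events(juncs), [
                (j.start, j.end, j.is_retention) for j in juncs
            ]

    @staticmethod
    def _counts(evset):
        out = {"ES": 0, "A5SS": 0, "A3SS": 0, "IR": 0}
        for fam, _ in evset:
            out[fam] += 1
        return out

    def test_coordinate_mirror_swaps_a5ss_a3ss(self):
        """Mirroring coordinates about a point (same strand annotation)
        swaps A5SS and A3SS counts exactly and preserves ES/IR counts:
        the donor/acceptor distinction follows genomic orientation."""
        rng = np.random.default_rng(7)
        C = 2000
        for _ in range(100):
            juncs = random_group(rng, strand="+")
            if not juncs:
                continue
            mirrored = [
                J(C - j.end, C - j.start, strand="+",
                  retention=j.is_retention, role=j.role, dpsi=j.stats.dpsi)
                for j in juncs
            ]
            cf = self._counts(enumerated(juncs))
            cr = self._counts(enumerated(mirrored))
            assert cf["ES"] == cr["ES"] and cf["IR"] == cr["IR"]
            assert cf["A5SS"] == cr["A3SS"] and cf["A3SS"] == cr["A5SS"]

    def test_reverse_complement_preserves_families(self):
        """Mirroring coordinates AND flipping strand is a reverse-complement
        symmetry: every family count is invariant (a 5' splice-site choice
        stays a 5' choice in transcript orientation)."""
        rng = np.random.default_rng(8)
        C = 2000
        for _ in range(100):
            juncs = random_group(rng, strand="+")
            if not juncs:
                continue
            revcomp = [
                J(C - j.end, C - j.start, strand="-",
                  retention=j.is_retention, role=j.role, dpsi=j.stats.dpsi)
                for j in juncs
            ]
            assert self._counts(enumerated(juncs)) == self._counts(enumerated(revcomp))


class TestRmatsFidelity:
    """Exploding an rMATS record and re-deriving the event graph must
    recover the original event family and anchors."""

    def _roundtrip(self, rec: RmatsRecord):
        juncs = js.rmats_event_to_junctions(rec)
        g = eg.build_splice_graph(juncs)
        return eg.enumerate_event_graphs(g)

    def test_se(self):
        rec = RmatsRecord(
            event_kind="SE", event_id="SE:1", gene_id="G", chrom="chr1",
            strand="+",
            coords={
                "exonStart_0base": 300, "exonEnd": 400,
                "upstreamES": 100, "upstreamEE": 200,
                "downstreamES": 500, "downstreamEE": 600,
            },
            inc_level_ref=0.5, inc_level_alt=0.8,
            inc_level_difference=0.3, fdr=0.01,
        )
        (ev,) = self._roundtrip(rec)
        assert ev.family is Family.ES
        assert ev.anchors == (200, 301, 400, 501)

    @pytest.mark.parametrize("kind,expected_family", [
        ("A5SS", Family.A5SS), ("A3SS", Family.A3SS),
    ])
    def test_alt_splice_site(self, kind, expected_family):
        # '+' strand: long/short share their start, flanking exon downstream
        # (A5SS layout) or upstream (A3SS layout)
        if kind == "A5SS":
            coords = {
                "longExonStart_0base": 100, "longExonEnd": 250,
                "shortES": 100, "shortEE": 200,
                "flankingES": 500, "flankingEE": 600,
            }
        else:
            coords = {
                "longExonStart_0base": 450, "longExonEnd": 600,
                "shortES": 500, "shortEE": 600,
                "flankingES": 100, "flankingEE": 200,
            }
        rec = RmatsRecord(
            event_kind=kind, event_id=f"{kind}:1", gene_id="G", chrom="chr1",
            strand="+", coords=coords,
            inc_level_ref=0.5, inc_level_alt=0.7,
            inc_level_difference=0.2, fdr=0.1,
        )
        (ev,) = self._roundtrip(rec)
        assert ev.family is expected_family
        # the long-exon variant must sit on the alternative path
        assert ev.path_alt[0].role is Role.LONG_VARIANT

    def test_ri(self):
        rec = RmatsRecord(
            event_kind="RI", event_id="RI:1", gene_id="G", chrom="chr1",
            strand="+",
            coords={
                "riExonStart_0base": 100, "riExonEnd": 400,
                "upstreamES": 100, "upstreamEE": 200,
                "downstreamES": 300, "downstreamEE": 400,
            },
            inc_level_ref=0.1, inc_level_alt=0.35,
            inc_level_difference=0.25, fdr=0.05,
        )
        (ev,) = self._roundtrip(rec)
        assert ev.family is Family.IR
        assert ev.anchors == (200, 301)


class TestLabels:
    def test_es_label(self):
        juncs = [J(201, 300), J(401, 500), J(201, 500)]
        (ev,) = eg.enumerate_event_graphs(eg.build_splice_graph(juncs))
        assert eg.label_event(ev) == "chr1:200-301-400-501:+"

    def test_ir_label(self):
        juncs = [J(201, 300, retention=True, role=Role.RETENTION)]
        (ev,) = eg.enumerate_event_graphs(eg.build_splice_graph(juncs))
        assert eg.label_event(ev) == "chr1:200-301:+"

    def test_identical_events_from_two_tools_share_labels(self):
        lc = [J(201, 300, group="clu_1"), J(401, 500, group="clu_1"),
              J(201, 500, group="clu_1")]
        mj = [J(201, 300, group="lsv", source=Source.MAJIQ),
              J(401, 500, group="lsv", source=Source.MAJIQ),
              J(201, 500, group="lsv", source=Source.MAJIQ)]
        (e1,) = eg.enumerate_event_graphs(eg.build_splice_graph(lc))
        (e2,) = eg.enumerate_event_graphs(eg.build_splice_graph(mj))
        assert e1.label == e2.label
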