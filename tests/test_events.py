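"""Event classification, proximal/distal labelling, and PSI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spliceshift as ss
from spliceshift.events import SpliceEvent, acceptor_of, donor_of, event_support
from spliceshift.io import Annotation

from conftest import make_junctions


def empty_annotation():
    return Annotation(
        introns=pd.DataFrame(columns=["chrom", "intron_start", "intron_end",
                                      "strand", "gene_id"]),
        terminal_exons=pd.DataFrame(columns=["chrom", "start", "end", "strand",
                                             "gene_id", "transcript_id"]))


class TestBuildEvents:
    def test_a3ss_from_shared_donor(self):
        # two junctions sharing a donor on chr3 (+): acceptors 150 vs 309 nt
        # into the intron, the alternative 3'ss arrangement of the CTNNB1
        # 3'UTR event (hg19 acceptors chr3:41281150 / chr3:41281309)
        juncs = make_junctions([
            ("chr3", 41281000, 41281150, "+", 30),
            ("chr3", 41281000, 41281309, "+", 20),
        ])
        events = ss.build_events(juncs, empty_annotation(), 2)
        assert len(events) == 1
        ev = events[0]
        assert ev.as_type == "A3SS"
        assert (ev.proximal_3ss, ev.distal_3ss) == (41281150, 41281309)

    def test_cassette_exon_and_labels(self):
        juncs = make_junctions([
            ("chr1", 100, 200, "+", 10),
            ("chr1", 250, 400, "+", 10),
            ("chr1", 100, 400, "+", 5),
        ])
        events = ss.build_events(juncs, empty_annotation(), 2)
        ce = [e for e in events if e.as_type == "CE"]
        assert len(ce) == 1
        ev = ce[0]
        assert set(ev.inclusion_junctions) == {("chr1", 100, 200, "+"),
                                               ("chr1", 250, 400, "+")}
        assert ev.exclusion_junctions == (("chr1", 100, 400, "+"),)
        # cassette exon body is 201..249; its acceptor is proximal
        assert (ev.proximal_3ss, ev.distal_3ss) == (200, 400)

    def test_min_event_count_drops_weak_events(self):
        juncs = make_junctions([
            ("chr3", 100, 250, "+", 30),
            ("chr3", 100, 409, "+", 1),   # below c=2
        ])
        assert ss.build_events(juncs, empty_annotation(), 2) == []

    def test_zero_length_junction_rejected_with_warning(self, caplog):
        juncs = make_junctions([("chr1", 100, 100, "+", 10)])
        import logging
        with caplog.at_level(logging.WARNING, logger="spliceshift"):
            events = ss.build_events(juncs, empty_annotation(), 2)
        assert events == [] and "donor == acceptor" in caplog.text

    def test_multi_acceptor_split_against_most_used(self):
        juncs = make_junctions([
            ("chr5", 100, 200, "+", 50),   # most used
            ("chr5", 100, 300, "+", 10),
            ("chr5", 100, 400, "+", 10),
        ])
        events = ss.build_events(juncs, empty_annotation(), 2)
        assert len(events) == 2
        assert all(("chr5", 100, 200, "+") in
                   (e.inclusion_junctions + e.exclusion_junctions) for e in events)

    def test_synthetic_truth_table_classes_reproduced(self, small_cohort):
        spec, loci, tables, body, sheet, events = small_cohort
        built = {e.event_id for e in events}
        assert built == set(loci.truth["event_id"])
        by_type = pd.Series([e.as_type for e in events]).value_counts().to_dict()
        assert by_type == loci.truth["as_type"].value_counts().to_dict()

    def test_brute_force_pairing_oracle(self, small_cohort):
        """A3SS/ALE calls match brute-force enumeration of junction pairs
        sharing (chrom, strand, donor)."""
        spec, loci, tables, body, sheet, events = small_cohort
        pooled = ss.pool_junctions(tables)
        juncs = [(r.chrom, int(r.intron_start), int(r.intron_end), r.strand)
                 for r in pooled.itertuples(index=False)]
        shared_donor_pairs = set()
        for i, a in enumerate(juncs):
            for b in juncs[i + 1:]:
                if (a[0], a[3]) == (b[0], b[3]) and donor_of(a) == donor_of(b):
                    shared_donor_pairs.add(frozenset((a, b)))
        built_pairs = {
            frozenset(e.inclusion_junctions + e.exclusion_junctions)
            for e in events if e.as_type in ("A3SS", "ALE")}
        # every built acceptor-choice event is a shared-donor pair ...
        assert built_pairs <= shared_donor_pairs
        # ... and pairs not built are exactly those explained by CE skipping
        ce_donor_pairs = set()
        for e in events:
            if e.as_type != "CE":
                continue
            jx = e.exclusion_junctions[0]
            for j in e.inclusion_junctions:
                if donor_of(j) == donor_of(jx):
                    ce_donor_pairs.add(frozenset((j, jx)))
        mxe_pairs = set()
        for e in events:
            if e.as_type == "MXE":
                for side in range(2):
                    mxe_pairs.add(frozenset((e.inclusion_junctions[side],
                                             e.exclusion_junctions[side])))
        assert shared_donor_pairs - built_pairs <= ce_donor_pairs | mxe_pairs


class TestProximalDistal:
    def test_minus_strand_distal_has_smaller_coordinate(self):
        # minus-strand alternative 3'ss: acceptors chr11:85693047 and
        # chr11:85693032 with the donor downstream (the PICALM arrangement)
        ev = SpliceEvent(
            event_id="x", as_type="A3SS", gene="PICALM", chrom="chr11", strand="-",
            inclusion_junctions=(("chr11", 85693047, 85693200, "-"),),
            exclusion_junctions=(("chr11", 85693032, 85693200, "-"),))
        ev = ss.assign_proximal_distal(ev)
        assert (ev.proximal_3ss, ev.distal_3ss) == (85693047, 85693032)

    def test_plus_strand_distal_is_larger(self):
        ev = SpliceEvent(
            event_id="x", as_type="A3SS", gene="g", chrom="c", strand="+",
            inclusion_junctions=(("c", 100, 150, "+"),),
            exclusion_junctions=(("c", 100, 309, "+"),))
        ev = ss.assign_proximal_distal(ev)
        assert (ev.proximal_3ss, ev.distal_3ss) == (150, 309)

    @settings(max_examples=100, deadline=None)
    @given(donor=st.integers(1000, 5000), d1=st.integers(10, 400),
           gap=st.integers(1, 400))
    def test_labels_invariant_under_coordinate_mirroring(self, donor, d1, gap):
        """Reverse-complementing the locus (mirror coordinates, flip strand)
        leaves proximal/distal labels on the same physical sites."""
        a1, a2 = donor + d1, donor + d1 + gap
        fwd = SpliceEvent(
            event_id="f", as_type="A3SS", gene="g", chrom="c", strand="+",
            inclusion_junctions=(("c", donor, a1, "+"),),
            exclusion_junctions=(("c", donor, a2, "+"),))
        fwd = ss.assign_proximal_distal(fwd)
        M = 10_000  # mirror: pos -> M - pos
        rev = SpliceEvent(
            event_id="r", as_type="A3SS", gene="g", chrom="c", strand="-",
            inclusion_junctions=(("c", M - a1, M - donor, "-"),),
            exclusion_junctions=(("c", M - a2, M - donor, "-"),))
        rev = ss.assign_proximal_distal(rev)
        assert rev.proximal_3ss == M - fwd.proximal_3ss
        assert rev.distal_3ss == M - fwd.distal_3ss


class TestPsi:
    @staticmethod
    def _a3ss_event():
        return ss.assign_proximal_distal(SpliceEvent(
            event_id="e", as_type="A3SS", gene="g", chrom="c", strand="+",
            inclusion_junctions=(("c", 100, 150, "+"),),
            exclusion_junctions=(("c", 100, 309, "+"),)))

    def test_direct_ratio(self):
        ev = self._a3ss_event()
        tables = {"s1": make_junctions([("c", 100, 150, "+", 80),
                                        ("c", 100, 309, "+", 20)])}
        pt = ss.compute_psi([ev], tables, psi_min_total=10)
        assert pt.psi.loc["e", "s1"] == pytest.approx(80.0)

    def test_below_threshold_is_missing(self):
        ev = self._a3ss_event()
        tables = {"s1": make_junctions([("c", 100, 150, "+", 3),
                                        ("c", 100, 309, "+", 4)])}
        pt = ss.compute_psi([ev], tables, psi_min_total=10)
        assert np.isnan(pt.psi.loc["e", "s1"])
        assert pt.totals.loc["e", "s1"] == 7

    def test_ce_inclusion_averages_flanking_junctions(self):
        ev = ss.assign_proximal_distal(SpliceEvent(
            event_id="ce", as_type="CE", gene="g", chrom="c", strand="+",
            inclusion_junctions=(("c", 100, 200, "+"), ("c", 250, 400, "+")),
            exclusion_junctions=(("c", 100, 400, "+"),)))
        tables = {"s1": make_junctions([("c", 100, 200, "+", 60),
                                        ("c", 250, 400, "+", 80),
                                        ("c", 100, 400, "+", 30)])}
        pt = ss.compute_psi([ev], tables, psi_min_total=10)
        # I = round_half_up((60+80)/2) = 70 -> PSI = 70/(70+30)
        assert pt.psi.loc["ce", "s1"] == pytest.approx(70.0)

    def test_ir_body_scaled_by_read_length(self):
        intron = ("c", 101, 300, "+")  # length 200
        ev = SpliceEvent(event_id="ir", as_type="IR", gene="g", chrom="c",
                         strand="+", inclusion_junctions=(),
                         exclusion_junctions=(intron,), intron_length=200)
        tables = {"s1": make_junctions([(*intron, 10)])}
        body = {"s1": make_junctions([(*intron, 100)])}
        pt = ss.compute_psi([ev], tables, psi_min_total=10, jcn_seq_len=88,
                            body_tables=body)
        scaled_i = 100 * 88 / 200  # = 44
        assert pt.psi.loc["ir", "s1"] == pytest.approx(100 * scaled_i / (scaled_i + 10))

    def test_negative_counts_error(self):
        ev = self._a3ss_event()
        tables = {"s1": make_junctions([("c", 100, 150, "+", -1),
                                        ("c", 100, 309, "+", 5)])}
        with pytest.raises(ValueError, match="negative"):
            ss.compute_psi([ev], tables, psi_min_total=0)

    @settings(max_examples=100, deadline=None)
    @given(i=st.integers(0, 500), e=st.integers(0, 500))
    def test_complementarity_under_role_swap(self, i, e):
        ev = self._a3ss_event()
        swapped = SpliceEvent(
            event_id="e", as_type="A3SS", gene="g", chrom="c", strand="+",
            inclusion_junctions=ev.exclusion_junctions,
            exclusion_junctions=ev.inclusion_junctions)
        tables = {"s": make_junctions([("c", 100, 150, "+", i),
                                       ("c", 100, 309, "+", e)])}
        pt = ss.compute_psi([ev], tables, psi_min_total=1)
        ps = ss.compute_psi([swapped], tables, psi_min_total=1)
        a, b = pt.psi.iloc[0, 0], ps.psi.iloc[0, 0]
        if not np.isnan(a):
            assert a + b == pytest.approx(100.0)

    @settings(max_examples=100, deadline=None)
    @given(i=st.integers(0, 300), e1=st.integers(0, 300), extra=st.integers(1, 100))
    def test_monotonicity_in_exclusion_reads(self, i, e1, extra):
        ev = self._a3ss_event()
        def psi(e):
            tables = {"s": make_junctions([("c", 100, 150, "+", i),
                                           ("c", 100, 309, "+", e)])}
            return ss.compute_psi([ev], tables, psi_min_total=0).psi.iloc[0, 0]
        lo, hi = psi(e1 + extra), psi(e1)
        if not (np.isnan(lo) or np.isnan(hi)):
            assert lo <= hi + 1e-12
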