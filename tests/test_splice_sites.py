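"""3' splice-site extraction, classification, motifs, and switches."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spliceshift as ss
from spliceshift.splice_sites import _revcomp

from conftest import make_junctions


def make_genome(seq, chrom="chr1"):
    return {chrom: seq}


class TestExtract3ss:
    def test_plus_strand_direct_slice(self):
        # acceptor G of "...CAG" at position 22; 3 exonic nt follow
        seq = "A" * 17 + "TTCAG" + "GCCAAA"
        site = ss.extract_3ss(make_genome(seq), "chr1", 22, "+")
        assert site.seq23.endswith("CAGGCC")
        assert site.minus3_class == "CAG"

    def test_minus_strand_reverse_complement_round_trip(self):
        seq = "A" * 17 + "TTCAG" + "GCCAAA"
        fwd = ss.extract_3ss(make_genome(seq), "chr1", 22, "+")
        mirrored = _revcomp(seq)
        L = len(seq)
        # position p on + maps to L + 1 - p on the flipped genome
        rev = ss.extract_3ss(make_genome(mirrored), "chr1", L + 1 - 22, "-")
        assert rev.seq23 == fwd.seq23

    def test_tag_site_classified(self):
        seq = "C" * 17 + "GGTAG" + "ATGCCC"
        site = ss.extract_3ss(make_genome(seq), "chr1", 22, "+")
        assert site.minus3_class == "TAG"
        assert site.minus3_trinucleotide == "TAG"

    def test_window_off_end_errors(self):
        with pytest.raises(ValueError, match="off chromosome"):
            ss.extract_3ss(make_genome("ACGT" * 3), "chr1", 10, "+")

    def test_noncanonical_warns_not_fails(self, caplog):
        import logging
        seq = "A" * 30
        with caplog.at_level(logging.WARNING, logger="spliceshift"):
            site = ss.extract_3ss(make_genome(seq), "chr1", 22, "+")
        assert site.minus3_class == "other"
        assert "non-canonical" in caplog.text

    def test_synthetic_acceptors_are_canonical(self, small_cohort):
        spec, loci, tables, body, sheet, events = small_cohort
        for ev in events:
            if ev.as_type in ("CE", "A3SS", "ALE"):
                for pos in (ev.proximal_3ss, ev.distal_3ss):
                    site = ss.extract_3ss(loci.genome, ev.chrom, pos, ev.strand)
                    assert site.seq23[18:20] == "AG"

    def test_class_counts_invariant_under_mirroring(self, small_cohort):
        spec, loci, tables, body, sheet, events = small_cohort
        counts, mirrored_counts = [], []
        for ev in events[:40]:
            if ev.as_type not in ("CE", "A3SS", "ALE"):
                continue
            seq = loci.genome[ev.chrom]
            L = len(seq)
            flipped = {ev.chrom: _revcomp(seq)}
            other = "-" if ev.strand == "+" else "+"
            for pos in (ev.proximal_3ss, ev.distal_3ss):
                counts.append(ss.extract_3ss(loci.genome, ev.chrom, pos,
                                             ev.strand).minus3_class)
                mirrored_counts.append(ss.extract_3ss(flipped, ev.chrom, L + 1 - pos,
                                                      other).minus3_class)
        assert counts == mirrored_counts


class TestDirectionCalls:
    def test_sign_rules(self):
        df = pd.DataFrame({"event_id": ["a", "b", "c"], "as_type": ["CE", "A3SS", "CE"],
                           "delta_psi": [-25.0, 12.0, 0.0]})
        calls = ss.direction_calls(df)
        assert calls.set_index("event_id")["direction"].to_dict() == {
            "a": "skipping", "b": "inclusion"}

    def test_table1_distal_usage_fraction(self):
        t1 = ss.table1_fixture()
        assert int(t1["distal_usage"].sum()) == 19
        assert t1["distal_usage"].mean() == pytest.approx(19 / 30)


class TestSkippingBias:
    def test_nine_of_ten_exact_tail(self):
        calls = pd.DataFrame({"as_type": ["CE"] * 10,
                              "direction": ["skipping"] * 9 + ["inclusion"]})
        prop, p = ss.skipping_bias_test(calls, "CE")
        assert prop == pytest.approx(0.9)
        assert p == pytest.approx(2 * 11 / 1024)

    def test_balanced_p_one(self):
        calls = pd.DataFrame({"as_type": ["CE"] * 10,
                              "direction": ["skipping"] * 5 + ["inclusion"] * 5})
        _, p = ss.skipping_bias_test(calls, "CE")
        assert p == pytest.approx(1.0)

    def test_cohort_scale_proportions_give_small_p(self):
        # 69/100 skipped cassette exons and 75/100 distal 3'ss choices both
        # reject the symmetric null
        ce = pd.DataFrame({"as_type": ["CE"] * 100,
                           "direction": ["skipping"] * 69 + ["inclusion"] * 31})
        _, p_ce = ss.skipping_bias_test(ce, "CE")
        assert p_ce < 1e-3
        a3 = pd.DataFrame({"as_type": ["A3SS"] * 100,
                           "direction": ["skipping"] * 75 + ["inclusion"] * 25})
        _, p_a3 = ss.skipping_bias_test(a3, "A3SS")
        assert p_a3 < 1e-5

    def test_zero_calls_error(self):
        with pytest.raises(ValueError):
            ss.skipping_bias_test(pd.DataFrame({"as_type": [], "direction": []}), "CE")


class TestMotif:
    def test_identical_sequences_reach_corrected_maximum(self):
        motif = ss.build_motif(["ACGTACGTACGTACGTACGTACG"] * 10)
        e_n = 3 / (2 * math.log(2) * 10)
        np.testing.assert_allclose(motif.information, 2 - e_n)
        np.testing.assert_allclose(motif.freqs.sum(axis=1), 1.0)

    def test_fewer_than_min_returns_none(self):
        assert ss.build_motif(["A" * 23] * 9) is None

    def test_uniform_random_ic_near_zero(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 23)) for _ in range(4000)]
        motif = ss.build_motif(seqs)
        assert np.all(np.abs(motif.information) < 0.01)

    def test_mixed_lengths_error(self):
        with pytest.raises(ValueError, match="length"):
            ss.build_motif(["A" * 23] * 9 + ["A" * 22])


def _two_choice_setup(psi_a_prox, psi_b_prox, depth=200):
    """One annotated A3SS event with a TAG proximal and CAG distal site."""
    spec = ss.SimulationSpec(events_per_class={"A3SS": 1}, planted_fraction=1.0,
                             planted_orientation=1.0, seed=5)
    loci = ss.generate_genome_and_annotation(spec)
    ev = loci.events[0]
    pj, dj = ev.inclusion_junctions[0], ev.exclusion_junctions[0]
    def tables(psi_prox):
        i = int(round(depth * psi_prox / 100))
        return {"lib": make_junctions([(*pj, i), (*dj, depth - i)])}
    return loci, [ev], tables(psi_a_prox), tables(psi_b_prox)


class TestSwitches:
    def test_switch_called_with_direction_and_dpsi(self):
        loci, events, ta, tb = _two_choice_setup(60, 40)
        cfg = ss.RunConfig(psi_min_total=25)
        table, summary = ss.enumerate_switches(ta, tb, events, loci.genome, cfg)
        assert summary["switched_events"] == 1
        row = table.iloc[0]
        assert (row["from_class"], row["to_class"]) == ("TAG", "CAG")
        assert row["dpsi"] == pytest.approx(20.0)

    def test_below_threshold_no_switch(self):
        loci, events, ta, tb = _two_choice_setup(50, 46)
        cfg = ss.RunConfig(psi_min_total=25)
        table, summary = ss.enumerate_switches(ta, tb, events, loci.genome, cfg)
        assert summary["eligible_events"] == 1
        assert summary["switched_events"] == 0

    def test_low_coverage_ineligible(self):
        loci, events, ta, tb = _two_choice_setup(60, 40, depth=20)
        cfg = ss.RunConfig(psi_min_total=25)
        _, summary = ss.enumerate_switches(ta, tb, events, loci.genome, cfg)
        assert summary["eligible_events"] == 0

    def test_swapping_conditions_reverses_directions(self, small_cohort):
        spec, loci, tables, body, sheet, events = small_cohort
        mut = {s: tables[s] for s in sheet.samples_in("mutant")}
        ctl = {s: tables[s] for s in sheet.samples_in("control")}
        cfg = ss.RunConfig(psi_min_total=25)
        fwd, s_fwd = ss.enumerate_switches(ctl, mut, events, loci.genome, cfg)
        rev, s_rev = ss.enumerate_switches(mut, ctl, events, loci.genome, cfg)
        assert set(fwd.loc[fwd["switched"], "event_id"]) == \
            set(rev.loc[rev["switched"], "event_id"])
        merged = fwd[fwd["switched"]].merge(rev, on="event_id", suffixes=("_f", "_r"))
        assert (merged["from_class_f"] == merged["to_class_r"]).all()
        assert (merged["to_class_f"] == merged["from_class_r"]).all()

    def test_planted_orientation_recovered(self, small_cohort):
        spec, loci, tables, body, sheet, events = small_cohort
        mut = {s: tables[s] for s in sheet.samples_in("mutant")}
        ctl = {s: tables[s] for s in sheet.samples_in("control")}
        cfg = ss.RunConfig(psi_min_total=25)
        table, summary = ss.enumerate_switches(ctl, mut, events, loci.genome, cfg)
        bd = summary["by_direction"]
        t2c = bd.get(("TAG", "CAG"), 0)
        c2t = bd.get(("CAG", "TAG"), 0)
        n = t2c + c2t
        frac = t2c / n
        half_width = 1.96 * math.sqrt(frac * (1 - frac) / n)
        assert frac - half_width <= spec.planted_orientation <= frac + half_width


class TestSwitchDirectionFisher:
    def test_cohort_scale_counts_highly_significant(self):
        # 884/1065 vs 347/660 toward the CAG site
        p = ss.switch_direction_fisher((884, 181), (347, 313))
        assert p < 2.2e-16

    def test_identical_proportions_p_one(self):
        assert ss.switch_direction_fisher((10, 10), (10, 10)) == pytest.approx(1.0)

    def test_small_table_matches_brute_force(self):
        from test_differential import brute_force_fisher_p
        p = ss.switch_direction_fisher((3, 1), (1, 3))
        assert p == pytest.approx(brute_force_fisher_p([[3, 1], [1, 3]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ss.switch_direction_fisher((-1, 5), (2, 2))
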