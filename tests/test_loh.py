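import numpy as np
import pandas as pd
import pytest

import hybridloh as h
from hybridloh.errors import InputError, QualityError
from conftest import uniform_counts


class TestComputeRc:
    def test_uniform_het_depth_30_gives_rc_half(self, mini_genome):
        rc = h.compute_rc(uniform_counts(mini_genome, 30))
        assert np.allclose(rc["rc_W"], 0.5) and np.allclose(rc["rc_Y"], 0.5)

    def test_loh_region_gives_rc_one_and_zero(self, mini_genome):
        counts = uniform_counts(mini_genome, 30)
        region = (counts["chrom"] == "chrI") & counts["pos"].between(20_000, 40_000)
        counts.loc[region, "count_W"] = 30
        counts.loc[region, "count_Y"] = 0
        rc = h.compute_rc(counts)
        assert np.allclose(rc.loc[region, "rc_W"], 1.0)
        assert np.allclose(rc.loc[region, "rc_Y"], 0.0)

    def test_trisomy_gives_rc_one_and_half(self, full_genome):
        plan = h.EventPlan(events=[h.PlannedEvent("trisomy", target="W", chrom="chrII")])
        out, _ = h.apply_events(full_genome, plan, seed=0)
        rc = h.compute_rc(h.simulate_allele_counts(out, 40, exact=True))
        tri = rc[rc["chrom"] == "chrII"]
        # genome mean total is pulled slightly above 40 by the trisomic chromosome
        assert tri["rc_W"].mean() == pytest.approx(1.0, rel=0.05)
        assert tri["rc_Y"].mean() == pytest.approx(0.5, rel=0.05)

    def test_degenerate_inputs_rejected(self, mini_genome):
        counts = uniform_counts(mini_genome, 30)
        zero = counts.assign(count_W=0, count_Y=0)
        with pytest.raises(InputError):
            h.compute_rc(zero)
        with pytest.raises(InputError):
            h.compute_rc(counts.head(50))  # too few sites for stable normalization


class TestGenotypeStates:
    def test_noise_free_het_genome_is_one_segment_per_chromosome(self, mini_genome):
        rc = h.compute_rc(uniform_counts(mini_genome, 30))
        segments, flagged = h.call_genotype_states(rc)
        assert len(segments) == mini_genome.snps["chrom"].nunique()
        assert (segments["state"] == "het").all()
        assert len(flagged) == 0

    def test_planted_conversion_recovered_as_hom_segment(self, mini_genome):
        chrom_snps = mini_genome.chrom_snps("chrI").reset_index(drop=True)
        start, end = int(chrom_snps.loc[20, "pos"]), int(chrom_snps.loc[24, "pos"])
        plan = h.EventPlan(events=[h.PlannedEvent("conversion", target="W",
                                                  chrom="chrI", start=start, end=end)])
        out, _ = h.apply_events(mini_genome, plan, seed=0)
        rc = h.compute_rc(h.simulate_allele_counts(out, 30, exact=True))
        segments, _ = h.call_genotype_states(rc)
        hom = segments[segments["state"] == "hom_Y"]
        assert len(hom) == 1
        assert hom.iloc[0]["n_snps"] == 5
        assert hom.iloc[0]["start_pos"] == start and hom.iloc[0]["end_pos"] == end

    def test_single_aberrant_marker_flagged_not_segmented(self, mini_genome):
        counts = uniform_counts(mini_genome, 30)
        idx = counts.index[counts["chrom"] == "chrII"][30]
        counts.loc[idx, "count_W"] = 30
        counts.loc[idx, "count_Y"] = 0
        segments, flagged = h.call_genotype_states(h.compute_rc(counts))
        assert (segments["state"] == "het").all()
        assert len(flagged) == 1
        assert flagged.iloc[0]["state"] == "hom_W"
        assert flagged.iloc[0]["pos"] == counts.loc[idx, "pos"]

    def test_segments_partition_each_chromosome_with_alternating_states(self, mini_genome):
        plan = h.EventPlan(events=[h.PlannedEvent("conversion") for _ in range(4)])
        out, _ = h.apply_events(mini_genome, plan, seed=8)
        rc = h.compute_rc(h.simulate_allele_counts(out, 30, seed=9))
        segments, _ = h.call_genotype_states(rc)
        for _, grp in segments.groupby("chrom", observed=True):
            grp = grp.sort_values("start_idx")
            assert grp.iloc[0]["start_idx"] == 0
            assert (grp["start_idx"].to_numpy()[1:] ==
                    grp["end_idx"].to_numpy()[:-1] + 1).all()
            assert (grp["state"].to_numpy()[1:] != grp["state"].to_numpy()[:-1]).all()

    def test_unclassifiable_excess_raises_quality_error(self, mini_genome):
        counts = uniform_counts(mini_genome, 30)
        counts["count_W"] = 24  # fraction 0.8/0.2: outside every band
        counts["count_Y"] = 6
        with pytest.raises(QualityError) as exc:
            h.call_genotype_states(h.compute_rc(counts))
        assert exc.value.offending_sites is not None
        assert len(exc.value.offending_sites) > 0


class TestEventClassification:
    def _events(self, genome, plan, seed=0, **kw):
        out, ledger = h.apply_events(genome, plan, seed=seed)
        counts = h.simulate_allele_counts(out, 30, exact=True)
        events, _, _ = h.call_loh(counts, **kw)
        return events, ledger

    def test_terminal_tract_called_t_loh_with_recipient(self, mini_genome):
        cfg = mini_genome.config
        bp = cfg.centromeres["chrI"] + 20_000
        plan = h.EventPlan(events=[h.PlannedEvent("crossover", target="W",
                                                  chrom="chrI", start=bp)])
        events, _ = self._events(mini_genome, plan)
        assert len(events) == 1
        ev = events[0]
        assert ev.loh_type == "T-LOH" and ev.cls == "CO/BIR-candidate"
        assert ev.retained == "Y" and ev.recipient == "W"
        assert ev.touches_end and not ev.touches_start

    def test_interior_tract_called_i_loh_con(self, mini_genome):
        plan = h.EventPlan(events=[h.PlannedEvent("conversion", target="W",
                                                  chrom="chrII", start=100_000,
                                                  end=110_000)])
        events, _ = self._events(mini_genome, plan)
        assert len(events) == 1
        assert events[0].loh_type == "I-LOH" and events[0].cls == "CON"
        assert events[0].complexity == "simple"

    def test_conversion_near_crossover_merges_to_co_con(self, mini_genome):
        cfg = mini_genome.config
        bp = cfg.centromeres["chrI"] + 30_000
        plan = h.EventPlan(min_separation=0, events=[
            h.PlannedEvent("crossover", target="W", chrom="chrI", start=bp),
            h.PlannedEvent("conversion", target="W", chrom="chrI",
                           start=bp - 8_000, end=bp - 4_000),
        ])
        events, _ = self._events(mini_genome, plan)
        assert len(events) == 1
        ev = events[0]
        assert ev.loh_type == "T-LOH" and ev.cls == "CO/CON"
        assert ev.complexity == "complex"

    def test_two_distant_interior_tracts_stay_separate_con_events(self, mini_genome):
        plan = h.EventPlan(min_separation=0, events=[
            h.PlannedEvent("conversion", target="W", chrom="chrII",
                           start=60_000, end=66_000),
            h.PlannedEvent("conversion", target="W", chrom="chrII",
                           start=200_000, end=206_000),
        ])
        events, _ = self._events(mini_genome, plan)
        assert [e.cls for e in events] == ["CON", "CON"]

    def test_close_interior_tracts_merge_to_complex_con_con(self, mini_genome):
        plan = h.EventPlan(min_separation=0, events=[
            h.PlannedEvent("conversion", target="W", chrom="chrII",
                           start=100_000, end=104_000),
            h.PlannedEvent("conversion", target="W", chrom="chrII",
                           start=108_000, end=112_000),
        ])
        events, _ = self._events(mini_genome, plan)
        assert len(events) == 1
        assert events[0].cls == "CON/CON" and events[0].complexity == "complex"


class TestBreakpoints:
    def test_interval_brackets_between_flanking_markers(self):
        bp = h.breakpoint_interval(100_000, 101_000)
        assert (bp.lo, bp.hi) == (100_000, 101_000)
        assert bp.midpoint == 100_500
        assert not bp.clipped

    def test_tract_at_first_marker_clipped_and_flagged(self):
        bp = h.breakpoint_interval(None, 5_000)
        assert bp.clipped and bp.lo == 1 and bp.hi == 5_000

    def test_planted_breakpoints_always_inside_reported_intervals(self, full_genome):
        """Containment of the planted lesion coordinate over many simulated events."""
        rng = np.random.default_rng(0)
        n_checked = 0
        for rep in range(5):
            plan = h.EventPlan(events=[h.PlannedEvent("conversion", target="W")
                                       for _ in range(20)]
                               + [h.PlannedEvent("crossover", target="W")
                                  for _ in range(5)])
            out, ledger = h.apply_events(full_genome, plan, seed=100 + rep)
            counts = h.simulate_allele_counts(out, 30, exact=True)
            events, _, _ = h.call_loh(counts)
            for _, row in ledger.iterrows():
                planted = int(row["breakpoint"])
                match = [e for e in events
                         if e.chrom == row["chrom"]
                         and e.start_pos <= int(row["end"]) and e.end_pos >= int(row["start"])]
                assert match, f"planted event on {row['chrom']} not recovered"
                ev = match[0]
                assert any(b.lo < planted <= b.hi or b.clipped for b in ev.breakpoints)
                n_checked += 1
        assert n_checked >= 100


class TestCompareEventSets:
    def _simple_events(self, genome, seeds):
        plan = h.EventPlan(events=[h.PlannedEvent("conversion", target="W")
                                   for _ in range(6)])
        out, _ = h.apply_events(genome, plan, seed=seeds)
        counts = h.simulate_allele_counts(out, 30, exact=True)
        events, _, _ = h.call_loh(counts)
        return events

    def test_identical_sets_fully_shared(self, mini_genome):
        events = self._simple_events(mini_genome, 1)
        res = h.compare_event_sets(events, list(events))
        assert res["n_shared"] == len(events)
        assert res["n_a_only"] == res["n_b_only"] == 0

    def test_extra_event_in_b_reported_private(self, mini_genome):
        events = self._simple_events(mini_genome, 1)
        extra_plan = h.EventPlan(events=[h.PlannedEvent(
            "crossover", target="W", chrom="chrIII",
            start=mini_genome.config.centromeres["chrIII"] + 10_000)])
        out, _ = h.apply_events(mini_genome, extra_plan, seed=2)
        counts = h.simulate_allele_counts(out, 30, exact=True)
        extra, _, _ = h.call_loh(counts)
        res = h.compare_event_sets(events, list(events) + extra)
        assert res["n_shared"] == len(events)
        assert res["n_b_only"] == 1
        assert res["b_only"][0].loh_type == "T-LOH"

    def test_disjoint_sets_share_nothing(self, mini_genome):
        a = self._simple_events(mini_genome, 1)
        b = self._simple_events(mini_genome, 99)
        res = h.compare_event_sets(a, b, tolerance=1)
        assert res["n_shared"] == 0


def test_probe_ratio_input_calls_same_event(mini_genome):
    """Array mode: centered probe ratios converted to the RC scale recover a
    planted conversion just like read counts do."""
    plan = h.EventPlan(events=[h.PlannedEvent("conversion", target="W",
                                              chrom="chrII", start=100_000,
                                              end=110_000)])
    out, _ = h.apply_events(mini_genome, plan, seed=0)
    probes = h.simulate_microarray_ratios(out, noise_sd=0.1, seed=1)
    rc = h.rc_from_probes(probes)
    segments, flagged = h.call_genotype_states(rc)
    events = h.segment_to_events(segments, flagged=flagged)
    assert len(events) == 1
    assert events[0].loh_type == "I-LOH" and events[0].cls == "CON"
    assert events[0].chrom == "chrII" and events[0].retained == "Y"


class TestNoiseProperties:
    def test_recipient_haplotype_recovered_when_all_lesions_on_w(self, full_genome):
        """With every lesion planted on W at depth 30, called simple conversions
        overwhelmingly name W as recipient."""
        plan = h.EventPlan(events=[h.PlannedEvent("conversion", target="W")
                                   for _ in range(40)])
        out, _ = h.apply_events(full_genome, plan, seed=21)
        counts = h.simulate_allele_counts(out, 30, seed=22)
        events, _, _ = h.call_loh(counts)
        cons = [e for e in events if e.cls == "CON"]
        assert len(cons) >= 20
        frac_w = np.mean([e.recipient == "W" for e in cons])
        assert frac_w >= 0.95

    def test_event_free_genomes_yield_almost_no_false_positives(self, mini_genome):
        """Binomial noise at depth 30 on event-free genomes: <1 false event
        per 10 genomes with the default minimum run of 2."""
        total_fp = 0
        for seed in range(10):
            counts = h.simulate_allele_counts(mini_genome, 30, seed=1000 + seed)
            events, _, _ = h.call_loh(counts)
            total_fp += len(events)
        assert total_fp <= 1
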