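import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import hybridloh as h
from hybridloh.errors import InputError, ParameterError


class TestRatesArithmetic:
    def test_colony_scale_loh_rate(self):
        # 120 events over 12 zygote colonies of 25 divisions each
        assert h.event_rate(120, 12, 25) == pytest.approx(0.4)

    def test_zero_events_zero_rate(self):
        assert h.event_rate(0, 12, 25) == 0.0

    def test_upd_rate(self):
        assert h.event_rate(4, 12, 25) == pytest.approx(1.3333e-2, rel=1e-3)

    def test_rate_scales_linearly_in_events(self):
        assert h.event_rate(240, 12, 25) == pytest.approx(2 * h.event_rate(120, 12, 25))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            h.event_rate(10, 0, 25)
        with pytest.raises(ParameterError):
            h.event_rate(-1, 12, 25)

    def test_fold_change_rounds_to_87(self):
        fold = h.fold_change(h.event_rate(120, 12, 25), 4.6e-3)
        assert fold.raw == pytest.approx(86.96, abs=0.01)
        assert fold.rounded == 87

    def test_first_division_assumption_exceeds_2100_fold(self):
        fold = h.fold_change(h.event_rate(120, 12, 1), 4.6e-3)
        assert fold.raw >= 2100

    def test_fold_of_baseline_is_one(self):
        assert h.fold_change(4.6e-3, 4.6e-3).raw == 1.0

    def test_dsb_extrapolation(self):
        assert h.dsb_extrapolation(10, 20) == 200
        assert h.dsb_extrapolation(0, 20) == 0
        assert h.dsb_extrapolation(3, 20) == 60

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(0, 10_000), k=st.integers(1, 20),
           isolates=st.integers(1, 100), divisions=st.integers(1, 100))
    def test_rate_scale_identity_property(self, n, k, isolates, divisions):
        """rate(kn) = k rate(n) and fold(r, r) = 1 for any admissible inputs."""
        r = h.event_rate(n, isolates, divisions)
        assert h.event_rate(k * n, isolates, divisions) == pytest.approx(k * r)
        if r > 0:
            assert h.fold_change(r, r).raw == pytest.approx(1.0)


class TestLocusExpectation:
    def test_five_percent_of_33_events_is_about_two(self):
        res = h.locus_loh_expectation(33, 0.05, observed=3)
        assert res["expected"] == pytest.approx(1.65)
        assert res["expected_rounded"] == 2
        assert res["p_chi2"] > 0.05  # insignificant departure

    def test_zero_fraction_zero_expectation(self):
        assert h.locus_loh_expectation(33, 0.0)["expected"] == 0.0

    def test_observed_equal_expected_p_one(self):
        res = h.locus_loh_expectation(40, 0.5, observed=20)
        assert res["p_chi2"] == pytest.approx(1.0)


class TestViabilityFisher:
    def test_paper_scale_table_matches_enumeration_oracle(self):
        res = h.viability_fisher([[5, 95], [7, 93]])
        assert res["p"] == pytest.approx(_fisher_enumeration(5, 95, 7, 93), rel=1e-9)

    def test_identical_rows_p_one(self):
        assert h.viability_fisher([[10, 90], [10, 90]])["p"] == 1.0

    def test_extreme_table_near_minimum(self):
        res = h.viability_fisher([[0, 100], [100, 0]])
        assert res["p"] < 1e-50

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            h.viability_fisher([[0, 0], [5, 5]])


def _fisher_enumeration(a, b, c, d):
    """Independent two-sided Fisher p: exhaustive hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's (with the usual
    relative-epsilon guard against ties lost to floating point).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestFisherAgainstEnumeration:
    def test_exhaustive_small_tables(self):
        """scipy's two-sided Fisher agrees with the enumeration oracle on
        every 2x2 table with total up to 16 and positive margins."""
        total_checked = 0
        for n in range(2, 17):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        res = h.viability_fisher([[a, b], [c, d]])
                        oracle = _fisher_enumeration(a, b, c, d)
                        assert res["p"] == pytest.approx(oracle, rel=1e-8, abs=1e-12)
                        total_checked += 1
        assert total_checked > 2000

    def test_random_tables_up_to_total_200(self):
        rng = np.random.default_rng(3)
        for _ in range(150):
            n = int(rng.integers(4, 201))
            cuts = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            res = h.viability_fisher([[a, b], [c, d]])
            oracle = _fisher_enumeration(a, b, c, d)
            assert res["p"] == pytest.approx(oracle, rel=1e-8, abs=1e-12)


class TestEnrichment:
    def _setup(self, seed, n_bp=120, planted_cls=None):
        cfg = h.HybridGenomeConfig(seed=0)
        ann = h.random_element_annotation(cfg, seed=99)
        rng = np.random.default_rng(seed)
        names = cfg.chromosomes
        lens = np.array([cfg.chromosome_lengths[c] for c in names], dtype=float)
        if planted_cls is None:
            ci = rng.choice(len(names), size=n_bp, p=lens / lens.sum())
            bps = pd.DataFrame({
                "chrom": [names[i] for i in ci],
                "pos": [int(rng.integers(1, cfg.chromosome_lengths[names[i]] + 1))
                        for i in ci]})
        else:
            cls_rows = ann[ann["cls"] == planted_cls]
            picks = cls_rows.sample(n=n_bp, replace=True, random_state=seed)
            bps = pd.DataFrame({"chrom": picks["chrom"].to_numpy(),
                                "pos": ((picks["start"] + picks["end"]) // 2).to_numpy()})
        return cfg, ann, bps

    def test_uniform_breakpoints_not_significant_after_correction(self):
        cfg, ann, bps = self._setup(seed=1)
        res = h.element_enrichment(bps, ann, cfg.chromosome_lengths)
        assert res["significant"].sum() == 0

    def test_ty_planted_breakpoints_enrich_ty_class(self):
        cfg, ann, bps = self._setup(seed=2, planted_cls="Ty")
        res = h.element_enrichment(bps, ann, cfg.chromosome_lengths)
        top = res.iloc[0]
        assert top["cls"] == "Ty" and top["significant"]

    def test_zero_footprint_class_skipped_with_warning(self):
        cfg, ann, bps = self._setup(seed=3)
        # a class whose only interval sits on a chromosome absent from the
        # genome contributes no footprint
        ann = pd.concat([ann, pd.DataFrame({"chrom": ["chrZZ"], "start": [1],
                                            "end": [100], "cls": ["ghost"]})],
                        ignore_index=True)
        with pytest.warns(UserWarning, match="ghost"):
            res = h.element_enrichment(bps, ann, cfg.chromosome_lengths)
        assert "ghost" not in set(res["cls"])

    def test_permutation_p_agrees_with_fisher_direction(self):
        cfg, ann, bps = self._setup(seed=4, planted_cls="Ty", n_bp=60)
        res = h.element_enrichment(bps, ann, cfg.chromosome_lengths,
                                   n_permutations=200, seed=5)
        top = res.iloc[0]
        assert top["cls"] == "Ty"
        assert top["p_perm"] <= 1 / 100

    def test_permutation_p_uniform_under_null(self):
        """Kolmogorov-Smirnov uniformity of permutation p-values across null
        simulations (single large-footprint class, many breakpoints, so the
        discrete permutation distribution has many support points)."""
        cfg = h.HybridGenomeConfig.miniature(n_chroms=2, scale=0.5, seed=0)
        rng = np.random.default_rng(11)
        ann = pd.DataFrame({"chrom": ["chrI", "chrII"], "start": [1, 1],
                            "end": [40_000, 60_000], "cls": ["blob", "blob"]})
        pvals = []
        names = cfg.chromosomes
        lens = np.array([cfg.chromosome_lengths[c] for c in names], dtype=float)
        for _ in range(150):
            ci = rng.choice(len(names), size=300, p=lens / lens.sum())
            bps = pd.DataFrame({
                "chrom": [names[i] for i in ci],
                "pos": (rng.random(300) * lens[ci]).astype(int) + 1})
            res = h.element_enrichment(bps, ann, cfg.chromosome_lengths,
                                       tolerance=0, n_permutations=99,
                                       seed=int(rng.integers(2**31)))
            pvals.append(res.iloc[0]["p_perm"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_breakpoints_rejected(self):
        cfg, ann, _ = self._setup(seed=6)
        with pytest.raises(InputError):
            h.element_enrichment(pd.DataFrame(columns=["chrom", "pos"]), ann,
                                 cfg.chromosome_lengths)


def _tandem_oracle(seq, min_region=24, unit_range=(1, 1998), min_units=2):
    """Brute-force tandem-repeat scan: direct character comparison for every
    start position and unit size, keeping maximal regions."""
    L = len(seq)
    regions = []
    for k in range(unit_range[0], min(unit_range[1], L // min_units) + 1):
        i = 0
        while i + k <= L:
            j = i
            while j + k < L and seq[j] == seq[j + k]:
                j += 1
            span = (j - i) + k if j > i else 0
            if j > i and span >= min_region and span >= min_units * k:
                regions.append((i + 1, i + span, k))
                i = j
            else:
                i += 1
    keep = []
    for start, end, k in sorted(regions, key=lambda r: (r[2], r[0])):
        if not any(s <= start and end <= e for s, e, kk in keep if kk < k):
            keep.append((start, end, k))
    return sorted(keep)


class TestTandemRepeats:
    def test_24bp_dinucleotide_run_detected(self):
        df = h.find_tandem_repeats("AG" * 12)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row["start"], row["end"], row["unit"]) == (1, 24, "AG")

    def test_22bp_run_below_minimum_not_reported(self):
        assert len(h.find_tandem_repeats("AG" * 11)) == 0

    def test_embedded_run_coordinates(self):
        seq = "T" * 30 + "CATG" * 8 + "A" * 30
        df = h.find_tandem_repeats(seq)
        units = set(df["unit"])
        assert "T" in units and "CATG" in units and "A" in units
        catg = df[df["unit"] == "CATG"].iloc[0]
        assert catg["start"] == 31 and catg["end"] == 62

    def test_random_sequence_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        # plant a few runs to make the comparison non-trivial
        seq = seq[:200] + "TA" * 15 + seq[230:600] + "GGC" * 10 + seq[630:]
        ours = h.find_tandem_repeats(seq, min_region=12)
        oracle = _tandem_oracle(seq, min_region=12)
        got = sorted(zip(ours["start"], ours["end"], ours["unit_size"]))
        assert got == oracle

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            h.find_tandem_repeats("")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=10, max_size=80),
           run=st.sampled_from(["A" * 14, "AG" * 7, "CAT" * 5]),
           cut=st.integers(0, 10))
    def test_property_agrees_with_brute_force(self, seq, run, cut):
        """Scanner and brute-force oracle agree on arbitrary sequences with
        an embedded run."""
        cut = min(cut, len(seq))
        composite = seq[:cut] + run + seq[cut:]
        ours = h.find_tandem_repeats(composite, min_region=10)
        got = sorted(zip(ours["start"], ours["end"], ours["unit_size"]))
        assert got == _tandem_oracle(composite, min_region=10)
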