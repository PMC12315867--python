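"""Concordance, F1, checkpoint selection, MIE, calibration, QC, PopVCF."""

from __future__ import annotations

import random
from dataclasses import replace

import numpy as np
import pytest

from triokit import (
    Call,
    GenomeIndex,
    Genotype,
    IntervalSet,
    Trio,
    VariantRecord,
    annotate_family,
    classify_variant_type,
    compare_callsets,
    f1_score,
    make_popvcf,
    mie_assess,
    mie_calibration_curve,
    select_best_checkpoint,
    summary_stats,
)
from triokit.evaluation import ConcordanceReport, StratumCounts
from triokit.mendelian import VerdictStatus

TRIO = Trio("kid", "dad", "mom")
GENOME = GenomeIndex([("1", 10_000_000), ("X", 1_000_000), ("Y", 100_000)])


def call_rec(pos, gt, sample="S", contig="1", ref="A", alts=("G",), gq=None):
    return VariantRecord(
        contig, pos, ref, alts, samples={sample: Call(Genotype(gt), gq)}
    )


def fam_rec(pos, kid, dad, mom, contig="1", filters=("PASS",), kid_gq=50,
            ref="A", alts=("G",)):
    rec = VariantRecord(
        contig, pos, ref, alts, filters=frozenset(filters),
        samples={
            "kid": Call(Genotype(kid), kid_gq),
            "dad": Call(Genotype(dad), 50),
            "mom": Call(Genotype(mom), 50),
        },
    )
    return next(annotate_family([rec], TRIO))


class TestClassifyVariantType:
    @pytest.mark.parametrize(
        "ref,alts,expected",
        [
            ("A", ("G",), "SNV"),
            ("A", ("G", "T"), "SNV"),
            ("AT", ("A",), "indel"),
            ("A", ("AT",), "indel"),
            ("AT", ("GC",), "other"),  # MNP
            ("A", ("A" + "T" * 60,), "other"),  # >=50 bp
        ],
    )
    def test_classes(self, ref, alts, expected):
        assert classify_variant_type(VariantRecord("1", 5, ref, alts)) == expected


class TestF1Score:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (1, 0, 0, 1.0),
            (0, 5, 5, 0.0),
            (90, 10, 30, 90 / (90 + 0.5 * 40)),
            (7, 0, 0, 1.0),
        ],
    )
    def test_formula(self, tp, fp, fn, expected):
        assert f1_score(tp, fp, fn) == pytest.approx(expected)

    def test_grid_matches_formula(self):
        for tp in range(0, 30, 7):
            for fp in range(0, 20, 3):
                for fn in range(0, 20, 5):
                    got = f1_score(tp, fp, fn)
                    if tp + fp + fn == 0:
                        assert got is None
                    else:
                        assert got == pytest.approx(tp / (tp + 0.5 * (fp + fn)))

    def test_absent_when_nothing_assessed(self):
        assert f1_score(0, 0, 0) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            f1_score(-1, 0, 0)

    def test_monotone_nonincreasing_in_errors(self):
        rng = random.Random(0)
        for _ in range(50):
            tp, fp, fn = rng.randint(1, 100), rng.randint(0, 50), rng.randint(0, 50)
            assert f1_score(tp, fp + 1, fn) <= f1_score(tp, fp, fn)
            assert f1_score(tp, fp, fn + 1) <= f1_score(tp, fp, fn)


def corrupt_query(truth, rng):
    """Mutate a truth callset at known positions; return query + expectations."""
    query = []
    expected = {"tp": 0, "fp": 0, "fn": 0, "gt_mismatch": 0}
    for rec in truth:
        roll = rng.random()
        if roll < 0.10:  # dropped -> FN
            expected["fn"] += 1
        elif roll < 0.20:  # genotype flipped -> FP + FN + mismatch
            call = rec.samples["S"]
            new_gt = (1, 1) if set(call.genotype.alleles) != {1} else (0, 1)
            query.append(replace(rec, samples={"S": Call(Genotype(new_gt))}))
            expected["gt_mismatch"] += 1
            expected["fp"] += 1
            expected["fn"] += 1
        else:
            query.append(rec)
            expected["tp"] += 1
    # novel calls -> FP
    for i in range(40):
        query.append(call_rec(9_000_000 + i, (0, 1)))
        expected["fp"] += 1
    return query, expected


class TestCompareCallsets:
    def truth_fixture(self, n=2000, seed=5):
        rng = random.Random(seed)
        truth = []
        for pos in sorted(rng.sample(range(1, 8_000_000), n)):
            gt = (0, 1) if rng.random() < 0.6 else (1, 1)
            if rng.random() < 0.15:
                truth.append(call_rec(pos, gt, ref="AT", alts=("A",)))
            else:
                truth.append(call_rec(pos, gt))
        return truth, rng

    def test_self_comparison_is_perfect_in_every_stratum(self):
        truth, _ = self.truth_fixture(n=500)
        report = compare_callsets(truth, truth)
        for counts in report.counts.values():
            assert counts.fp == 0 and counts.fn == 0
            assert counts.f1 == 1.0
        assert report.pooled().tp == 500
        assert report.overall_f1 == 1.0

    def test_truth_only_site_is_false_negative(self):
        report = compare_callsets([call_rec(100, (0, 1))], [])
        pooled = report.pooled()
        assert (pooled.tp, pooled.fp, pooled.fn) == (0, 0, 1)

    def test_query_only_site_is_false_positive(self):
        report = compare_callsets([], [call_rec(100, (0, 1))])
        pooled = report.pooled()
        assert (pooled.tp, pooled.fp, pooled.fn) == (0, 1, 0)

    def test_genotype_mismatch_counts_fp_and_fn(self):
        report = compare_callsets(
            [call_rec(100, (0, 1))], [call_rec(100, (1, 1))]
        )
        pooled = report.pooled()
        assert (pooled.tp, pooled.fp, pooled.fn, pooled.gt_mismatch) == (0, 1, 1, 1)

    def test_genotype_match_is_order_invariant(self):
        report = compare_callsets(
            [call_rec(100, (1, 0))], [call_rec(100, (0, 1))]
        )
        assert report.pooled().tp == 1

    def test_fp_only_mode(self):
        report = compare_callsets(
            [call_rec(100, (0, 1))], [call_rec(100, (1, 1))],
            gt_mismatch_mode="fp_only",
        )
        pooled = report.pooled()
        assert (pooled.fp, pooled.fn, pooled.gt_mismatch) == (1, 0, 1)

    def test_matches_brute_force_classifier_on_corrupted_fixture(self):
        truth, rng = self.truth_fixture()
        query, expected = corrupt_query(truth, rng)
        report = compare_callsets(truth, query)
        pooled = report.pooled()
        assert pooled.tp == expected["tp"]
        assert pooled.fp == expected["fp"]
        assert pooled.fn == expected["fn"]
        assert pooled.gt_mismatch == expected["gt_mismatch"]

    def test_swapping_truth_and_query_swaps_fp_fn(self):
        truth, rng = self.truth_fixture(n=800, seed=9)
        query, _ = corrupt_query(truth, rng)
        fwd = compare_callsets(truth, query).pooled()
        rev = compare_callsets(query, truth).pooled()
        assert (fwd.tp, fwd.fp, fwd.fn) == (rev.tp, rev.fn, rev.fp)
        assert fwd.gt_mismatch == rev.gt_mismatch

    def test_stratified_counts_sum_to_pooled(self):
        truth, rng = self.truth_fixture()
        query, _ = corrupt_query(truth, rng)
        strat = {"left": IntervalSet([("1", 0, 4_000_000)])}
        report = compare_callsets(truth, query, strat=strat)
        pooled = report.pooled()
        by_stratum = StratumCounts()
        for (vt, gc, reg), c in report.counts.items():
            if reg is None:
                by_stratum += c
        assert (by_stratum.tp, by_stratum.fp, by_stratum.fn) == (
            pooled.tp, pooled.fp, pooled.fn)
        left = report.pooled("left")
        assert left.tp <= pooled.tp and left.fp <= pooled.fp

    def test_multi_sample_input_rejected(self):
        rec = VariantRecord(
            "1", 5, "A", ("G",),
            samples={"A": Call(Genotype((0, 1))), "B": Call(Genotype((0, 1)))},
        )
        with pytest.raises(ValueError, match="single-sample"):
            compare_callsets([rec], [rec])


def report_with_f1(target_f1, n=1000):
    """Build a one-stratum report with a chosen F1."""
    tp = int(round(target_f1 * n))
    errors = 2 * (n - tp)
    rep = ConcordanceReport()
    counts = rep.at("SNV", "Het")
    counts.tp, counts.fp, counts.fn = tp, errors // 2, errors - errors // 2
    return rep


class TestSelectBestCheckpoint:
    def test_picks_maximum_f1(self):
        reports = [
            ("ckpt-27", report_with_f1(0.98)),
            ("ckpt-28", report_with_f1(0.99)),
            ("ckpt-29", report_with_f1(0.985)),
        ]
        assert select_best_checkpoint(reports) == "ckpt-28"

    def test_tie_goes_to_earliest(self):
        reports = [("a", report_with_f1(0.99)), ("b", report_with_f1(0.99))]
        assert select_best_checkpoint(reports) == "a"

    def test_adding_strictly_worse_report_never_changes_winner(self):
        rng = random.Random(31)
        for _ in range(30):
            f1s = [round(rng.uniform(0.5, 1.0), 3) for _ in range(5)]
            reports = [(f"c{i}", report_with_f1(f)) for i, f in enumerate(f1s)]
            winner = select_best_checkpoint(reports)
            worse = report_with_f1(min(f1s) - 0.05)
            assert select_best_checkpoint(reports + [("worse", worse)]) == winner

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best_checkpoint([])


class TestMieAssess:
    def test_rate_arithmetic(self):
        fam = [fam_rec(i + 1, (0, 1), (0, 1), (0, 1)) for i in range(990)]
        fam += [fam_rec(100_000 + i, (1, 1), (0, 0), (0, 0)) for i in range(10)]
        result = mie_assess(fam, GENOME)
        assert result.assessed == 1000
        assert result.discordant == 10
        assert result.rate == pytest.approx(0.01)

    def test_error_free_trio_has_zero_rate(self):
        fam = [fam_rec(i + 1, (0, 1), (0, 1), (1, 1)) for i in range(100)]
        assert mie_assess(fam, GENOME).rate == 0.0

    def test_restricted_to_pass_autosomes_x_called(self):
        fam = [
            fam_rec(10, (0, 1), (0, 1), (0, 1)),
            fam_rec(20, (0, 1), (0, 1), (0, 1), filters=("Tranche99.7",)),
            fam_rec(30, (0, 1), (0, 1), (0, 1), contig="Y"),
            fam_rec(40, (None, None), (0, 1), (0, 1)),
            fam_rec(50, (0, 1), (0, 1), (0, 1), contig="X"),
        ]
        result = mie_assess(fam, GENOME)
        assert result.assessed == 2  # pos 10 on chr1 and pos 50 on X

    def test_snv_only_mode(self):
        fam = [
            fam_rec(10, (1, 1), (0, 0), (0, 0)),
            fam_rec(20, (1, 1), (0, 0), (0, 0), ref="AT", alts=("A",)),
        ]
        assert mie_assess(fam, GENOME).discordant == 2
        assert mie_assess(fam, GENOME, snv_only=True).discordant == 1

    def test_rate_absent_when_nothing_assessed(self):
        assert mie_assess([], GENOME).rate is None

    def test_parent_swap_invariance(self, sim_data, trio_ids):
        fam = list(annotate_family(sim_data["trio"], trio_ids))
        swapped_trio = Trio(trio_ids.child, trio_ids.mother, trio_ids.father)
        fam_swapped = list(annotate_family(sim_data["trio"], swapped_trio))
        genome = sim_data["genome"]
        assert mie_assess(fam, genome).rate == mie_assess(fam_swapped, genome).rate

    def test_recovers_simulated_detectable_fraction(self, sim_data, trio_ids):
        """MIE on the full trio equals the planted detectable fraction."""
        truth = sim_data["truth"]
        fam = annotate_family(sim_data["trio"], trio_ids)
        result = mie_assess(fam, sim_data["genome"])
        pass_rows = truth[truth.is_pass]
        assert result.assessed == len(pass_rows)
        assert result.discordant == int(pass_rows.detectable_discordance.sum())


class TestCalibrationCurve:
    def test_all_concordant_curve_is_flat_zero(self):
        fam = [fam_rec(i + 1, (0, 1), (0, 1), (0, 1), kid_gq=50 - i % 20)
               for i in range(50)]
        result = mie_calibration_curve(fam, GENOME)
        assert [p.cum_errors for p in result.curve] == [0] * 50
        assert result.curve[-1].cum_variants == 50

    def test_terminal_point_matches_mie_assess(self, sim_data, trio_ids):
        fam = list(annotate_family(sim_data["trio"], trio_ids))
        genome = sim_data["genome"]
        curve = mie_calibration_curve(fam, genome)
        flat = mie_assess(fam, genome)
        assert curve.curve[-1].cum_variants == flat.assessed
        assert curve.curve[-1].cum_errors == flat.discordant

    def test_monotone_and_gq_sorted(self, sim_data, trio_ids):
        fam = annotate_family(sim_data["trio"], trio_ids)
        result = mie_calibration_curve(fam, sim_data["genome"])
        gqs = [p.gq for p in result.curve if p.gq is not None]
        assert gqs == sorted(gqs, reverse=True)
        errs = [p.cum_errors for p in result.curve]
        assert all(b - a in (0, 1) for a, b in zip(errs, errs[1:]))

    def test_absent_gq_sorts_last(self):
        fam = [
            fam_rec(10, (1, 1), (0, 0), (0, 0), kid_gq=None),
            fam_rec(20, (0, 1), (0, 1), (0, 1), kid_gq=0),
        ]
        result = mie_calibration_curve(fam, GENOME)
        assert [p.gq for p in result.curve] == [0, None]

    def test_low_gq_errors_give_smaller_area_than_permuted_control(
        self, sim_data, trio_ids
    ):
        """Errors concentrated at low GQ => flat-then-rising curve."""
        genome = sim_data["genome"]
        fam = list(annotate_family(sim_data["trio"], trio_ids))
        result = mie_calibration_curve(fam, genome)
        area = sum(p.cum_errors for p in result.curve)

        rng = np.random.default_rng(99)
        entries = [fr for fr in fam if fr.verdict.is_assessed
                   and fr.site.is_pass
                   and genome.is_autosome_or_x(fr.site.contig)]
        flags = [fr.verdict.status is VerdictStatus.DISCORDANT for fr in entries]
        perm = rng.permutation(len(flags))
        cum = 0
        area_control = 0
        for i in perm:
            cum += flags[i]
            area_control += cum
        assert area < area_control


class TestSummaryStats:
    def test_single_transition_degenerate(self):
        recs = [call_rec(10, (0, 1))]  # A->G
        s = summary_stats(recs, "S", genome_span=1_000_000)
        assert (s.ti, s.tv) == (1, 0)
        assert s.titv_ratio is None

    def test_balanced_ti_tv(self):
        recs = [
            call_rec(10, (0, 1), ref="A", alts=("G",)),
            call_rec(20, (0, 1), ref="C", alts=("T",)),
            call_rec(30, (0, 1), ref="A", alts=("C",)),
            call_rec(40, (0, 1), ref="G", alts=("T",)),
        ]
        s = summary_stats(recs, "S", genome_span=1_000_000)
        assert s.titv_ratio == pytest.approx(1.0)

    def test_homref_and_missing_genotypes_not_counted(self):
        recs = [
            call_rec(10, (0, 0)),
            call_rec(20, (None, None)),
            call_rec(30, (0, 1)),
        ]
        s = summary_stats(recs, "S", genome_span=2_000_000)
        assert s.n_variants == 1
        assert s.variant_density_per_mb == pytest.approx(0.5)

    def test_counts_and_ratios(self):
        recs = [
            call_rec(10, (0, 1)),
            call_rec(20, (1, 1)),
            call_rec(30, (0, 1), ref="AT", alts=("A",)),
        ]
        s = summary_stats(recs, "S", genome_span=1_000_000)
        assert (s.snv_count, s.indel_count) == (2, 1)
        assert s.snv_indel_ratio == pytest.approx(2.0)
        assert (s.het_count, s.homalt_count) == (2, 1)
        assert s.het_homalt_ratio == pytest.approx(2.0)

    def test_uniform_random_substitutions_approach_one_half(self):
        """2 transition vs 4 transversion targets per site => Ti:Tv -> 0.5."""
        rng = random.Random(12)
        bases = "ACGT"
        recs = []
        for i in range(20_000):
            ref = rng.choice(bases)
            alt = rng.choice([b for b in bases if b != ref])
            recs.append(call_rec(i + 1, (0, 1), ref=ref, alts=(alt,)))
        s = summary_stats(recs, "S", genome_span=10_000_000)
        n = s.ti + s.tv
        p = 1 / 3
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(s.ti - n * p) < 3 * sigma


def cohort_rec(pos, genotypes, ref="A", alts=("G",)):
    samples = {f"S{i}": Call(Genotype(gt)) for i, gt in enumerate(genotypes)}
    return VariantRecord("1", pos, ref, alts, samples=samples)


class TestMakePopvcf:
    def test_af_counting(self):
        out = list(make_popvcf([cohort_rec(10, [(0, 1), (0, 1), (1, 1)])]))
        assert out[0].info["AF"] == pytest.approx((4 / 6,))
        assert out[0].samples == {}

    def test_missing_alleles_excluded_from_denominator(self):
        out = list(make_popvcf([cohort_rec(10, [(None, None), (0, 1)])]))
        assert out[0].info["AF"] == pytest.approx((0.5,))

    def test_zero_called_site_retained_with_absent_af(self):
        out = list(make_popvcf([cohort_rec(10, [(None, None)])]))
        assert len(out) == 1
        assert "AF" not in out[0].info

    def test_multiallelic_per_alt_frequencies(self):
        out = list(make_popvcf(
            [cohort_rec(10, [(0, 1), (2, 2), (0, 0)], alts=("G", "T"))]
        ))
        assert out[0].info["AF"] == pytest.approx((1 / 6, 2 / 6))

    def test_matches_brute_force_tally_on_simulated_cohort(self, sim_data):
        cohort = sim_data["cohort"][:500]
        out = list(make_popvcf(cohort))
        for rec, pop in zip(cohort, out):
            counts = [0] * (1 + len(rec.alts))
            called = 0
            for c in rec.samples.values():
                for a in c.genotype.alleles:
                    if a is not None:
                        counts[a] += 1
                        called += 1
            expected = tuple(c / called for c in counts[1:])
            assert pop.info["AF"] == pytest.approx(expected)
            afs = pop.info["AF"]
            assert all(0.0 <= a <= 1.0 for a in afs)
            assert sum(afs) <= 1.0 + 1e-12
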