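"""Weighted P values, BH step-up, Benjamini–Liu step-down, lead SNPs."""

import logging

import numpy as np
import pytest
from scipy import stats

from igwas import (
    FdrRecord,
    PriorSpec,
    bayes_weights,
    bh_adjust,
    bl_adjust,
    select_lead_snps,
    weight_pvalues,
    weighted_fdr_records,
)


class TestWeightPvalues:
    def test_unit_weight_identity(self):
        assert weight_pvalues([0.5], [1.0])[0] == 0.5

    def test_zero_weight_never_rejectable(self):
        assert weight_pvalues([0.5], [0.0])[0] == 1.0

    def test_published_raw_to_weighted_ratio(self):
        # rs2075650: raw 2.36E-10 with weight 641.3 gives 3.68E-13
        weight = 2.36e-10 / 3.68e-13
        assert weight == pytest.approx(641.3, rel=1e-3)
        assert weight_pvalues([2.36e-10], [weight])[0] == pytest.approx(
            3.68e-13, rel=1e-6
        )

    def test_clipped_at_one(self):
        assert weight_pvalues([0.9], [0.5])[0] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weight_pvalues([0.1, 0.2], [1.0])


class TestBhAdjust:
    def test_single_test_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_three_test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9]
        )

    def test_genomewide_rank_one_adjustment(self):
        # top weighted P among S=243,980 tests, no competition from the rest
        rng = np.random.default_rng(0)
        p = np.concatenate([[3.68e-13], rng.uniform(0.5, 1.0, size=243_979)])
        assert bh_adjust(p)[0] == pytest.approx(8.98e-8, rel=1e-3)

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        adjusted = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestBlAdjust:
    def test_single_test_rejects_at_the_level(self):
        assert bl_adjust([0.04], q=0.05)[0][0]
        assert not bl_adjust([0.06], q=0.05)[0][0]

    def test_all_ones_never_rejected(self):
        reject, _ = bl_adjust([1.0, 1.0, 1.0], q=0.2)
        assert not reject.any()

    def test_three_test_worked_example(self):
        # delta_1 = 1-(1-0.05)^(1/3) = 0.01695: only the first passes
        reject, adjusted = bl_adjust([0.001, 0.2, 0.9], q=0.05)
        np.testing.assert_array_equal(reject, [True, False, False])
        # smallest level rejecting p=0.001 at step 1: 1-(1-0.001)^3
        assert adjusted[0] == pytest.approx(1 - 0.999**3, rel=1e-12)

    def test_rejections_are_a_prefix_of_the_sorted_order(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 10)))
            reject, adjusted = bl_adjust(p, q=0.1)
            order = np.argsort(p)
            flags = reject[order]
            assert not np.any(~flags[:-1] & flags[1:])  # no True after a False
            assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_adjusted_values_invert_the_sequential_rule(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p = rng.uniform(size=5)
            _, adjusted = bl_adjust(p, q=0.5)
            for level in (0.01, 0.05, 0.2, 0.4):
                reject, _ = bl_adjust(p, q=level)
                np.testing.assert_array_equal(
                    reject, adjusted <= level + 1e-12
                )


class TestLeadSnps:
    @staticmethod
    def record(snp_id, p_adjusted, p_weighted=None, block="b1", significant=True):
        rec = FdrRecord(snp_id=snp_id, p_raw=p_adjusted, weight=1.0)
        rec.p_adjusted = p_adjusted
        rec.p_weighted = p_weighted if p_weighted is not None else p_adjusted
        rec.block = block
        rec.significant = significant
        return rec

    def test_lowest_adjusted_p_leads_within_block(self):
        records = [self.record("a", 0.01), self.record("b", 0.02)]
        select_lead_snps(records)
        assert [r.is_lead for r in records] == [True, False]

    def test_one_lead_per_block(self):
        records = [
            self.record("a", 0.01, block="b1"),
            self.record("b", 0.02, block="b2"),
            self.record("c", 0.03, block="b2"),
        ]
        select_lead_snps(records)
        assert sum(r.is_lead for r in records) == 2
        assert records[0].is_lead and records[1].is_lead

    def test_tie_broken_by_weighted_p(self):
        records = [
            self.record("a", 0.01, p_weighted=2e-5),
            self.record("b", 0.01, p_weighted=1e-5),
        ]
        select_lead_snps(records)
        assert records[1].is_lead and not records[0].is_lead

    def test_nonsignificant_records_never_lead(self):
        records = [self.record("a", 0.5, significant=False)]
        select_lead_snps(records)
        assert not records[0].is_lead

    def test_missing_block_label_gets_singleton_block(self, caplog):
        records = [self.record("a", 0.01, block=None)]
        with caplog.at_level(logging.WARNING, logger="igwas"):
            select_lead_snps(records)
        assert records[0].is_lead
        assert "own block" in caplog.text


class TestWeightedBhPipeline:
    def test_constant_eta_weights_reduce_to_plain_bh(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=500)
        prior = PriorSpec(eta=np.full(500, 2.0), sigma=0.25, q=1 / 500)
        w = bayes_weights(prior).weights
        np.testing.assert_array_equal(
            bh_adjust(weight_pvalues(p, w)), bh_adjust(p)
        )

    def test_fdr_controlled_on_independent_nulls(self):
        # scaled-down companion of the full-size experiment: weights from
        # an independent random prior, all-null uniform P values
        rng = np.random.default_rng(7)
        m, reps, level = 2000, 100, 0.10
        fdp = []
        for _ in range(reps):
            eta = np.maximum(0.0, rng.normal(0.3, 0.5, size=m))
            w = bayes_weights(PriorSpec(eta=eta, sigma=0.25, q=1 / m)).weights
            p = rng.uniform(size=m)
            rejected = bh_adjust(weight_pvalues(p, w)) < level
            # every rejection is false under the global null
            fdp.append(1.0 if rejected.any() else 0.0)
        fdp = np.asarray(fdp)
        se = fdp.std(ddof=1) / np.sqrt(reps)
        assert fdp.mean() <= level + 3 * se

    def test_informative_weights_recover_more_true_signals(self):
        rng = np.random.default_rng(8)
        m, n_causal = 2000, 20
        wins = 0
        for _ in range(20):
            mu = np.zeros(m)
            causal = rng.choice(m, size=n_causal, replace=False)
            mu[causal] = 4.0
            z = mu + rng.standard_normal(m)
            p = 2 * stats.norm.sf(np.abs(z))
            eta = np.abs(mu) + rng.normal(0, 0.2, size=m).clip(0)
            w = bayes_weights(PriorSpec(eta=eta, sigma=0.25, q=1 / m)).weights
            weighted_hits = (bh_adjust(weight_pvalues(p, w)) < 0.1)[causal].sum()
            plain_hits = (bh_adjust(p) < 0.1)[causal].sum()
            wins += int(weighted_hits >= plain_hits)
        assert wins >= 18

    def test_records_pipeline_flags_and_blocks(self):
        records = weighted_fdr_records(
            ["a", "b", "c"],
            [1e-6, 0.5, 0.9],
            [1.0, 1.0, 1.0],
            q=0.10,
            blocks={"a": "blk1", "b": "blk1", "c": "blk2"},
        )
        assert records[0].significant and records[0].is_lead
        assert records[0].rank == 1
        assert not records[1].significant
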