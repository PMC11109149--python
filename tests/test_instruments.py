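import itertools

import numpy as np
import pytest

from metabomr.errors import ConfigurationError, DegenerateInputError, LdLookupError
from metabomr.instruments import (
    IndependentLd,
    PairwiseLd,
    SelectionParams,
    build_instrument_set,
    f_statistic,
    ld_clump,
    select_by_pvalue,
    variance_explained,
)
from metabomr.synthetic_data import ScenarioConfig, simulate_pair

from conftest import SEED, make_table, make_variant


def random_table(rng, n=30):
    recs = [
        make_variant(
            f"rs{i}",
            chrom=str(rng.integers(1, 3)),
            pos=int(rng.integers(1, 5_000_000)),
            pval=float(rng.uniform(1e-9, 1.0)),
        )
        for i in range(n)
    ]
    return make_table(recs)


class TestSelectByPvalue:
    def test_none_below_threshold(self):
        t = make_table([make_variant(f"rs{i}", pos=i * 10**6 + 1, pval=0.5) for i in range(4)])
        assert len(select_by_pvalue(t, 1e-5)) == 0

    def test_boundary_is_strict(self):
        t = make_table([
            make_variant("rs1", pval=9e-6),
            make_variant("rs2", pos=2_000_000, pval=1e-5),  # equal to threshold: excluded
        ])
        kept = select_by_pvalue(t, 1e-5)
        assert [r.variant_id for r in kept.records] == ["rs1"]

    def test_matches_brute_force(self, rng):
        t = random_table(rng)
        thr = 0.3
        expected = [r.variant_id for r in t.records if r.pval < thr]
        assert [r.variant_id for r in select_by_pvalue(t, thr).records] == expected

    def test_bad_threshold(self):
        with pytest.raises(ConfigurationError):
            select_by_pvalue(make_table([make_variant()]), 1.0)


def greedy_clump_reference(records, ld, r2_max, window_kb):
    """Independent re-statement of the greedy rule used as oracle."""
    pool = sorted(records, key=lambda r: (r.pval, r.chrom, r.pos))
    kept = []
    while pool:
        lead, rest = pool[0], pool[1:]
        kept.append(lead.variant_id)
        pool = [
            r for r in rest
            if not (
                r.chrom == lead.chrom
                and abs(r.pos - lead.pos) <= window_kb * 1000
                and ld.r2(lead.variant_id, r.variant_id) >= r2_max
            )
        ]
    return kept


class TestLdClump:
    def test_no_ld_returns_input(self, rng):
        t = random_table(rng, n=10)
        out = ld_clump(t, IndependentLd())
        assert [r.variant_id for r in out.records] == [r.variant_id for r in t.records]

    def test_single_clump_keeps_lowest_p(self):
        t = make_table([
            make_variant("rs1", pos=1_000_000, pval=1e-6),
            make_variant("rs2", pos=1_010_000, pval=1e-8),
        ])
        ld = PairwiseLd({("rs1", "rs2"): 0.5})
        assert [r.variant_id for r in ld_clump(t, ld).records] == ["rs2"]

    def test_matches_reference_oracle(self, rng):
        for _ in range(10):
            n = 20
            recs = [
                make_variant(
                    f"rs{i}",
                    chrom=str(rng.integers(1, 3)),
                    pos=int(rng.integers(1, 2_000_000)),
                    pval=float(rng.uniform(0, 1)),
                )
                for i in range(n)
            ]
            pairs = {
                (f"rs{a}", f"rs{b}"): float(rng.uniform(0, 1))
                for a, b in itertools.combinations(range(n), 2)
            }
            ld = PairwiseLd(pairs)
            t = make_table(recs)
            got = [r.variant_id for r in ld_clump(t, ld, 0.2, 500).records]
            assert set(got) == set(greedy_clump_reference(recs, ld, 0.2, 500))
            # output preserves the input table's row order
            input_order = [r.variant_id for r in recs if r.variant_id in set(got)]
            assert got == input_order

    def test_no_retained_pair_violates_rule(self, rng):
        n = 25
        recs = [
            make_variant(f"rs{i}", chrom="1", pos=int(rng.integers(1, 1_000_000)),
                         pval=float(rng.uniform(0, 1)))
            for i in range(n)
        ]
        ld = PairwiseLd({
            (f"rs{a}", f"rs{b}"): float(rng.uniform(0, 1))
            for a, b in itertools.combinations(range(n), 2)
        })
        kept = ld_clump(make_table(recs), ld, 0.1, 500).records
        for a, b in itertools.combinations(kept, 2):
            within = a.chrom == b.chrom and abs(a.pos - b.pos) <= 500_000
            assert not (within and ld.r2(a.variant_id, b.variant_id) >= 0.1)

    def test_missing_pair_is_an_error(self):
        t = make_table([
            make_variant("rs1", pos=1_000_000, pval=1e-8),
            make_variant("rs2", pos=1_005_000, pval=1e-6),
        ])
        with pytest.raises(LdLookupError, match="rs[12].*rs[12]"):
            ld_clump(t, PairwiseLd({}))


class TestStrength:
    def test_zero_beta_zero_r2(self):
        assert variance_explained(make_variant(beta=0.0)) == 0.0

    def test_hand_computed_value(self):
        # eaf 0.3, beta 0.1, se 0.01, n 7824
        r2 = variance_explained(make_variant())
        assert r2 == pytest.approx(0.0126199, rel=1e-4)
        f = f_statistic(r2, 7824, k=1)
        assert f == pytest.approx(99.97, rel=1e-3)
        # asymptotic identity with (beta/se)^2 = 100
        assert f == pytest.approx((0.1 / 0.01) ** 2, rel=0.05)

    def test_symmetric_in_allele_frequency(self):
        a = variance_explained(make_variant(eaf=0.3))
        b = variance_explained(make_variant(eaf=0.7))
        assert a == pytest.approx(b, rel=1e-12)

    def test_degenerate_eaf(self):
        with pytest.raises(DegenerateInputError):
            variance_explained(make_variant(eaf=0.0))

    def test_f_zero_and_monotone(self):
        assert f_statistic(0.0, 1000) == 0.0
        grid = [f_statistic(r2, 1000) for r2 in (0.001, 0.01, 0.1, 0.5)]
        assert grid == sorted(grid) and len(set(grid)) == len(grid)

    def test_f_requires_enough_samples(self):
        with pytest.raises(DegenerateInputError):
            f_statistic(0.1, n=2, k=1)

    def test_wald_squared_agreement_property(self, rng):
        # f(k=1) within 5% of (beta/se)^2 for weak-moderate r2 and large n
        for _ in range(50):
            v = make_variant(
                eaf=float(rng.uniform(0.05, 0.95)),
                beta=float(rng.uniform(-0.15, 0.15)) or 0.01,
                se=float(rng.uniform(0.008, 0.02)),
            )
            r2 = variance_explained(v)
            if r2 >= 0.05:
                continue
            assert f_statistic(r2, v.n) == pytest.approx((v.beta / v.se) ** 2, rel=0.05)


class TestBuildInstrumentSet:
    def test_stage_counts_monotone(self, rng):
        t = random_table(rng, n=40)
        iv = build_instrument_set(t, SelectionParams(p_threshold=0.5), IndependentLd())
        c = iv.stage_counts
        assert c["input"] >= c["after_pvalue"] >= c["after_clump"] >= c["after_strength"]
        assert c["after_strength"] == len(iv)

    def test_strength_filter_keeps_f_at_threshold(self):
        v = make_variant(pval=1e-8)
        f = f_statistic(variance_explained(v), v.n)
        t = make_table([v])
        kept = build_instrument_set(t, SelectionParams(f_min=f), IndependentLd())
        assert kept.variant_ids == ["rs1"]  # F >= f_min retained ("lower than" excluded)
        dropped = build_instrument_set(
            t, SelectionParams(f_min=f * (1 + 1e-9)), IndependentLd()
        )
        assert len(dropped) == 0

    def test_recovers_strong_independent_instruments(self):
        exposure, _, truth = simulate_pair(ScenarioConfig(seed=SEED, n_snps=10))
        iv = build_instrument_set(exposure, SelectionParams(), IndependentLd())
        assert set(iv.variant_ids) == set(truth.instrument_ids())

    def test_empty_result_is_not_an_error(self):
        t = make_table([make_variant(pval=0.9)])
        assert len(build_instrument_set(t, SelectionParams(), IndependentLd())) == 0
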