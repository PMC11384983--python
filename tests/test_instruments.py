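"""Instrument selection: thresholding, clumping, exclusion, F filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmediate import (
    BlockLD,
    EmptyInstrumentSetError,
    SelectionParams,
    SummaryStatTable,
    TableLD,
    ZeroLD,
    build_instrument_set,
    exclude_confounder_snps,
    f_statistic,
    ld_clump,
    threshold_select,
)

from conftest import sumstat_frame


def table_with_pvals(pvals, positions=None, chrom="1"):
    n = len(pvals)
    df = sumstat_frame(n, seed=1)
    df["pval"] = pvals
    df["chr"] = chrom
    if positions is not None:
        df["pos"] = positions
    return SummaryStatTable("t", df)


class TestThreshold:
    def test_keeps_exactly_sub_threshold_records(self):
        t = table_with_pvals([1e-6, 1e-4, 1e-8])
        kept = threshold_select(t, 1e-5)
        assert list(kept.df["pval"]) == [1e-6, 1e-8]

    def test_threshold_is_strict(self):
        t = table_with_pvals([1e-5, 0.99e-5])
        kept = threshold_select(t, 1e-5)
        assert len(kept) == 1

    def test_threshold_one_keeps_everything_but_p_equal_one(self):
        t = table_with_pvals([0.2, 0.5, 1.0])
        assert len(threshold_select(t, 1.0)) == 2

    def test_false_inclusion_rate_matches_binomial_expectation(self):
        """1e5 uniform null p-values at threshold 1e-4: expected ~10 kept."""
        rng = np.random.default_rng(0)
        n = 100_000
        df = sumstat_frame(200, seed=2)
        pvals = rng.uniform(size=n)
        reps = pd.concat([df] * (n // 200), ignore_index=True)
        reps["snp"] = [f"rs{i}" for i in range(n)]
        reps["pval"] = pvals
        t = SummaryStatTable("null", reps)
        kept = len(threshold_select(t, 1e-4))
        # Binomial(1e5, 1e-4): mean 10, sd ~3.16; allow 4 sd
        assert abs(kept - 10) < 4 * np.sqrt(10)


class TestClump:
    def test_independent_snps_identity(self):
        t = table_with_pvals([1e-6, 1e-7, 1e-8], positions=[100, 200, 300])
        out = ld_clump(t, ZeroLD(), SelectionParams())
        assert set(out.df["snp"]) == set(t.df["snp"])

    def test_single_pair_keeps_lower_p(self):
        t = table_with_pvals([1e-9, 1e-6], positions=[1, 5_000_000])
        ld = TableLD({("rs0", "rs1"): 0.5})
        out = ld_clump(t, ld, SelectionParams())
        assert list(out.df["snp"]) == ["rs0"]

    def test_window_limits_claiming(self):
        """Same r2 but 15,000 kb apart: both survive the 10,000 kb window."""
        t = table_with_pvals([1e-9, 1e-6], positions=[1, 15_000_000_0])
        ld = TableLD({("rs0", "rs1"): 0.9})
        out = ld_clump(t, ld, SelectionParams())
        assert len(out) == 2

    def test_three_blocks_give_three_index_snps(self):
        """10 SNPs in 3 LD blocks (r2 0.9 within, 0 between): survivors are
        each block's minimum-p SNP, confirmed by brute force over orderings."""
        rng = np.random.default_rng(3)
        pvals = rng.uniform(1e-10, 1e-6, 10)
        blocks = {f"rs{i}": i % 3 for i in range(10)}
        t = table_with_pvals(pvals, positions=list(range(100, 1100, 100)))
        ld = BlockLD(blocks, within_r2=0.9)
        out = ld_clump(t, ld, SelectionParams())
        expected = {
            min((p, f"rs{i}") for i, p in enumerate(pvals) if i % 3 == b)[1]
            for b in range(3)
        }
        assert set(out.df["snp"]) == expected
        # brute force: any processing order of distinct p-values gives the
        # same greedy result because each block's min-p SNP is never claimed
        for perm in itertools.islice(itertools.permutations(range(3)), 6):
            shuffled = t.df.iloc[list(np.argsort([perm[i % 3] for i in range(10)]))]
            t2 = SummaryStatTable("t", shuffled)
            out2 = ld_clump(t2, ld, SelectionParams())
            assert set(out2.df["snp"]) == expected

    def test_order_independence(self):
        df = sumstat_frame(20, seed=4)
        df["chr"] = "2"
        df["pos"] = np.arange(20) * 1000
        t1 = SummaryStatTable("t", df)
        t2 = SummaryStatTable("t", df.sample(frac=1, random_state=0))
        ld = BlockLD({f"rs{i}": i // 5 for i in range(20)}, within_r2=0.8)
        a = ld_clump(t1, ld, SelectionParams())
        b = ld_clump(t2, ld, SelectionParams())
        assert list(a.df["snp"]) == list(b.df["snp"])

    def test_missing_position_forms_own_clump(self):
        df = sumstat_frame(3, seed=5)
        df["pval"] = [1e-8, 1e-7, 1e-6]
        df["chr"] = "1"
        df["pos"] = pd.array([100, pd.NA, 200], dtype="Int64")
        t = SummaryStatTable("t", df)
        ld = TableLD({("rs0", "rs1"): 0.99, ("rs0", "rs2"): 0.99})
        out = ld_clump(t, ld, SelectionParams())
        # rs1 has no position: cannot be claimed; rs2 is claimed by rs0
        assert set(out.df["snp"]) == {"rs0", "rs1"}


class TestExclusion:
    def test_empty_set_identity(self, default_chain):
        t = default_chain[0]
        assert exclude_confounder_snps(t, set()).df.equals(t.df)

    def test_full_exclusion_empties_table(self, default_chain):
        t = default_chain[0]
        out = exclude_confounder_snps(t, set(t.df["snp"]))
        assert len(out) == 0

    def test_random_20pct_exclusion(self):
        df = sumstat_frame(100, seed=6)
        t = SummaryStatTable("t", df)
        rng = np.random.default_rng(0)
        excl = set(rng.choice(df["snp"], 20, replace=False))
        out = exclude_confounder_snps(t, excl)
        assert len(out) == 80
        assert set(out.df["snp"]) == set(df["snp"]) - excl


class TestFStatistic:
    def test_closed_form(self):
        assert f_statistic(0.2, 0.05) == pytest.approx(16.0)

    def test_sign_free(self):
        assert f_statistic(-0.1, 0.05) == pytest.approx(4.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    @given(
        beta=st.floats(-10, 10, allow_nan=False),
        se=st.floats(1e-3, 10),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, beta, se, c):
        assert f_statistic(c * beta, c * se) == pytest.approx(
            f_statistic(beta, se), rel=1e-9
        )


class TestBuildInstrumentSet:
    def test_clean_table_passes_unchanged(self):
        df = sumstat_frame(5, seed=7)
        df["pval"] = 1e-9
        df["beta"] = 0.5
        df["se"] = 0.05  # F = 100
        df["pos"] = np.arange(5) * 10**8
        t = SummaryStatTable("t", df)
        iv = build_instrument_set(t, ZeroLD(), SelectionParams())
        assert iv.n_snp == 5
        assert all(v == 0 for v in iv.audit.values())
        assert iv.mean_f == pytest.approx(100.0)

    def test_weak_instrument_removed_at_f_stage(self):
        df = sumstat_frame(3, seed=8)
        df["pval"] = 1e-9
        df["beta"] = [0.5, 0.1, 0.5]
        df["se"] = 0.05  # F = 100, 4, 100
        t = SummaryStatTable("t", df)
        iv = build_instrument_set(t, ZeroLD(), SelectionParams())
        assert iv.audit["weak"] == 1
        assert "rs1" not in set(iv.table.df["snp"])
        assert (iv.f_stats > 10).all()

    def test_audit_counts_sum_to_attrition(self, default_chain):
        exp = default_chain[0]
        params = SelectionParams(exclusion_ids=frozenset({"rs000001"}))
        iv = build_instrument_set(exp, ZeroLD(), params)
        assert sum(iv.audit.values()) == len(exp) - iv.n_snp

    def test_empty_stage_raises_with_stage_name(self):
        df = sumstat_frame(3, seed=9)
        df["pval"] = 0.5
        t = SummaryStatTable("t", df)
        with pytest.raises(EmptyInstrumentSetError) as exc:
            build_instrument_set(t, ZeroLD(), SelectionParams())
        assert exc.value.stage == "threshold"

    def test_matches_independent_stagewise_filter(self):
        """Full pipeline on a seeded table == hand-coded stage-by-stage
        filter (threshold, greedy clump, exclusion, F > 10)."""
        rng = np.random.default_rng(12)
        n = 60
        df = sumstat_frame(n, seed=12)
        df["chr"] = "1"
        df["pos"] = np.sort(rng.integers(1, 5_000_000, n))
        df["beta"] = rng.normal(0, 0.2, n)
        df["se"] = rng.uniform(0.02, 0.1, n)
        z = df["beta"] / df["se"]
        from scipy import stats as ss

        df["pval"] = np.clip(2 * ss.norm.sf(np.abs(z)), 1e-300, 1)
        t = SummaryStatTable("t", df)
        blocks = {f"rs{i}": i // 6 for i in range(n)}
        ld = BlockLD(blocks, within_r2=0.5)
        excl = frozenset({f"rs{i}" for i in range(0, n, 7)})
        params = SelectionParams(p_threshold=1e-3, exclusion_ids=excl)

        # independent filter, coded from the rules directly
        cand = df[df["pval"] < 1e-3].copy()
        kept, claimed = [], set()
        for _, row in cand.sort_values(["pval", "chr", "pos", "snp"]).iterrows():
            if row["snp"] in claimed:
                continue
            kept.append(row["snp"])
            claimed.add(row["snp"])
            for _, o in cand.iterrows():
                if o["snp"] in claimed:
                    continue
                near = abs(o["pos"] - row["pos"]) <= 10_000 * 1000
                if near and blocks[o["snp"]] == blocks[row["snp"]] and 0.5 > 0.001:
                    claimed.add(o["snp"])
        kept = [s for s in kept if s not in excl]
        expected = [
            s
            for s in kept
            if (df.set_index("snp").loc[s, "beta"] / df.set_index("snp").loc[s, "se"])
            ** 2
            > 10
        ]
        iv = build_instrument_set(t, ld, params)
        assert set(iv.table.df["snp"]) == set(expected)
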