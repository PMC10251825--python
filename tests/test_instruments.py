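"""Instrument selection: thresholding, clumping, proxies, F-statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen import (
    DomainError,
    LDPanel,
    SummaryDataset,
    clump,
    f_statistic,
    find_proxy,
    per_snp_r2,
    threshold_filter,
)
from mrscreen.summary_io import CANONICAL_COLUMNS

from conftest import make_variant


def _dataset(rows, name="exp"):
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return SummaryDataset(trait_name=name, variants=df)


def _row(vid, chrom="1", pos=1000, pval=1e-10, beta=0.1, se=0.01, eaf=0.3, n=50_000):
    return dict(variant_id=vid, chromosome=chrom, position=pos, effect_allele="A",
                other_allele="G", eaf=eaf, beta=beta, se=se, pval=pval, n=n)


class TestThresholdFilter:
    def test_strict_inequality_at_boundary(self):
        ds = _dataset([_row("a", pval=1e-9), _row("b", pval=5e-8), _row("c", pval=1e-7)])
        kept = threshold_filter(ds)
        assert list(kept["variant_id"]) == ["a"]

    def test_all_above_threshold_gives_empty(self):
        ds = _dataset([_row("a", pval=0.5), _row("b", pval=5e-8)])
        assert threshold_filter(ds).empty

    def test_count_matches_direct_scan(self, rng):
        pvals = 10.0 ** rng.uniform(-12, 0, 100)
        ds = _dataset([_row(f"v{i}", pval=p) for i, p in enumerate(pvals)])
        kept = threshold_filter(ds, 5e-8)
        assert len(kept) == int(sum(1 for p in pvals if p < 5e-8))
        # original order preserved
        assert list(kept["variant_id"]) == [f"v{i}" for i, p in enumerate(pvals) if p < 5e-8]


def _r2_panel(ids, pairs, positions=None):
    return LDPanel(variant_ids=list(ids), r2_table=dict(pairs), positions=positions)


class TestClump:
    def test_single_clump_keeps_smallest_pval(self):
        cands = pd.DataFrame([_row("a", pos=1000, pval=1e-10),
                              _row("b", pos=2000, pval=1e-9),
                              _row("c", pos=3000, pval=1e-8)])
        panel = _r2_panel("abc", {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0})
        kept, dropped = clump(cands, panel)
        assert list(kept["variant_id"]) == ["a"]
        assert dropped == []

    def test_window_limits_clumping(self):
        cands = pd.DataFrame([_row("a", pos=1_000_000, pval=1e-10),
                              _row("b", pos=21_000_000, pval=1e-9)])
        panel = _r2_panel("ab", {("a", "b"): 0.9})
        kept, _ = clump(cands, panel)  # 20 Mb apart > 10,000 kb window
        assert sorted(kept["variant_id"]) == ["a", "b"]

    def test_different_chromosomes_never_clump(self):
        cands = pd.DataFrame([_row("a", chrom="1", pos=1000, pval=1e-10),
                              _row("b", chrom="2", pos=1000, pval=1e-9)])
        panel = _r2_panel("ab", {("a", "b"): 1.0})
        kept, _ = clump(cands, panel)
        assert sorted(kept["variant_id"]) == ["a", "b"]

    @staticmethod
    def _brute_force(cands: pd.DataFrame, panel, r2_thr, window_kb):
        """Independent greedy reference over explicit pair checks."""
        from mrscreen import ld_r2

        rows = cands.to_dict("records")
        rows.sort(key=lambda r: (r["pval"], r["chromosome"], r["position"], r["variant_id"]))
        kept = []
        while rows:
            idx = rows[0]
            kept.append(idx["variant_id"])
            survivors = []
            for r in rows[1:]:
                same = r["chromosome"] == idx["chromosome"]
                near = abs(r["position"] - idx["position"]) <= window_kb * 1000
                linked = ld_r2(panel, idx["variant_id"], r["variant_id"]) >= r2_thr
                if not (same and near and linked):
                    survivors.append(r)
            rows = survivors
        return kept

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_instances(self, seed):
        r = np.random.default_rng(seed)
        n = 15
        ids = [f"v{i}" for i in range(n)]
        cands = pd.DataFrame([
            _row(v, chrom=str(r.integers(1, 3)), pos=int(r.integers(1, 30_000_000)),
                 pval=float(10.0 ** r.uniform(-12, -8)))
            for v in ids
        ])
        pairs = {}
        for i in range(n):
            for j in range(i + 1, n):
                if r.random() < 0.4:
                    pairs[(ids[i], ids[j])] = float(r.random())
        panel = _r2_panel(ids, pairs)
        kept, _ = clump(cands, panel, 0.01, 10_000)
        assert list(kept["variant_id"]) == self._brute_force(cands, panel, 0.01, 10_000)

    def test_invariant_to_input_order(self, rng):
        cands = pd.DataFrame([
            _row(f"v{i}", pos=int(rng.integers(1, 5_000_000)),
                 pval=float(10.0 ** rng.uniform(-12, -8)))
            for i in range(10)
        ])
        ids = list(cands["variant_id"])
        pairs = {(a, b): float(rng.random()) for i, a in enumerate(ids)
                 for b in ids[i + 1:] if rng.random() < 0.5}
        panel = _r2_panel(ids, pairs)
        kept1, _ = clump(cands, panel)
        kept2, _ = clump(cands.sample(frac=1, random_state=0), panel)
        assert list(kept1["variant_id"]) == list(kept2["variant_id"])

    def test_retained_pairs_below_threshold_audit(self, rng):
        from mrscreen import ld_r2

        n = 12
        ids = [f"v{i}" for i in range(n)]
        cands = pd.DataFrame([
            _row(v, pos=int(rng.integers(1, 2_000_000)),
                 pval=float(10.0 ** rng.uniform(-12, -8)))
            for v in ids
        ])
        pairs = {(a, b): float(rng.random()) for i, a in enumerate(ids)
                 for b in ids[i + 1:]}
        panel = _r2_panel(ids, pairs)
        kept, _ = clump(cands, panel, 0.05, 10_000)
        kept_rows = kept.to_dict("records")
        for i, a in enumerate(kept_rows):
            for b in kept_rows[i + 1:]:
                if a["chromosome"] == b["chromosome"] and \
                        abs(a["position"] - b["position"]) <= 10_000_000:
                    assert ld_r2(panel, a["variant_id"], b["variant_id"]) < 0.05

    def test_uncovered_candidates_dropped_with_log(self):
        cands = pd.DataFrame([_row("a", pval=1e-10), _row("zz", pval=1e-9, pos=2000)])
        panel = _r2_panel(["a"], {})
        kept, dropped = clump(cands, panel)
        assert list(kept["variant_id"]) == ["a"]
        assert dropped == ["zz"]


class TestFindProxy:
    def _outcome(self, ids):
        return _dataset([_row(v, pos=1000 + i) for i, v in enumerate(ids)], name="out")

    def test_single_qualifying_candidate(self):
        panel = _r2_panel(["t", "p"], {("p", "t"): 0.95})
        assert find_proxy("t", self._outcome(["p"]), panel) == "p"

    def test_boundary_r2_is_excluded(self):
        panel = _r2_panel(["t", "p"], {("p", "t"): 0.8})
        assert find_proxy("t", self._outcome(["p"]), panel) is None

    def test_tie_break_by_distance_then_id(self):
        positions = {"t": ("1", 100_000), "p1": ("1", 105_000),
                     "p2": ("1", 108_000), "p3": ("1", 92_000)}
        panel = _r2_panel(
            ["t", "p1", "p2", "p3"],
            {("p1", "t"): 0.92, ("p2", "t"): 0.92, ("p3", "t"): 0.85},
            positions=positions,
        )
        # p1 and p2 tie on r2; p1 is 5 kb away vs 8 kb
        assert find_proxy("t", self._outcome(["p1", "p2", "p3"]), panel) == "p1"

    def test_target_not_in_panel_returns_none(self):
        panel = _r2_panel(["p"], {})
        assert find_proxy("t", self._outcome(["p"]), panel) is None


class TestPerSnpR2:
    @pytest.mark.parametrize(
        "eaf,beta,expected", [(0.5, 0.0, 0.0), (0.5, 0.1, 0.005), (0.2, 0.3, 0.0288)]
    )
    def test_direct_values(self, eaf, beta, expected):
        v = make_variant(eaf=eaf, beta=beta, pval=0.5 if beta == 0 else 1e-10)
        assert per_snp_r2(v) == pytest.approx(expected)

    def test_matches_simulated_genotype_variance(self, rng):
        # explained variance equals var(G) * beta^2 under Hardy-Weinberg
        eaf, beta = 0.27, 0.13
        g = rng.binomial(2, eaf, 400_000)
        empirical = g.var() * beta**2
        assert per_snp_r2(make_variant(eaf=eaf, beta=beta)) == pytest.approx(
            empirical, rel=0.02
        )

    def test_missing_eaf_raises(self):
        with pytest.raises(DomainError):
            per_snp_r2(make_variant(eaf=None))


class TestFStatistic:
    def test_printed_formula_example(self):
        res = f_statistic(0.01, 10, 10_000)
        assert res.f == pytest.approx((0.01 / 10) / (0.99 / 9989))
        assert res.f == pytest.approx(10.09, abs=0.005)
        assert res.strong

    def test_zero_r2_gives_zero_and_weak_flag(self):
        res = f_statistic(0.0, 5, 1000)
        assert res.f == 0.0 and not res.strong

    def test_independent_arithmetic(self):
        assert f_statistic(0.05, 1, 1000).f == pytest.approx(
            (0.05 / 1) / (0.95 / 998), abs=1e-12
        )

    @pytest.mark.parametrize("r2,k,n", [(1.0, 1, 100), (0.5, 10, 11), (-0.1, 1, 100)])
    def test_domain_errors(self, r2, k, n):
        with pytest.raises(DomainError):
            f_statistic(r2, k, n)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.001, 0.5),
        st.integers(1, 50),
        st.integers(200, 10**6),
        st.floats(1e-4, 0.1),
    )
    def test_monotonicity(self, r2, k, n, dr):
        # strictly increasing in r2 and n, strictly decreasing in k
        f0 = f_statistic(r2, k, n).f
        assert f_statistic(min(r2 + dr, 0.99), k, n).f > f0
        assert f_statistic(r2, k, n + 1000).f > f0
        assert f_statistic(r2, k + 1, n).f < f0
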