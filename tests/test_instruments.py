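"""Cis-window extraction, thresholding with fallback, greedy clumping,
proxy lookup."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vadmr.gwas_io import LDMatrix
from vadmr.instruments import (
    find_proxies,
    select_cis_window,
    select_genome_wide,
    threshold_and_clump,
)

from conftest import make_table


class TestCisWindow:
    def test_boundaries_inclusive(self, toy_target):
        df = make_table(
            [
                {"pos": toy_target.start - 500_000},  # exactly on edge
                {"pos": toy_target.start - 500_001},  # one bp outside
                {"pos": toy_target.end + 500_000},
                {"pos": toy_target.end + 500_001},
                {"pos": (toy_target.start + toy_target.end) // 2},
            ]
        )
        win = select_cis_window(df, toy_target)
        assert set(win["variant_id"]) == {"rs1", "rs3", "rs5"}

    def test_other_chromosome_excluded(self, toy_target):
        df = make_table([{"pos": toy_target.start, "chrom": "2"}])
        assert select_cis_window(df, toy_target).empty

    def test_counts(self, toy_target):
        inside = [{"pos": toy_target.start + i} for i in range(4)]
        outside = [{"pos": 99}, {"pos": 10**9}] * 3
        win = select_cis_window(make_table(inside + outside), toy_target)
        assert len(win) == 4


def _ld_from_pairs(ids, pairs):
    r = np.eye(len(ids))
    idx = {v: i for i, v in enumerate(ids)}
    for a, b, val in pairs:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = val
    # make PSD-safe for small examples
    lam = np.linalg.eigvalsh(r).min()
    if lam < 0:
        r = (r + (abs(lam) + 1e-9) * np.eye(len(ids))) / (1 + abs(lam) + 1e-9)
        np.fill_diagonal(r, 1.0)
    return LDMatrix(ids, r)


class TestThresholdAndClump:
    def test_worked_three_variant_example(self):
        # A most significant; B in tight LD with A; C independent, 600 kb off
        df = make_table(
            [
                {"variant_id": "A", "pos": 1_000_000, "pvalue": 1e-10},
                {"variant_id": "B", "pos": 1_001_000, "pvalue": 1e-9},
                {"variant_id": "C", "pos": 1_600_000, "pvalue": 1e-8},
            ]
        )
        df["variant_id"] = ["A", "B", "C"]
        ld = _ld_from_pairs(["A", "B", "C"], [("A", "B", np.sqrt(0.9))])
        sel = threshold_and_clump(df, ld)
        assert sel.variant_ids == ["A", "C"]
        assert sel.threshold_used == 5e-8
        assert (sel.n_before_clump, sel.n_after_clump) == (3, 2)

    def test_fallback_threshold_triggers(self):
        df = make_table([{"pvalue": 1e-6}, {"pvalue": 4e-5, "pos": 200}])
        sel = threshold_and_clump(df, None, missing_r2=0.0)
        assert sel.threshold_used == 5e-5
        assert sel.fallback_used

    def test_no_instruments_status(self):
        df = make_table([{"pvalue": 0.1}])
        sel = threshold_and_clump(df, None)
        assert sel.status == "no-instruments"
        assert sel.instruments.empty and sel.threshold_used is None

    def test_single_candidate_identity(self):
        df = make_table([{"pvalue": 1e-9}])
        sel = threshold_and_clump(df, None)
        assert sel.n_before_clump == sel.n_after_clump == 1

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [
            {"variant_id": f"v{i}", "pos": 1_000_000 + 1000 * i,
             "pvalue": float(p)}
            for i, p in enumerate(rng.uniform(1e-12, 1e-8, 8))
        ]
        df = make_table(rows)
        df["variant_id"] = [r["variant_id"] for r in rows]
        ids = list(df["variant_id"])
        ld = _ld_from_pairs(
            ids, [(a, b, 0.3) for a, b in itertools.combinations(ids[:4], 2)]
        )
        base = threshold_and_clump(df, ld, clump_r2=0.05)
        shuffled = threshold_and_clump(
            df.sample(frac=1, random_state=1), ld, clump_r2=0.05
        )
        assert base.variant_ids == shuffled.variant_ids

    def test_retained_pairs_satisfy_independence_rule(self):
        # every kept pair: r2 < threshold or distance > window
        rng = np.random.default_rng(3)
        n = 12
        ids = [f"v{i}" for i in range(n)]
        a = rng.normal(size=(n, n + 5))
        ld = LDMatrix(ids, np.corrcoef(a))
        rows = [
            {"variant_id": ids[i], "pos": 1_000_000 + 5_000 * i,
             "pvalue": float(p)}
            for i, p in enumerate(rng.uniform(1e-12, 1e-9, n))
        ]
        df = make_table(rows)
        df["variant_id"] = ids
        sel = threshold_and_clump(df, ld, clump_r2=0.1, clump_window_bp=30_000)
        kept = sel.instruments.set_index("variant_id")
        for a_id, b_id in itertools.combinations(sel.variant_ids, 2):
            dist = abs(int(kept.loc[a_id, "pos"]) - int(kept.loc[b_id, "pos"]))
            assert ld.r2(a_id, b_id) < 0.1 or dist > 30_000

    def test_missing_ld_pairs_conservative_by_default(self):
        df = make_table(
            [
                {"variant_id": "A", "pos": 1_000_000, "pvalue": 1e-10},
                {"variant_id": "B", "pos": 1_001_000, "pvalue": 1e-9},
            ]
        )
        df["variant_id"] = ["A", "B"]
        ld = _ld_from_pairs(["A"], [])  # B absent from the matrix
        assert threshold_and_clump(df, ld).variant_ids == ["A"]
        assert threshold_and_clump(df, ld, missing_r2=0.0).variant_ids == ["A", "B"]

    def test_relaxing_fallback_never_loses_instruments(self):
        rng = np.random.default_rng(8)
        rows = [
            {"variant_id": f"v{i}", "pos": 10**6 + 10**5 * i, "pvalue": float(p)}
            for i, p in enumerate(rng.uniform(1e-9, 1e-4, 10))
        ]
        df = make_table(rows)
        df["variant_id"] = [r["variant_id"] for r in rows]
        strict = threshold_and_clump(df, None, p_fallback=1e-6, missing_r2=0.0,
                                     clump_window_bp=1000)
        relaxed = threshold_and_clump(df, None, p_fallback=5e-5, missing_r2=0.0,
                                      clump_window_bp=1000)
        assert relaxed.n_after_clump >= strict.n_after_clump


class TestGenomeWide:
    def test_hits_on_distinct_chromosomes_both_kept(self):
        df = make_table(
            [
                {"chrom": "1", "pvalue": 1e-9},
                {"chrom": "2", "pvalue": 1e-9, "pos": 100},
            ]
        )
        sel = select_genome_wide(df, None)
        assert sel.n_after_clump == 2
        assert sel.mode == "genome-wide"

    def test_consistent_with_single_chromosome_clump(self):
        df = make_table(
            [
                {"variant_id": "A", "pos": 1_000_000, "pvalue": 1e-10},
                {"variant_id": "B", "pos": 1_001_000, "pvalue": 1e-9},
                {"variant_id": "C", "pos": 1_600_000, "pvalue": 1e-8},
            ]
        )
        df["variant_id"] = ["A", "B", "C"]
        ld = _ld_from_pairs(["A", "B", "C"], [("A", "B", np.sqrt(0.9))])
        cis = threshold_and_clump(df, ld)
        gw = select_genome_wide(df, {"1": ld})
        assert sorted(gw.variant_ids) == sorted(cis.variant_ids)

    def test_ld_pair_on_one_chromosome(self):
        df = make_table(
            [
                {"variant_id": "A", "chrom": "1", "pos": 10**6, "pvalue": 1e-10},
                {"variant_id": "B", "chrom": "1", "pos": 10**6 + 1000, "pvalue": 1e-9},
                {"variant_id": "C", "chrom": "2", "pos": 10**6, "pvalue": 1e-9},
            ]
        )
        df["variant_id"] = ["A", "B", "C"]
        ld1 = _ld_from_pairs(["A", "B"], [("A", "B", 0.95)])
        sel = select_genome_wide(df, {"1": ld1})
        assert sorted(sel.variant_ids) == ["A", "C"]


class TestProxies:
    def _ld(self):
        # factor-structured (hence PSD): m1, p1, p2 near-duplicates, far weak
        loadings = np.array([0.99, 0.97, 0.97, 0.3])
        r = np.outer(loadings, loadings)
        np.fill_diagonal(r, 1.0)
        return LDMatrix(["m1", "p1", "p2", "far"], r)

    def test_best_proxy_found(self):
        outcome = make_table([{"variant_id": "p1", "pos": 500}])
        outcome["variant_id"] = ["p1"]
        mapping, unproxied = find_proxies(["m1"], outcome, self._ld())
        assert mapping == {"m1": "p1"} and not unproxied

    def test_below_threshold_unproxied(self):
        outcome = make_table([{"variant_id": "far", "pos": 500}])
        outcome["variant_id"] = ["far"]
        mapping, unproxied = find_proxies(["m1"], outcome, self._ld())
        assert mapping == {} and unproxied == ["m1"]

    def test_tie_broken_by_position(self):
        outcome = make_table(
            [{"variant_id": "p2", "pos": 400}, {"variant_id": "p1", "pos": 500}]
        )
        outcome["variant_id"] = ["p2", "p1"]
        mapping, _ = find_proxies(["m1"], outcome, self._ld())
        assert mapping == {"m1": "p2"}
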