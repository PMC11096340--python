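"""Phosphopeptide merging, missingness filter, rank product, differential set."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aa_phenoscreen.phospho import (
    KEY_COLS,
    KO_COLS,
    WT_COLS,
    differential_set,
    filter_missing,
    merge_entries,
    rank_product_test,
    run_differential,
)
from aa_phenoscreen.simulate import simulate_phosphoproteome


def entry(seq="PEP1", prot="P1", sites="10", n_sites=1, sl=1,
          wt=(100.0, 100.0, 100.0), ko=(100.0, 100.0, 100.0)):
    d = {"sequence": seq, "protein": prot, "site_positions": sites,
         "n_sites": n_sites, "slice": sl}
    d.update(dict(zip(WT_COLS, wt)))
    d.update(dict(zip(KO_COLS, ko)))
    return d


class TestMerge:
    def test_componentwise_sum_with_missing(self):
        df = pd.DataFrame([
            entry(sl=1, wt=(100.0, 200.0, np.nan)),
            entry(sl=2, wt=(50.0, 50.0, 50.0)),
        ])
        merged = merge_entries(df)
        assert len(merged) == 1
        assert merged[WT_COLS].iloc[0].tolist() == [150.0, 250.0, 50.0]

    def test_single_entry_unchanged(self):
        df = pd.DataFrame([entry(wt=(1.0, 2.0, 3.0), ko=(4.0, 5.0, 6.0))])
        merged = merge_entries(df)
        assert merged[WT_COLS + KO_COLS].iloc[0].tolist() == [1, 2, 3, 4, 5, 6]

    def test_replicate_missing_only_if_missing_everywhere(self):
        df = pd.DataFrame([
            entry(sl=1, ko=(np.nan, 1.0, np.nan)),
            entry(sl=2, ko=(np.nan, 2.0, 4.0)),
        ])
        merged = merge_entries(df)
        ko = merged[KO_COLS].iloc[0]
        assert np.isnan(ko.iloc[0]) and ko.iloc[1] == 3.0 and ko.iloc[2] == 4.0

    def test_twenty_entry_fixture_counts_and_sums(self, rng):
        rows = []
        # 17 unique keys; keys 0..2 duplicated across two slices
        for i in range(17):
            rows.append(entry(seq=f"S{i}", prot=f"P{i}", sl=1,
                              wt=tuple(rng.uniform(10, 100, 3)),
                              ko=tuple(rng.uniform(10, 100, 3))))
        for i in range(3):
            rows.append(entry(seq=f"S{i}", prot=f"P{i}", sl=2,
                              wt=tuple(rng.uniform(10, 100, 3)),
                              ko=tuple(rng.uniform(10, 100, 3))))
        df = pd.DataFrame(rows)
        merged = merge_entries(df)
        assert len(merged) == 17
        # independent hand computation by explicit dict accumulation
        expect: dict = {}
        for r in rows:
            key = (r["sequence"], r["protein"], r["site_positions"])
            acc = expect.setdefault(key, dict.fromkeys(WT_COLS + KO_COLS, 0.0))
            for c in WT_COLS + KO_COLS:
                acc[c] += r[c]
        got = merged.set_index(["sequence", "protein", "site_positions"])
        for key, acc in expect.items():
            for c in WT_COLS + KO_COLS:
                assert got.loc[key, c] == pytest.approx(acc[c])

    def test_merge_is_idempotent_and_order_invariant(self, rng):
        rows = [entry(seq=f"S{i % 5}", prot=f"P{i % 5}", sl=i % 3 + 1,
                      wt=tuple(rng.uniform(1, 9, 3)), ko=tuple(rng.uniform(1, 9, 3)))
                for i in range(12)]
        df = pd.DataFrame(rows)
        once = merge_entries(df)
        twice = merge_entries(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = merge_entries(df.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(once, shuffled)

    def test_conflicting_site_count_is_a_data_error(self):
        df = pd.DataFrame([entry(n_sites=1), entry(n_sites=2, sl=2)])
        with pytest.raises(ValueError, match="n_sites"):
            merge_entries(df)


class TestFilterMissing:
    def test_two_missing_in_one_genotype_removes_entry(self):
        df = pd.DataFrame([entry(wt=(100.0, np.nan, np.nan))])
        assert len(filter_missing(df)) == 0

    def test_single_missing_is_allowed(self):
        df = pd.DataFrame([entry(wt=(100.0, np.nan, 120.0))])
        assert len(filter_missing(df)) == 1

    def test_complete_table_unchanged(self):
        df = pd.DataFrame([entry(seq=f"S{i}") for i in range(5)])
        out = filter_missing(df)
        assert len(out) == 5
        assert len(out.attrs["removed"]) == 0


def _toy_table(rng, n=10):
    rows = []
    for i in range(n):
        base = rng.uniform(50, 150)
        rows.append(entry(seq=f"S{i}", prot=f"P{i}",
                          wt=tuple(base * rng.lognormal(0, 0.2, 3)),
                          ko=tuple(base * rng.lognormal(0, 0.2, 3))))
    return pd.DataFrame(rows)


class TestRankProduct:
    def test_top_ranked_entry_has_minimal_rank_product(self, rng):
        df = _toy_table(rng, n=8)
        df.loc[0, KO_COLS] = 1e6  # ranked 1 in every up comparison
        res = rank_product_test(df, B=200, seed=0)
        assert res["rp_up"].iloc[0] == pytest.approx(1.0)
        assert res["p_up"].iloc[0] == min(res["p_up"])

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # 4 entries, complete 3v3 -> a fixed entry's null ranks are iid
        # uniform on {1..4} over the 3 replicate-pair comparisons; enumerate
        # the exact product law.
        rng = np.random.default_rng(42)
        df = _toy_table(rng, n=4)
        res = rank_product_test(df, B=4000, seed=1)
        counts = {1: 1}
        for _ in range(3):
            new = {}
            for prod, c in counts.items():
                for r in (1, 2, 3, 4):
                    new[prod * r] = new.get(prod * r, 0) + c
            counts = new
        total = 4 ** 3
        for i in range(4):
            rp_obs = res["rp_up"].iloc[i]
            prod_obs = rp_obs ** 3
            p_exact = sum(c for v, c in counts.items() if v <= prod_obs * (1 + 1e-9)) / total
            assert res["p_up"].iloc[i] == pytest.approx(p_exact, abs=0.03)

    def test_invariant_to_monotone_intensity_transform(self, rng):
        df = _toy_table(rng, n=8)
        res1 = rank_product_test(df, B=100, seed=3)
        df2 = df.copy()
        df2[WT_COLS + KO_COLS] = df2[WT_COLS + KO_COLS] ** 2  # monotone on R+
        res2 = rank_product_test(df2, B=100, seed=3)
        np.testing.assert_allclose(res1["rp_up"], res2["rp_up"])
        np.testing.assert_allclose(res1["p_down"], res2["p_down"])

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="B"):
            rank_product_test(_toy_table(rng), B=10)


class TestDifferentialSet:
    def _results(self, rows):
        df = pd.DataFrame(rows)
        for c in KEY_COLS + ["n_sites"]:
            if c not in df:
                df[c] = [f"X{i}" for i in range(len(df))] if c != "n_sites" else 1
        return df

    def test_ratio_and_p_gates(self):
        res = self._results([
            {"protein": "A", "ratio": 3.0, "p_up": 0.01, "p_down": 0.9},
            {"protein": "B", "ratio": 1.2, "p_up": 0.001, "p_down": 0.9},
            {"protein": "C", "ratio": 0.3, "p_up": 0.9, "p_down": 0.02},
            {"protein": "D", "ratio": 3.0, "p_up": 0.2, "p_down": 0.01},
        ])
        sel = differential_set(res)
        assert set(sel["protein"]) == {"A", "C"}  # D fails direction-matched p

    def test_protein_mode_collapses_accessions(self):
        res = self._results([
            {"protein": "A", "sequence": "s1", "ratio": 3.0, "p_up": 0.01, "p_down": 1.0},
            {"protein": "A", "sequence": "s2", "ratio": 4.0, "p_up": 0.02, "p_down": 1.0},
        ])
        assert len(differential_set(res, mode="protein")) == 1
        assert len(differential_set(res, mode="peptide")) == 2

    def test_planted_signal_recovered_with_low_false_discovery(self):
        # 20 seeds of a 200-entry table with 10 planted 4-fold entries
        fdps, sens = [], []
        for seed in range(10):
            table, truth = simulate_phosphoproteome(
                n_entries=200, n_true=10, effect_fold=4.0, missing_rate=0.05,
                seed=seed)
            diff = run_differential(table, B=200, seed=seed, mode="peptide")
            called = set(diff.selected["protein"])
            true = set(truth.loc[truth["is_true"], "protein"])
            tp = len(called & true)
            fdps.append((len(called) - tp) / max(len(called), 1))
            sens.append(tp / len(true))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdps) <= 0.05
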