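"""Differential phosphoproteomics: merge, missingness filter, rank product.

The input is an identified-phosphopeptide intensity table from a two-genotype
(WT vs KO) design with three biological replicates per genotype, acquired in
five gel slices. Processing follows three refinement steps:

1. entries from all gel slices are pooled;
2. identical phosphopeptides — same sequence, protein accession, and number
   and positions of phosphorylated residues — are merged by summing their
   per-replicate intensities (a replicate stays missing only if it is missing
   in every merged entry);
3. an entry is removed if either genotype has more than one missing value
   across its three replicates.

Differential abundance per direction is tested with the rank product: for
each replicate-pair comparison (KO_i vs WT_i, i = 1..3) the entries are
ranked by fold change, and the rank product is the geometric mean of an
entry's ranks over the comparisons. Because each comparison uses a disjoint
pair of replicates, the comparisons are independent under the null and the
permutation null of random rank matrices is exact:
p = (1 + #{permuted RP <= observed}) / (B + 1). The reported
differential set keeps entries whose mean KO/WT intensity ratio exceeds the
fold-change threshold (default 2, in either direction) with the
direction-matched permutation p below the p threshold (default 0.05).

Tables are plain pandas DataFrames with columns ``sequence, protein,
site_positions, n_sites, slice, WT_1..WT_3, KO_1..KO_3`` (NaN = missing);
``site_positions`` is a semicolon-joined list in files and a tuple in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

WT_COLS = ["WT_1", "WT_2", "WT_3"]
KO_COLS = ["KO_1", "KO_2", "KO_3"]
KEY_COLS = ["sequence", "protein", "site_positions"]
TABLE_COLS = KEY_COLS + ["n_sites", "slice"] + WT_COLS + KO_COLS


def _normalise_sites(v) -> str:
    if isinstance(v, str):
        parts = [p for p in v.split(";") if p != ""]
    else:
        parts = list(np.atleast_1d(v))
    return ";".join(str(int(p)) for p in parts)


def read_phospho_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TABLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"phospho table {path} missing column(s): {missing}")
    df = df.copy()
    df["site_positions"] = df["site_positions"].map(_normalise_sites)
    return df


def write_phospho_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def merge_entries(entries: pd.DataFrame) -> pd.DataFrame:
    """Merge identical phosphopeptides across gel slices by summing
    intensities componentwise; a replicate is missing in the merged entry only
    if missing in all contributing entries. Conflicting phospho-site counts
    under one key are a data error.
    """
    df = entries.copy()
    df["site_positions"] = df["site_positions"].map(_normalise_sites)
    n_sites_check = df.groupby(KEY_COLS)["n_sites"].nunique()
    bad = n_sites_check[n_sites_check > 1]
    if len(bad):
        raise ValueError(f"conflicting n_sites for identical key(s): {list(bad.index)[:5]}")
    agg = {c: lambda s: (np.nan if s.isna().all() else s.sum()) for c in WT_COLS + KO_COLS}
    agg["n_sites"] = "first"
    merged = df.groupby(KEY_COLS, sort=True, as_index=False).agg(agg)
    merged["slice"] = 0  # slices pooled
    return merged[KEY_COLS + ["n_sites", "slice"] + WT_COLS + KO_COLS]


def filter_missing(entries: pd.DataFrame, max_missing: int = 1) -> pd.DataFrame:
    """Drop entries with more than ``max_missing`` missing replicate values in
    either genotype; removals are recorded in ``df.attrs['removed']``."""
    wt_miss = entries[WT_COLS].isna().sum(axis=1)
    ko_miss = entries[KO_COLS].isna().sum(axis=1)
    keep = (wt_miss <= max_missing) & (ko_miss <= max_missing)
    out = entries[keep].reset_index(drop=True)
    removed = entries[~keep][KEY_COLS].copy()
    removed["reason"] = np.where(wt_miss[~keep] > max_missing, "WT missing > 1", "KO missing > 1")
    out.attrs["removed"] = removed.reset_index(drop=True)
    return out


def _rank_products(log_fc: np.ndarray, direction: str) -> np.ndarray:
    """Geometric mean of per-comparison fold-change ranks (NaN-aware).

    ``log_fc``: (n_entries, n_comparisons). Rank 1 = most up-regulated
    (direction 'up') or most down-regulated ('down') among entries with a
    value in that comparison.
    """
    z = log_fc if direction == "down" else -log_fc
    n_entries, n_comp = z.shape
    log_rp = np.zeros(n_entries)
    counts = np.zeros(n_entries, dtype=int)
    for j in range(n_comp):
        col = z[:, j]
        ok = ~np.isnan(col)
        if ok.sum() < 2:
            continue
        ranks = np.empty(ok.sum())
        order = np.argsort(col[ok], kind="stable")
        ranks[order] = np.arange(1, ok.sum() + 1)
        log_rp[ok] += np.log(ranks)
        counts[ok] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = np.exp(log_rp / counts)
    rp[counts == 0] = np.nan
    return rp


def _fold_change_matrix(entries: pd.DataFrame) -> np.ndarray:
    """log fold changes of the replicate-pair comparisons KO_i / WT_i
    (NaN where either replicate is missing)."""
    wt = entries[WT_COLS].to_numpy(dtype=float)
    ko = entries[KO_COLS].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(ko) - np.log(wt)


def rank_product_test(
    entries: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class rank-product test per entry and direction.

    The permutation null draws, for each of ``B`` replicates, an independent
    uniformly random rank assignment per comparison (the classic rank-product
    null, exact here because the replicate-pair comparisons use disjoint
    replicates); ``p = (1 + #{permuted RP <= observed}) / (B + 1)``. Entries
    with no complete replicate pair get NaN results.
    """
    if len(entries) < 2:
        raise ValueError("need >= 2 entries")
    if B < 100:
        raise ValueError("need B >= 100 permutations")
    rng = np.random.default_rng(seed)
    log_fc = _fold_change_matrix(entries)
    n, n_comp = log_fc.shape

    wt_mean = np.nanmean(entries[WT_COLS].to_numpy(dtype=float), axis=1)
    ko_mean = np.nanmean(entries[KO_COLS].to_numpy(dtype=float), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ko_mean / wt_mean

    out = entries[KEY_COLS + ["n_sites"]].copy()
    out["ratio"] = ratio
    valid_counts = (~np.isnan(log_fc)).sum(axis=0)
    for direction in ("up", "down"):
        rp_obs = _rank_products(log_fc, direction)
        # Null: per comparison, ranks are an independent uniform permutation of
        # the entries that carry a value in that comparison.
        exceed = np.zeros(n)
        valid_mask = ~np.isnan(log_fc)
        for b in range(B):
            log_rp = np.zeros(n)
            counts = np.zeros(n, dtype=int)
            for j in range(n_comp):
                ok = valid_mask[:, j]
                m = int(ok.sum())
                if m < 2:
                    continue
                perm = rng.permutation(m) + 1
                log_rp[ok] += np.log(perm)
                counts[ok] += 1
            with np.errstate(divide="ignore", invalid="ignore"):
                rp_b = np.exp(log_rp / counts)
            exceed += (rp_b <= rp_obs)
        p = (1.0 + exceed) / (B + 1.0)
        p[np.isnan(rp_obs)] = np.nan
        out[f"rp_{direction}"] = rp_obs
        out[f"p_{direction}"] = p
    out.attrs["n_comparisons_valid"] = valid_counts
    return out


def differential_set(
    results: pd.DataFrame,
    ratio_thresh: float = 2.0,
    p_thresh: float = 0.05,
    mode: str = "protein",
) -> pd.DataFrame:
    """Entries passing the fold-change and direction-matched p gates.

    An entry qualifies if its mean KO/WT ratio exceeds ``ratio_thresh`` with
    ``p_up < p_thresh``, or falls below ``1/ratio_thresh`` with
    ``p_down < p_thresh``. ``mode='protein'`` collapses to unique protein
    accessions (keeping each protein's most significant entry);
    ``mode='peptide'`` keeps one row per phosphopeptide.
    """
    if mode not in ("protein", "peptide"):
        raise ValueError(f"unknown mode {mode!r}")
    r = results["ratio"].to_numpy(dtype=float)
    up = (r > ratio_thresh) & (results["p_up"].to_numpy(dtype=float) < p_thresh)
    down = (r < 1.0 / ratio_thresh) & (results["p_down"].to_numpy(dtype=float) < p_thresh)
    sel = results[np.nan_to_num(up | down, nan=False).astype(bool)].copy()
    sel["direction"] = np.where(sel["ratio"] > 1.0, "up", "down")
    sel["p"] = np.where(sel["direction"] == "up", sel["p_up"], sel["p_down"])
    if mode == "protein":
        sel = sel.sort_values(["p", "protein"]).drop_duplicates("protein", keep="first")
    return sel.sort_values(["p", "protein"] + (["sequence"] if mode == "peptide" else [])).reset_index(drop=True)


@dataclass
class DifferentialResult:
    """Convenience bundle of the per-entry table and derived protein set."""

    results: pd.DataFrame
    selected: pd.DataFrame

    @property
    def proteins(self) -> list[str]:
        return sorted(self.selected["protein"].unique())


def run_differential(
    entries: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    ratio_thresh: float = 2.0,
    p_thresh: float = 0.05,
    mode: str = "protein",
) -> DifferentialResult:
    """Full phospho arm: merge -> missingness filter -> rank product -> gate."""
    merged = merge_entries(entries)
    kept = filter_missing(merged)
    results = rank_product_test(kept, B=B, seed=seed)
    selected = differential_set(results, ratio_thresh=ratio_thresh,
                                p_thresh=p_thresh, mode=mode)
    return DifferentialResult(results=results, selected=selected)
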