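"""Signalling-hub identification against a random background-network null.

Given a weighted undirected physical-interaction network, a differential
phosphoprotein set and the full phosphoproteome universe, a candidate protein
is scored by its number of interactions with the differential set. Candidate
hubs are proteins with either >= ``k_min`` (default 7) interactions or more
than ``k_high`` (default 3) high-weight interactions (weight strictly above
``w_high``, default 0.04).

Significance is assessed two ways:

* an empirical null: for each of B (default 1000) background replicates, a
  random protein set of the same size as the differential set is drawn from
  the universe (excluding the candidate itself) and the candidate's
  interaction count into the random set is recorded;
* the hypergeometric upper tail P(X >= k) with N = universe size, K = the
  candidate's degree within the universe, n = differential-set size — the
  analytic counterpart of the sampling null.

Benjamini-Hochberg adjustment across candidates is applied to the
hypergeometric p; the empirical p (resolution floor 1/(B+1)) is reported
alongside as the boxplot-style evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust


def read_network(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV (protein_a, protein_b, weight) into an undirected
    weighted graph; self-loops are rejected, duplicate pairs keep the first
    weight seen."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("protein_a", "protein_b", "weight"):
        if col not in df.columns:
            raise ValueError(f"network file {path} missing column {col!r}")
    g = nx.Graph()
    for a, b, w in df[["protein_a", "protein_b", "weight"]].itertuples(index=False):
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if w <= 0:
            raise ValueError(f"non-positive weight on edge ({a}, {b})")
        if not g.has_edge(a, b):
            g.add_edge(a, b, weight=float(w))
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    rows = [(a, b, d["weight"]) for a, b, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def induced_counts(
    network: nx.Graph,
    diff_set: Iterable[str],
    candidate: str,
    w_high: float = 0.04,
) -> tuple[int, int]:
    """(interaction count, strictly-high-weight interaction count) between the
    candidate and the differential set (excluding itself)."""
    if candidate not in network:
        raise KeyError(f"candidate {candidate!r} absent from network")
    targets = set(diff_set) - {candidate}
    count = 0
    high = 0
    for nbr, data in network[candidate].items():
        if nbr in targets:
            count += 1
            if data.get("weight", 0.0) > w_high:
                high += 1
    return count, high


def select_candidates(
    network: nx.Graph,
    diff_set: Iterable[str],
    k_min: int = 7,
    k_high: int = 3,
    w_high: float = 0.04,
    pool: Iterable[str] | None = None,
) -> list[str]:
    """Candidate hubs: proteins with >= ``k_min`` interactions with the
    differential set OR strictly more than ``k_high`` high-weight ones.

    The candidate pool defaults to the differential-set members present in
    the network; an optional ``pool`` (e.g. a disease-gene list) restricts it.
    """
    diff_set = set(diff_set)
    pool = set(pool) if pool is not None else diff_set
    selected = []
    for prot in sorted(pool):
        if prot not in network:
            continue
        count, high = induced_counts(network, diff_set, prot, w_high=w_high)
        if count >= k_min or high > k_high:
            selected.append(prot)
    return selected


def null_counts(
    network: nx.Graph,
    universe: Sequence[str],
    set_size: int,
    candidate: str,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Empirical background null: candidate's interaction count into ``B``
    uniformly drawn size-``set_size`` subsets of the universe (candidate
    excluded from sampling)."""
    if candidate not in network:
        raise KeyError(f"candidate {candidate!r} absent from network")
    pool = [u for u in universe if u != candidate]
    if set_size > len(pool):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(pool)}")
    rng = np.random.default_rng(seed)
    nbrs = set(network[candidate])
    is_nbr = np.fromiter((u in nbrs for u in pool), dtype=bool, count=len(pool))
    # vectorised sampling without replacement: n smallest random keys per row
    keys = rng.random((B, len(pool)))
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    return is_nbr[idx].sum(axis=1).astype(int)


def hub_significance(
    observed: int,
    null: np.ndarray,
    N: int,
    K: int,
    n: int,
) -> tuple[float, float]:
    """(hypergeometric upper-tail p, empirical p) for an observed count.

    ``N`` universe size, ``K`` candidate degree within the universe, ``n``
    differential-set size. p_hyper = P(X >= observed) for
    X ~ Hypergeometric(N, K, n); p_emp = (1 + #{null >= observed}) / (B + 1).
    """
    if observed > min(K, n):
        raise ValueError(f"observed count {observed} exceeds min(K={K}, n={n})")
    p_hyper = float(hypergeom.sf(observed - 1, N, K, n))
    null = np.asarray(null)
    p_emp = (1.0 + int((null >= observed).sum())) / (null.size + 1.0)
    return min(p_hyper, 1.0), p_emp


@dataclass
class HubResult:
    candidate: str
    observed_count: int
    high_weight_count: int
    degree_universe: int
    null_counts: np.ndarray
    p_hyper: float
    p_empirical: float
    p_adj: float = float("nan")
    selected: bool = False


def run_hub_analysis(
    network: nx.Graph,
    diff_set: Sequence[str],
    universe: Sequence[str],
    B: int = 1000,
    seed: int = 0,
    k_min: int = 7,
    k_high: int = 3,
    w_high: float = 0.04,
    candidate_pool: Sequence[str] | None = None,
    alpha: float = 0.05,
    compute_empirical: bool = True,
) -> pd.DataFrame:
    """Full hub arm over a candidate pool (default: the differential set).

    Returns one row per candidate with observed/high-weight counts, degree
    within the universe, hypergeometric and empirical p, and BH-adjusted
    ``p_adj`` (of the hypergeometric p) across candidates. ``selected`` flags
    candidates meeting the count criteria with ``p_adj < alpha``.
    """
    universe = [u for u in universe if u in network] + [u for u in universe if u not in network]
    universe_set = set(universe)
    diff_in = [d for d in diff_set if d in universe_set]
    n = len(set(diff_in))
    pool = list(candidate_pool) if candidate_pool is not None else sorted(set(diff_in))
    rows: list[HubResult] = []
    rng = np.random.default_rng(seed)
    for cand in pool:
        if cand not in network:
            continue
        obs, high = induced_counts(network, diff_set, cand, w_high=w_high)
        K = sum(1 for nbr in network[cand] if nbr in universe_set and nbr != cand)
        if compute_empirical:
            nc = null_counts(network, universe, min(n, len(universe_set) - 1), cand,
                             B=B, seed=int(rng.integers(2**31 - 1)))
        else:
            nc = np.zeros(0, dtype=int)
        p_h = float(hypergeom.sf(obs - 1, len(universe_set), K, n))
        p_e = ((1.0 + int((nc >= obs).sum())) / (nc.size + 1.0)) if nc.size else float("nan")
        rows.append(HubResult(cand, obs, high, K, nc, min(p_h, 1.0), p_e))
    if not rows:
        return pd.DataFrame(columns=["candidate", "observed_count", "high_weight_count",
                                     "degree_universe", "p_hyper", "p_empirical",
                                     "p_adj", "meets_criteria", "selected"])
    p_adj = bh_adjust(np.array([r.p_hyper for r in rows]))
    recs = []
    for r, pa in zip(rows, p_adj):
        meets = r.observed_count >= k_min or r.high_weight_count > k_high
        recs.append({
            "candidate": r.candidate,
            "observed_count": r.observed_count,
            "high_weight_count": r.high_weight_count,
            "degree_universe": r.degree_universe,
            "p_hyper": r.p_hyper,
            "p_empirical": r.p_empirical,
            "p_adj": float(pa),
            "meets_criteria": bool(meets),
            "selected": bool(meets and pa < alpha),
        })
    df = pd.DataFrame(recs)
    df.attrs["null_counts"] = {r.candidate: r.null_counts for r in rows}
    return df
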