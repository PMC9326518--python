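"""Shared fixtures: toy graphs, tiny matrices and brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from disimir import ExpressionMatrix
from disimir.network_inference import WeightedDirectedNetwork


@pytest.fixture
def toy_whole_network() -> WeightedDirectedNetwork:
    """The worked whole-network example: A has four children B, C, D, E;
    B and D each have one child, C has two, E and the grandchildren are
    leaves."""
    ids = ["A", "B", "C", "D", "E", "gB", "gC1", "gC2", "gD"]
    idx = {n: i for i, n in enumerate(ids)}
    w = np.zeros((9, 9))
    for s, t in [("A", "B"), ("A", "C"), ("A", "D"), ("A", "E"),
                 ("B", "gB"), ("C", "gC1"), ("C", "gC2"), ("D", "gD")]:
        w[idx[s], idx[t]] = 0.9
    return WeightedDirectedNetwork(ids, w)


@pytest.fixture
def toy_disease_network() -> WeightedDirectedNetwork:
    """The pruned disease-specific example: A keeps children B and D,
    B keeps one child E; D and E are leaves."""
    ids = ["A", "B", "D", "E"]
    idx = {n: i for i, n in enumerate(ids)}
    w = np.zeros((4, 4))
    for s, t in [("A", "B"), ("A", "D"), ("B", "E")]:
        w[idx[s], idx[t]] = 0.8
    return WeightedDirectedNetwork(ids, w)


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = rng.gamma(2.0, 2.0, size=(6, 12))
    return ExpressionMatrix([f"mir-{i}" for i in range(6)],
                            [f"s{j}" for j in range(12)], values)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive, loop-based implementations)

def mi_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Direct-summation MI in nats with the Miller-Madow term."""
    n = len(x)
    xs, ys = np.unique(x), np.unique(y)
    mi = 0.0
    kxy = 0
    for a in xs:
        for b in ys:
            pxy = np.mean((x == a) & (y == b))
            if pxy > 0:
                kxy += 1
                px = np.mean(x == a)
                py = np.mean(y == b)
                mi += pxy * np.log(pxy / (px * py))
    mm = (len(xs) + len(ys) - kxy - 1) / (2.0 * n)
    return max(0.0, mi + mm)


def aracne_oracle(mim: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """DPI pruning by explicit enumeration of all ordered triples."""
    m = mim.shape[0]
    out = mim.copy()
    np.fill_diagonal(out, 0.0)
    for i, j, k in itertools.combinations(range(m), 3):
        trio = sorted([(mim[i, j], (i, j)), (mim[i, k], (i, k)),
                       (mim[j, k], (j, k))])
        if trio[0][0] == 0:
            continue
        if trio[0][0] < trio[1][0] - eps:
            a, b = trio[0][1]
            out[a, b] = out[b, a] = 0.0
    return out


def influence_oracle(g: nx.DiGraph, m: str) -> float:
    """Influence via explicit unit-weight Dijkstra path enumeration."""
    dist = nx.single_source_dijkstra_path_length(g, m, weight=lambda *_: 1)
    total = 0.0
    for node, d in dist.items():
        nk = g.out_degree(node)
        if nk > 0:
            total += nk ** (1.0 / (d + 1))
    return total


def levenshtein_oracle(a: str, b: str) -> int:
    """Quadratic dynamic-programming edit distance."""
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    dp[:, 0] = np.arange(len(a) + 1)
    dp[0, :] = np.arange(len(b) + 1)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            dp[i, j] = min(dp[i - 1, j] + 1, dp[i, j - 1] + 1,
                           dp[i - 1, j - 1] + (a[i - 1] != b[j - 1]))
    return int(dp[len(a), len(b)])


def threshold_oracle(probs: np.ndarray, labels: np.ndarray,
                     min_fp: int) -> float:
    """Brute-force scan of every cutoff, mirroring the selection rule."""
    feasible = []
    unconstrained = []
    for cut in np.unique(probs):
        pred = probs >= cut
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        unconstrained.append((fp + fn, -cut))
        if fp >= min_fp:
            feasible.append((fp + fn, -cut))
    pool = feasible if feasible else unconstrained
    err, negcut = min(pool)
    return -negcut


def hypergeom_oracle(N: int, K: int, n: int, k: int) -> float:
    """Explicit combinatorial summation of the upper tail."""
    from math import comb
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)
               if n - j <= N - K) / total


def random_feature_table(n_rows: int, seed: int,
                         informative: bool = True) -> pd.DataFrame:
    """Small labelled table for classifier tests."""
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_rows) < 0.3).astype(int)
    x = rng.normal(size=(n_rows, 4))
    if informative:
        x[:, 2] += 3.0 * labels
    table = pd.DataFrame(
        x, columns=["disease_influence", "network_influence",
                    "conservation", "n_targets"],
        index=[f"mir-{i}" for i in range(n_rows)])
    table["is_associated"] = rng.random(n_rows) < 0.6
    table.loc[labels == 1, "is_associated"] = True
    table["label"] = labels
    return table
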