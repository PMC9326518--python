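"""Consensus miRNA-miRNA network inference.

Five networks are inferred from the expression matrix and combined:

* four information-theoretic methods (CLR, ARACNE, MRNET, MRNETB)
  operating on a shared mutual-information matrix estimated by
  equal-frequency discretization with the Miller-Madow bias correction;
* GENIE3, which fits one random-forest regression per target node and
  reads edge confidences off the predictor importances.

Each network is min-max scaled to [0, 1], the five are averaged
entrywise, and edges below the confidence threshold (default 0.7,
inclusive) are pruned, yielding the consensus influence network.  The
four MI-based methods are symmetric and contribute equal weight in both
directions; only GENIE3 injects directionality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MutualInformationMatrix", "WeightedDirectedNetwork", "ConsensusConfig",
    "discretize", "mutual_information_matrix", "clr", "aracne", "mrnet",
    "mrnetb", "genie3", "scale_network", "consensus", "consensus_network",
]


@dataclass
class MutualInformationMatrix:
    """Symmetric pairwise mutual information (nats) with zero diagonal."""

    mirna_ids: list[str]
    mim: np.ndarray

    def __post_init__(self) -> None:
        self.mim = np.asarray(self.mim, dtype=float)
        m = self.mim
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.mirna_ids):
            raise ValueError("MIM shape mismatch")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("MIM not symmetric")
        if (m < -1e-12).any():
            raise ValueError("MIM has negative entries")
        if np.abs(np.diag(m)).max(initial=0.0) > 1e-12:
            raise ValueError("MIM diagonal not zero")


@dataclass
class WeightedDirectedNetwork:
    """m x m edge-confidence matrix; entry [i, j] = i influences j."""

    mirna_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.mirna_ids)

    def edge_set(self) -> set[tuple[str, str]]:
        src, tgt = np.nonzero(self.weights)
        return {(self.mirna_ids[i], self.mirna_ids[j])
                for i, j in zip(src, tgt)}


@dataclass
class ConsensusConfig:
    """Tunables for the consensus inference step."""

    threshold: float = 0.7
    genie3_n_trees: int = 100
    genie3_k: str = "all"
    n_bins: int | str = "auto"
    aracne_eps: float = 0.0
    genie3_sample_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.genie3_k not in ("sqrt", "all"):
            raise ValueError("genie3_k must be 'sqrt' or 'all'")
        if self.aracne_eps < 0:
            raise ValueError("aracne_eps must be >= 0")


def discretize(expr: ExpressionMatrix | np.ndarray,
               n_bins: int | str = "auto") -> np.ndarray:
    """Equal-frequency discretization of each miRNA row.

    ``auto`` uses floor(sqrt(n_samples)) bins (minimum 2).  Ties are
    broken by stable rank order so the bins are always balanced to
    within one sample; a constant row collapses to bin 0 with a warning.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else \
        np.asarray(expr, dtype=float)
    n = values.shape[1]
    if n_bins == "auto":
        n_bins = max(2, int(np.floor(np.sqrt(n))))
    if not isinstance(n_bins, (int, np.integer)) or n_bins < 2:
        raise ValueError("n_bins must be an integer >= 2 or 'auto'")
    n_bins = min(int(n_bins), n)

    out = np.empty_like(values, dtype=np.int64)
    for r, row in enumerate(values):
        if np.ptp(row) == 0:
            logger.warning("constant expression row %d; all samples bin 0", r)
            out[r] = 0
            continue
        ranks = np.argsort(np.argsort(row, kind="stable"), kind="stable")
        out[r] = (ranks * n_bins) // n
    return out


def mutual_information_matrix(disc: np.ndarray,
                              mirna_ids: list[str] | None = None
                              ) -> MutualInformationMatrix:
    """Pairwise MI from the empirical joint, Miller-Madow corrected.

    For each pair the plug-in MI is corrected by
    (K_x + K_y - K_xy - 1) / (2n), where K are the occupied bin counts,
    then clipped at zero.  The diagonal is set to zero.
    """
    disc = np.asarray(disc)
    m, n = disc.shape
    if n < 3:
        raise ValueError("need at least 3 samples for MI estimation")
    if mirna_ids is None:
        mirna_ids = [f"m{i}" for i in range(m)]

    n_levels = int(disc.max()) + 1
    # one-hot encode once: counts via matrix products
    onehot = np.zeros((m, n_levels, n))
    rows = np.repeat(np.arange(m), n)
    onehot[rows, disc.ravel(), np.tile(np.arange(n), m)] = 1.0

    marg = onehot.sum(axis=2)  # m x levels
    k_marg = (marg > 0).sum(axis=1)
    h_marg = np.zeros(m)
    p = marg / n
    nz = p > 0
    h_marg = -np.where(nz, p * np.log(np.where(nz, p, 1.0)), 0.0).sum(axis=1)

    mim = np.zeros((m, m))
    for i in range(m):
        # joint counts of i with all j >= i in one product
        joint = np.einsum("ls,kms->kml", onehot[i], onehot[i:])
        pj = joint / n
        with np.errstate(divide="ignore", invalid="ignore"):
            h_joint = -np.where(pj > 0, pj * np.log(pj), 0.0).sum(axis=(1, 2))
        k_joint = (joint > 0).sum(axis=(1, 2))
        mi = h_marg[i] + h_marg[i:] - h_joint
        mm = (k_marg[i] + k_marg[i:] - k_joint - 1) / (2.0 * n)
        vals = np.clip(mi + mm, 0.0, None)
        mim[i, i:] = vals
        mim[i:, i] = vals
    np.fill_diagonal(mim, 0.0)
    return MutualInformationMatrix(mirna_ids, mim)


def clr(mim: MutualInformationMatrix) -> WeightedDirectedNetwork:
    """Context Likelihood of Relatedness.

    Each MI value is z-scored against the background of its row and of
    its column (mean/sd over off-diagonal entries, negative z clipped to
    0); the edge weight is sqrt(z_i^2 + z_j^2), symmetric.
    """
    m = mim.mim.shape[0]
    off = ~np.eye(m, dtype=bool)
    mu = np.array([mim.mim[i, off[i]].mean() for i in range(m)])
    sd = np.array([mim.mim[i, off[i]].std(ddof=0) for i in range(m)])
    z = np.zeros((m, m))
    for i in range(m):
        if sd[i] == 0:
            logger.warning("CLR: zero MI variance for row %d", i)
            continue
        z[i] = np.clip((mim.mim[i] - mu[i]) / sd[i], 0.0, None)
    w = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(w, 0.0)
    return WeightedDirectedNetwork(list(mim.mirna_ids), w)


def aracne(mim: MutualInformationMatrix,
           eps: float = 0.0) -> WeightedDirectedNetwork:
    """ARACNE: data-processing-inequality pruning of the MI network.

    In every triangle the weakest edge is removed if its MI is below
    the minimum of the other two minus ``eps``; surviving edges keep
    their MI as weight.
    """
    w = mim.mim.copy()
    m = w.shape[0]
    keep = w > 0
    for i in range(m):
        for j in range(i + 1, m):
            if not keep[i, j]:
                continue
            wij = w[i, j]
            # vectorized over the third vertex k
            lo = np.minimum(w[i], w[j])
            mask = (w[i] > 0) & (w[j] > 0) & (wij < lo - eps)
            mask[i] = mask[j] = False
            if mask.any():
                keep[i, j] = keep[j, i] = False
    out = np.where(keep, w, 0.0)
    np.fill_diagonal(out, 0.0)
    return WeightedDirectedNetwork(list(mim.mirna_ids), out)


def _mrmr_forward(mi_col: np.ndarray, red: np.ndarray,
                  target: int) -> np.ndarray:
    """Forward-selection MRMR scores for one target.

    Candidates are added greedily by relevance minus mean redundancy
    with the already-selected set; each variable's weight is its score
    at the moment of selection, floored at 0.
    """
    m = red.shape[0]
    candidates = [i for i in range(m) if i != target]
    selected: list[int] = []
    scores = np.zeros(m)
    red_sum = np.zeros(m)
    while candidates:
        if selected:
            s = mi_col[candidates] - red_sum[candidates] / len(selected)
        else:
            s = mi_col[candidates]
        best = int(np.argmax(s))
        i = candidates.pop(best)
        scores[i] = max(0.0, float(s[best]))
        selected.append(i)
        red_sum += red[i]
    return scores


def mrnet(mim: MutualInformationMatrix) -> WeightedDirectedNetwork:
    """MRNET: per-target forward-selection MRMR, symmetrized by max."""
    m = mim.mim.shape[0]
    w = np.zeros((m, m))
    for j in range(m):
        w[:, j] = _mrmr_forward(mim.mim[:, j], mim.mim, j)
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return WeightedDirectedNetwork(list(mim.mirna_ids), w)


def _mrnetb_target(mi_col: np.ndarray, red: np.ndarray, target: int,
                   max_swaps: int = 20) -> np.ndarray:
    """MRNETB selection for one target with incremental redundancy sums.

    ``red_sum[i]`` tracks the summed redundancy of i with the current
    subset; scores are relevance minus mean redundancy over the other
    members, so each add/remove is an O(m) update.
    """
    m = red.shape[0]
    in_subset = np.ones(m, dtype=bool)
    in_subset[target] = False
    size = m - 1
    red_sum = red[:, in_subset].sum(axis=1)

    def scores() -> np.ndarray:
        s = np.full(m, np.inf)
        if size == 1:
            s[in_subset] = mi_col[in_subset]
        else:
            # i's own diagonal term is 0, and red[i, i in subset] counts 0
            s[in_subset] = (mi_col[in_subset]
                            - red_sum[in_subset] / (size - 1))
        return s

    # backward elimination: drop the worst member while its score < 0
    while size > 1:
        s = scores()
        worst = int(np.argmin(s))
        if s[worst] >= 0:
            break
        in_subset[worst] = False
        red_sum -= red[worst]
        size -= 1

    # sequential replacement: swap an excluded variable for the worst
    # member whenever that raises the worst score (bounded scan count)
    for _ in range(max_swaps):
        s = scores()
        worst = int(np.argmin(np.where(in_subset, s, np.inf)))
        excluded = np.flatnonzero(~in_subset)
        excluded = excluded[excluded != target]
        if excluded.size == 0:
            break
        base = red_sum - red[worst]
        improved = False
        for e in excluded:
            # trial subset = subset - worst + e
            trial_sum = base + red[e]
            if size == 1:
                trial_min = mi_col[e]
            else:
                members = in_subset.copy()
                members[worst] = False
                members[e] = True
                t = mi_col[members] - trial_sum[members] / (size - 1)
                trial_min = t.min()
            if trial_min > s[worst] + 1e-12:
                in_subset[worst] = False
                in_subset[e] = True
                red_sum = trial_sum
                improved = True
                break
        if not improved:
            break

    s = scores()
    out = np.zeros(m)
    out[in_subset] = np.clip(s[in_subset], 0.0, None)
    return out


def mrnetb(mim: MutualInformationMatrix) -> WeightedDirectedNetwork:
    """MRNETB: MRMR by backward elimination plus sequential replacement.

    Per target, start from the full candidate set, repeatedly drop the
    worst-scoring variable while its score is negative, then try
    swapping excluded variables for the worst remaining member whenever
    that raises the subset's minimum score.  Weights are the final
    scores of the selected set, floored at 0, symmetrized by max.
    """
    m = mim.mim.shape[0]
    w = np.zeros((m, m))
    for j in range(m):
        w[:, j] = _mrnetb_target(mim.mim[:, j], mim.mim, j)
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return WeightedDirectedNetwork(list(mim.mirna_ids), w)


def genie3(expr: ExpressionMatrix, n_trees: int = 100, k: str = "all",
           seed: int = 0, sample_cap: int | None = None,
           min_samples_leaf: int = 5) -> WeightedDirectedNetwork:
    """GENIE3: random-forest importances as directed edge confidences.

    One regression problem per target miRNA: its expression row is
    predicted from all other rows, and the total variance-reduction
    importance of each predictor becomes the weight of the edge
    predictor -> target, normalized per target to sum 1.

    Tree growth stops at ``min_samples_leaf`` samples per leaf (default
    5): the deep, near-singleton splits of fully grown trees contribute
    noise rather than signal to the importances and dominate the
    runtime.
    """
    if n_trees < 10:
        raise ValueError("n_trees must be >= 10")
    values = expr.values
    m, n = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    if sample_cap is not None and sample_cap < n:
        cols = rng.choice(n, size=sample_cap, replace=False)
        values = values[:, cols]
        n = sample_cap
    max_features = "sqrt" if k == "sqrt" else 1.0
    w = np.zeros((m, m))
    for j in range(m):
        predictors = np.delete(np.arange(m), j)
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(2 ** 31)), n_jobs=1)
        rf.fit(values[predictors].T, values[j])
        imp = rf.feature_importances_
        total = imp.sum()
        if total > 0:
            w[predictors, j] = imp / total
    return WeightedDirectedNetwork(list(expr.mirna_ids), w)


def scale_network(net: WeightedDirectedNetwork) -> WeightedDirectedNetwork:
    """Min-max scale all off-diagonal weights to [0, 1].

    An all-zero network is returned unchanged; a constant nonzero
    network maps to all zeros (max = min) with a warning.
    """
    w = net.weights.copy()
    m = w.shape[0]
    off = ~np.eye(m, dtype=bool)
    lo, hi = w[off].min(), w[off].max()
    if hi == lo:
        if hi != 0:
            logger.warning("constant network weights; scaled to all zeros")
            w[off] = 0.0
        return WeightedDirectedNetwork(list(net.mirna_ids), w)
    w[off] = (w[off] - lo) / (hi - lo)
    return WeightedDirectedNetwork(list(net.mirna_ids), w)


def consensus(nets: list[WeightedDirectedNetwork],
              cfg: ConsensusConfig | None = None) -> WeightedDirectedNetwork:
    """Entrywise mean of the scaled networks, pruned at the threshold.

    The threshold comparison is inclusive: an averaged weight exactly at
    the threshold is retained.
    """
    cfg = cfg or ConsensusConfig()
    ids = nets[0].mirna_ids
    for net in nets[1:]:
        if net.mirna_ids != ids:
            raise ValueError("networks have mismatched miRNA id orderings")
    mean = np.mean([net.weights for net in nets], axis=0)
    mean[mean < cfg.threshold] = 0.0
    np.fill_diagonal(mean, 0.0)
    return WeightedDirectedNetwork(list(ids), mean)


def consensus_network(expr: ExpressionMatrix,
                      cfg: ConsensusConfig | None = None,
                      return_parts: bool = False):
    """Run all five methods on an expression matrix and combine them."""
    cfg = cfg or ConsensusConfig()
    disc = discretize(expr, cfg.n_bins)
    mim = mutual_information_matrix(disc, list(expr.mirna_ids))
    parts = {
        "clr": scale_network(clr(mim)),
        "mrnet": scale_network(mrnet(mim)),
        "mrnetb": scale_network(mrnetb(mim)),
        "aracne": scale_network(aracne(mim, cfg.aracne_eps)),
        "genie3": scale_network(genie3(
            expr, cfg.genie3_n_trees, cfg.genie3_k, cfg.seed,
            cfg.genie3_sample_cap)),
    }
    net = consensus(list(parts.values()), cfg)
    return (net, parts) if return_parts else net
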