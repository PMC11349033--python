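"""Network-level enrichment: block statistics, permutation FWER, reliability.

Given an edge weight map (from any of the estimation methods), the map is
Z-scored across edges, thresholded at |Z| > 2 and binarized into "strong"
edges. For every network block a 1-df chi-square statistic compares the
observed number of strong edges in the block to the count expected if strong
edges were spread uniformly over the connectome; a hypergeometric upper-tail
test is available as an alternative. Family-wise error over the blocks is
controlled by an age-shuffling permutation null: each permutation refits the
same estimation method on shuffled ages (functional networks are never
shuffled, preserving the covariance structure of the data), and the
max-statistic rule converts the observed chi-squares into FWER-controlled
p values. Day-to-day reliability of the significance calls is summarized by
the Matthews correlation coefficient, and edge-level stability by the
overlap-percentage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import BlockMap
from .edge_models import (
    EdgeWeightMap,
    FeatureSelectionConfig,
    LSVRConfig,
    _fit_one,
)
from .resampling import make_inner_folds

__all__ = [
    "EnrichmentConfig",
    "BlockStatistic",
    "PermutationNull",
    "ConfusionSummary",
    "zscore_binarize",
    "block_contingency",
    "chi_square_block",
    "hypergeometric_block_p",
    "observed_block_statistics",
    "permutation_null",
    "fwer_pvalues",
    "mcc_reliability",
    "overlap_percentage",
]


@dataclass
class EnrichmentConfig:
    """Knobs of the enrichment procedure.

    ``perm_train_frac`` controls the family-grouped subsample each
    permutation refits on, so null maps carry sampling variability
    comparable to the observed maps; ``perm_inner_reps`` > 1 averages that
    many refits per permutation (mirroring observed-map averaging at a cost
    of that many extra fits). ``tune_each_permutation=False`` reuses the
    penalty chosen on the observed fit for null LSVR fits.
    """

    z_threshold: float = 2.0
    test: str = "chi_square"  # or "hypergeometric"
    n_permutations: int = 1000
    perm_train_frac: float = 0.8
    perm_inner_reps: int = 1
    tune_each_permutation: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.test not in ("chi_square", "hypergeometric"):
            raise ValueError(f"unknown test '{self.test}'")


@dataclass
class BlockStatistic:
    """Contingency counts and significance for one network block."""

    block: tuple  # 1-based network pair (a, b)
    m: int  # edges in the block
    k: int  # strong edges in the block
    K: int  # strong edges in the connectome
    M: int  # edges in the connectome
    chi2: float
    nominal_p: float
    fwer_p: float | None = None


@dataclass
class PermutationNull:
    """Null chi-square values: one row per permutation, one column per block."""

    null_chi2: np.ndarray  # (J_perm, B)

    @property
    def max_per_permutation(self) -> np.ndarray:
        return self.null_chi2.max(axis=1)


@dataclass
class ConfusionSummary:
    """Block-level day-1 vs day-2 agreement (day 1 = truth, day 2 = call)."""

    tp: int
    tn: int
    fp: int
    fn: int
    mcc: float


def zscore_binarize(weight_map: EdgeWeightMap, z_threshold: float = 2.0) -> np.ndarray:
    """Binary strong-edge mask: |Z| > threshold after Z-scoring across edges.

    For feature-selected maps the Z-score is computed over selected edges
    only; unselected edges are never strong.
    """
    values = weight_map.values
    sel = weight_map.selected_mask
    pool = values[sel]
    if np.unique(pool).size < 2:
        raise ValueError("weight map is (near-)constant; Z-scoring undefined")
    sd = pool.std(ddof=0)
    if sd == 0:
        raise ValueError("zero spread across edges; Z-scoring undefined")
    z = (pool - pool.mean()) / sd
    mask = np.zeros(values.shape[0], dtype=bool)
    mask[np.nonzero(sel)[0]] = np.abs(z) > z_threshold
    return mask


def block_contingency(mask: np.ndarray, block_map: BlockMap):
    """Per-block (k, m) counts plus the global (K, M) margins."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != block_map.edge_count:
        raise ValueError("mask length must equal the edge count")
    b = block_map.block_count
    m = np.bincount(block_map.block_of_edge, minlength=b)
    k = np.bincount(block_map.block_of_edge, weights=mask, minlength=b).astype(np.int64)
    return k, m, int(mask.sum()), int(mask.shape[0])


def chi_square_block(k, m, K, M):
    """1-df chi-square of the 2x2 table {in/out of block} x {strong/not}.

    Expectations come from the margins (no continuity correction). A
    connectome with no strong edges (K=0, or all strong, K=M) carries no
    enrichment information: chi2 = 0, p = 1. Vectorized over blocks.
    """
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0) or np.any(m >= M):
        raise ValueError("block size m must satisfy 0 < m < M")
    if not 0 <= K <= M:
        raise ValueError("strong-edge count K must lie in [0, M]")
    if K == 0 or K == M:
        chi2 = np.zeros_like(k)
    else:
        obs = np.stack([k, m - k, K - k, (M - m) - (K - k)])
        exp = np.stack(
            [m * K / M, m * (M - K) / M, (M - m) * K / M, (M - m) * (M - K) / M]
        )
        chi2 = ((obs - exp) ** 2 / exp).sum(axis=0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(chi2 == 0, 1.0, p)
    if chi2.ndim == 0:
        return float(chi2), float(p)
    return chi2, p


def hypergeometric_block_p(k, m, K, M):
    """Upper-tail enrichment p: P(X >= k), X ~ Hypergeom(M, K, m)."""
    k = np.asarray(k)
    m = np.asarray(m)
    if np.any(m <= 0) or np.any(m >= M):
        raise ValueError("block size m must satisfy 0 < m < M")
    p = stats.hypergeom.sf(k - 1, M, K, m)
    if p.ndim == 0:
        return float(p)
    return p


def observed_block_statistics(
    weight_map: EdgeWeightMap,
    block_map: BlockMap,
    z_threshold: float = 2.0,
    test: str = "chi_square",
) -> list[BlockStatistic]:
    """Threshold a weight map and score every block."""
    mask = zscore_binarize(weight_map, z_threshold)
    k, m, K, M = block_contingency(mask, block_map)
    chi2, chi_p = chi_square_block(k, m, K, M)
    if test == "hypergeometric":
        nominal = hypergeometric_block_p(k, m, K, M)
    else:
        nominal = chi_p
    return [
        BlockStatistic(
            block=tuple(int(x) for x in block_map.block_pairs[b]),
            m=int(m[b]),
            k=int(k[b]),
            K=K,
            M=M,
            chi2=float(chi2[b]),
            nominal_p=float(nominal[b]),
        )
        for b in range(block_map.block_count)
    ]


def _grouped_subsample(family_ids, frac, rng):
    """Family-grouped subsample of about ``frac`` of the subjects."""
    n = family_ids.shape[0]
    target = int(round(frac * n))
    fams = rng.permutation(np.unique(family_ids))
    keep, size = [], 0
    for fam in fams:
        idx = np.nonzero(family_ids == fam)[0]
        keep.append(idx)
        size += idx.size
        if size >= target:
            break
    return np.sort(np.concatenate(keep))


def permutation_null(
    dataset,
    method: str,
    config: EnrichmentConfig,
    block_map: BlockMap,
    lsvr_config: LSVRConfig | None = None,
    fs_config: FeatureSelectionConfig | None = None,
    fixed_penalty: float | None = None,
) -> PermutationNull:
    """Age-shuffling null distribution of block chi-squares.

    Each permutation shuffles all ages, draws one family-grouped training
    subsample, refits the estimation method on it, Z-scores and binarizes
    the resulting map, and records the per-block chi-square. Functional
    networks are never shuffled. Reproducible from ``config.seed``.

    With ``config.tune_each_permutation`` off, LSVR null fits use
    ``fixed_penalty`` (typically the penalty chosen on the observed data)
    instead of re-running the inner CV.
    """
    lsvr_config = lsvr_config or LSVRConfig()
    fs_config = fs_config or FeatureSelectionConfig()
    if (
        method != "pearson"
        and not config.tune_each_permutation
        and fixed_penalty is not None
    ):
        lsvr_config = LSVRConfig(
            penalty_grid=(float(fixed_penalty),),
            epsilon=lsvr_config.epsilon,
            max_iter=lsvr_config.max_iter,
            tol=lsvr_config.tol,
        )
    b = block_map.block_count
    null = np.zeros((config.n_permutations, b))
    needs_lsvr = method != "pearson"

    seed_key = (
        [int(config.seed)] if np.ndim(config.seed) == 0
        else [int(s) for s in config.seed]
    )
    for perm in range(config.n_permutations):
        rng = np.random.default_rng(seed_key + [7919, perm])
        y = rng.permutation(dataset.ages)
        chi_acc = np.zeros(b)
        for rep in range(config.perm_inner_reps):
            idx = _grouped_subsample(dataset.family_ids, config.perm_train_frac, rng)
            x_tr, y_tr = dataset.edges[idx], y[idx]
            folds = None
            if needs_lsvr and config.tune_each_permutation:
                folds = make_inner_folds(
                    np.arange(idx.size), dataset.family_ids[idx], k=5,
                    grouped=True, rng=rng,
                )
            wmap, _ = _fit_one(
                x_tr, y_tr, method, folds, lsvr_config, fs_config, perm
            )
            try:
                mask = zscore_binarize(wmap, config.z_threshold)
            except ValueError:
                continue  # degenerate null map: contributes zeros
            k, m, K, M = block_contingency(mask, block_map)
            chi2, _ = chi_square_block(k, m, K, M)
            chi_acc += chi2
        null[perm] = chi_acc / config.perm_inner_reps
    return PermutationNull(null)


def fwer_pvalues(observed, null: PermutationNull) -> np.ndarray:
    """Max-statistic FWER p values with the add-one convention.

    ``fwer_p(b) = (1 + #{perms: max_b' null chi2 >= observed chi2(b)})
    / (J_perm + 1)``; a zero observed statistic maps to p = 1.
    """
    if isinstance(observed, (list, tuple)) and observed and isinstance(
        observed[0], BlockStatistic
    ):
        obs = np.array([s.chi2 for s in observed])
    else:
        obs = np.asarray(observed, dtype=float)
    maxima = null.max_per_permutation
    j = maxima.shape[0]
    if j == 0:
        raise ValueError("empty permutation null")
    count = (maxima[:, None] >= obs[None, :]).sum(axis=0)
    p = (1.0 + count) / (j + 1.0)
    p = np.where(obs == 0, 1.0, p)
    if isinstance(observed, (list, tuple)) and observed and isinstance(
        observed[0], BlockStatistic
    ):
        for s, pv in zip(observed, p):
            s.fwer_p = float(pv)
    return p


def mcc_reliability(sig_day1: np.ndarray, sig_day2: np.ndarray) -> ConfusionSummary:
    """Matthews correlation of the two days' block significance calls.

    Day 1 defines truth, day 2 the prediction. Any zero marginal makes the
    MCC denominator vanish; it is defined as 0 in that case.
    """
    s1 = np.asarray(sig_day1, dtype=bool)
    s2 = np.asarray(sig_day2, dtype=bool)
    if s1.shape != s2.shape:
        raise ValueError("the two significance masks must have equal length")
    tp = int(np.sum(s1 & s2))
    tn = int(np.sum(~s1 & ~s2))
    fp = int(np.sum(~s1 & s2))
    fn = int(np.sum(s1 & ~s2))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn, mcc=float(mcc))


def overlap_percentage(masks) -> np.ndarray:
    """Per-edge fraction of repetition masks (across both days) that are
    strong; denominator = total number of masks supplied."""
    masks = np.asarray(masks, dtype=float)
    if masks.ndim != 2 or masks.shape[0] == 0:
        raise ValueError("need a nonempty stack of edge masks")
    return masks.mean(axis=0)
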