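"""Rank-based comparison of cord-blood and follow-up serum proteomes.

Cord serum and later follow-up serum differ so strongly in composition
that their quantification batches are processed separately; absolute
intensities are therefore not comparable across the two sample types
and all cross-comparisons here operate on within-sample intensity ranks
(rank 1 = most intense protein), which are invariant to any monotone
per-sample transformation or normalization.

Three analyses are provided:

- within-sample intensity ranking with tie-averaging;
- a paired rank-product test on cord-minus-follow-up rank differences,
  with permutation-based (or, for tiny instances, exact) percentage of
  false prediction (pfp);
- per-protein Spearman correlations across subjects between cord and
  follow-up levels, with Benjamini-Hochberg adjustment over the pooled
  family of (protein, timepoint) tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product as _iterproduct

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankProductResult",
    "CorrelationResult",
    "intensity_ranks",
    "rank_product_test",
    "cord_followup_correlation",
    "bh_adjust",
]


def intensity_ranks(matrix: pd.DataFrame) -> pd.DataFrame:
    """Within-sample descending ranks with tie-averaging.

    Rank 1 is the most intense protein in the sample; missing values
    stay missing and are excluded from the within-sample ranking, so
    non-missing ranks form a tie-averaged permutation of ``1..m``.
    """
    return matrix.rank(axis=0, ascending=False, na_option="keep")


@dataclass
class RankProductResult:
    """Outcome of the paired rank-product test, both directions.

    ``table`` has one row per protein with columns ``rp_up``/``rp_down``
    (geometric-mean ranks; up = higher in cord), ``pfp_up``/``pfp_down``,
    the combined ``direction`` ("up", "down" or "ns") and
    ``significant`` at the stored ``alpha``.
    """

    table: pd.DataFrame
    n_pairs: int
    n_permutations: int | None  # None when pfp was computed exactly
    alpha: float
    seed: int | None


def _pfp(rp_obs: np.ndarray, null_values: np.ndarray,
         n_null_datasets: float) -> np.ndarray:
    """Percentage of false prediction for observed rank products.

    For each protein, the expected number of null rank products at
    least as extreme (small) as its own, divided by the observed number
    at least as extreme, with monotonicity in rank-product order
    enforced by a running maximum.
    """
    null_sorted = np.sort(null_values)
    order = np.argsort(rp_obs, kind="stable")
    pfp = np.empty_like(rp_obs)
    m = len(rp_obs)
    # rank products recomputed along different floating-point paths can
    # differ in the last bits; count "at least as extreme" with a small
    # relative tolerance so exact ties are never missed
    thresh = rp_obs[order] * (1.0 + 1e-9)
    exp_fp = np.searchsorted(null_sorted, thresh, side="right") \
        / n_null_datasets
    observed = np.searchsorted(np.sort(rp_obs), thresh, side="right")
    vals = exp_fp / observed
    vals = np.maximum.accumulate(vals)
    pfp[order] = vals
    return pfp


def _exact_null(m: int, k: int) -> tuple[np.ndarray, float]:
    """Exhaustive null rank products for m proteins, k pairs.

    Under the exchangeable null each protein's rank in each pair is
    uniform on ``1..m`` and independent across pairs, so the expected
    count of null rank products below a threshold in one dataset of m
    proteins is ``m * P(RP <= t)``; enumerating all ``m^k`` rank tuples
    yields that probability exactly. Returned as a pool of ``m^k``
    values with an effective dataset count of ``m^(k-1)`` so that
    ``searchsorted / count`` reproduces ``m * P(RP <= t)``.
    """
    tuples = np.array(list(_iterproduct(range(1, m + 1), repeat=k)), float)
    rps = np.exp(np.mean(np.log(tuples), axis=1))
    return rps, float(m ** (k - 1))


def _normalized_rank_rp(ranks: np.ndarray, m_per_pair: np.ndarray,
                        present: np.ndarray) -> np.ndarray:
    """Rank product from within-pair ranks with missingness.

    Ranks are normalized to ``r / m_pair`` (so pairs with different
    numbers of quantified proteins are comparable) and geometrically
    averaged over the pairs where the protein is present. For complete
    data this is the plain geometric-mean rank scaled by ``1/m``, which
    leaves pfp unchanged.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(present, np.log(ranks / m_per_pair[None, :]), 0.0)
    return np.exp(logs.sum(axis=1) / present.sum(axis=1))


def rank_product_test(cord: pd.DataFrame, followup: pd.DataFrame,
                      pairs: list | None = None, B: int = 10_000,
                      seed: int = 0, alpha: float = 0.05,
                      exact: bool | None = None,
                      min_pair_fraction: float = 0.5) -> RankProductResult:
    """Paired rank-product test between cord and follow-up matrices.

    Both matrices are proteins x samples with columns keyed by subject;
    ``pairs`` selects the subjects present in both (default: the column
    intersection, in cord order). Per subject, the within-pair
    difference ``cord - followup`` of each protein is ranked across the
    proteins quantified in that pair (descending difference = rank 1
    for the ``up`` direction, ascending for ``down``); ranks are
    normalized by the pair's protein count and the rank product is
    their geometric mean across the pairs where the protein is present.
    Proteins present in fewer than ``min_pair_fraction`` of pairs are
    dropped with a warning.

    Percentage of false prediction comes from ``B`` within-pair
    permutations of the observed ranks (seeded, missingness pattern
    preserved), or from exhaustive enumeration when ``exact=True``
    (chosen automatically for complete instances with
    ``m^k <= 100_000``).
    """
    if pairs is None:
        pairs = [c for c in cord.columns if c in set(followup.columns)]
    else:
        missing = [p for p in pairs
                   if p not in cord.columns or p not in followup.columns]
        if missing:
            warnings.warn(f"unpaired subjects excluded: {missing}")
            pairs = [p for p in pairs if p not in missing]
    if not pairs:
        raise ValueError("no paired subjects between the two matrices")

    common = cord.index.intersection(followup.index)
    diffs = cord.loc[common, pairs].to_numpy(float) \
        - followup.loc[common, pairs].to_numpy(float)
    present = np.isfinite(diffs)
    enough = present.mean(axis=1) >= min_pair_fraction
    if not enough.all():
        warnings.warn(f"{(~enough).sum()} proteins dropped: present in "
                      f"< {min_pair_fraction:.0%} of pairs")
    proteins = common[enough]
    diffs = diffs[enough]
    present = present[enough]
    m, k = diffs.shape
    if m < 2:
        raise ValueError("need >=2 proteins with complete pairs")
    complete = bool(present.all())

    # within-pair ranks of the differences; rank 1 = largest difference
    ranks_up = pd.DataFrame(diffs).rank(axis=0, ascending=False).to_numpy()
    m_per_pair = present.sum(axis=0).astype(float)
    ranks_down = np.where(present, m_per_pair[None, :] + 1 - ranks_up,
                          np.nan)
    rp_up = _normalized_rank_rp(ranks_up, m_per_pair, present)
    rp_down = _normalized_rank_rp(ranks_down, m_per_pair, present)

    if exact is None:
        exact = complete and m**k <= 100_000
    if exact:
        if not complete:
            raise ValueError("exact enumeration requires complete pairs")
        null_pool, n_null = _exact_null(m, k)
        null_pool = null_pool / m  # normalized-rank scale
        n_perm = None
        pfp_up = _pfp(rp_up, null_pool, n_null)
        pfp_down = _pfp(rp_down, null_pool, n_null)
    else:
        if B < 1000:
            warnings.warn(f"B={B} permutations is low; recommend >=1000")
        rng = np.random.default_rng(seed)
        # B null datasets: permute observed normalized ranks within each
        # pair among the proteins present there (missingness preserved)
        logs = np.zeros((B, m))
        counts = present.sum(axis=1).astype(float)
        for j in range(k):
            rows = np.flatnonzero(present[:, j])
            u = np.log(ranks_up[rows, j] / m_per_pair[j])
            perm = np.argsort(rng.random((B, len(rows))), axis=1)
            logs[:, rows] += u[perm]
        null_pool = np.exp(logs / counts[None, :]).ravel()
        n_null = float(B)
        n_perm = B
        pfp_up = _pfp(rp_up, null_pool, n_null)
        # the permuted normalized up-ranks are exchangeable with the
        # down-ranks under the null, so one pool serves both directions
        pfp_down = _pfp(rp_down, null_pool, n_null)

    direction = np.where(
        (pfp_up < alpha) & (rp_up < rp_down), "up",
        np.where((pfp_down < alpha) & (rp_down < rp_up), "down", "ns"))
    table = pd.DataFrame({
        "rp_up": rp_up, "rp_down": rp_down,
        "pfp_up": pfp_up, "pfp_down": pfp_down,
        "direction": direction,
        "significant": direction != "ns",
    }, index=proteins)
    return RankProductResult(table=table, n_pairs=k, n_permutations=n_perm,
                             alpha=alpha, seed=None if exact else seed)


@dataclass
class CorrelationResult:
    """Spearman correlations of cord vs follow-up levels across subjects."""

    table: pd.DataFrame  # protein, timepoint, n, rho, p, q, significant
    fdr: float


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        pv = p[ok]
        m = len(pv)
        order = np.argsort(pv, kind="stable")
        q = pv[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        q = np.minimum(q, 1.0)
        adj = np.empty(m)
        adj[order] = q
        out[ok] = adj
    return out


def cord_followup_correlation(cord: pd.DataFrame,
                              followup_by_timepoint: dict[object, pd.DataFrame],
                              min_subjects: int = 5,
                              fdr: float = 0.1) -> CorrelationResult:
    """Spearman rank correlation of cord vs follow-up values per protein.

    For every protein and follow-up timepoint with at least
    ``min_subjects`` subjects carrying both a cord and a follow-up
    value, computes Spearman rho across subjects with a two-sided
    p-value; all tests are pooled into one family for BH adjustment and
    flagged at ``q < fdr``. Constant vectors leave rho undefined
    (reported as missing, excluded from the family).
    """
    rows = []
    for tp, fu in followup_by_timepoint.items():
        subjects = [s for s in cord.columns if s in set(fu.columns)]
        proteins = cord.index.intersection(fu.index)
        for prot in proteins:
            a = cord.loc[prot, subjects].to_numpy(float)
            b = fu.loc[prot, subjects].to_numpy(float)
            ok = np.isfinite(a) & np.isfinite(b)
            n = int(ok.sum())
            if n < min_subjects:
                continue
            av, bv = a[ok], b[ok]
            if np.all(av == av[0]) or np.all(bv == bv[0]):
                rows.append({"protein": prot, "timepoint": tp, "n": n,
                             "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(av, bv)
            rows.append({"protein": prot, "timepoint": tp, "n": n,
                         "rho": float(rho), "p": float(p)})
    table = pd.DataFrame(
        rows, columns=["protein", "timepoint", "n", "rho", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["significant"] = table["q"] < fdr
    return CorrelationResult(table=table, fdr=fdr)
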