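"""Hit selection, profile clustering and rank-product statistics on dDSS.

Works on a drugs x pairs matrix of differential drug sensitivity scores
(dDSS = DSS(resistant) - DSS(parental)). A drug is a *hit* for a pair when
its dDSS strictly exceeds +cutoff (sensitizing) or falls strictly below
-cutoff (co-resistant); the default cutoff of 5 score units sits in the tail
of typical dDSS distributions. Consistency of a drug's differential response
across resistant/parental pairs is tested with the rank product: the
geometric mean of the drug's per-pair ranks, calibrated by permuting ranks
within each pair and corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "select_hits",
    "ClusterResult",
    "cluster_profiles",
    "rank_product",
    "overlap_summary",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("sensitizing", "co-resistant")


def select_hits(ddss: pd.DataFrame, cutoff: float = 5.0):
    """Select per-pair hit drugs at a strict |dDSS| > cutoff.

    Returns
    -------
    (hits, omitted)
        ``hits``: long table (drug_id, pair_id, ddss, direction, cutoff),
        direction "sensitizing" for dDSS > cutoff, "co-resistant" for
        dDSS < -cutoff; values at exactly +/-cutoff are not hits.
        ``omitted``: drugs whose |dDSS| stays below the cutoff in every
        pair (dropped from heatmap displays).
    """
    if not np.isfinite(ddss.to_numpy(float)[~ddss.isna().to_numpy()]).all():
        raise ValueError("dDSS matrix contains non-finite values")
    long = ddss.stack().rename("ddss").reset_index()
    long.columns = ["drug_id", "pair_id", "ddss"]
    sens = long[long.ddss > cutoff].assign(direction="sensitizing")
    cores = long[long.ddss < -cutoff].assign(direction="co-resistant")
    hits = pd.concat([sens, cores], ignore_index=True).sort_values(
        ["pair_id", "direction", "drug_id"], ignore_index=True
    )
    hits["cutoff"] = cutoff
    max_abs = ddss.abs().max(axis=1)
    omitted = list(max_abs.index[max_abs < cutoff])
    return hits, omitted


@dataclass
class ClusterResult:
    """Complete-linkage clustering of a dDSS matrix, both axes."""

    drug_linkage: np.ndarray
    sample_linkage: np.ndarray
    drug_order: list
    sample_order: list
    ordered: pd.DataFrame  # matrix reordered by both dendrograms
    drug_distance: pd.DataFrame


def _spearman_distance(mat: np.ndarray) -> np.ndarray:
    """1 - Spearman rho between rows; undefined rows get max distance 2."""
    n = mat.shape[0]
    ranks = np.apply_along_axis(rankdata, 1, mat)  # average ranks for ties
    sd = ranks.std(axis=1)
    constant = sd == 0
    d = np.full((n, n), 2.0)
    ok = ~constant
    if ok.sum() >= 2:
        r = np.corrcoef(ranks[ok])
        d_ok = 1.0 - r
        d[np.ix_(ok, ok)] = d_ok
    np.fill_diagonal(d, 0.0)
    if constant.any():
        logger.warning(
            "%d constant drug profile(s): Spearman undefined, distance set to 2.0",
            int(constant.sum()),
        )
    # numerical symmetry for squareform
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_profiles(ddss: pd.DataFrame) -> ClusterResult:
    """Unsupervised hierarchical complete-linkage clustering of dDSS profiles.

    Drugs are compared by 1 - Spearman correlation of their per-pair
    profiles; samples (pairs) by Euclidean distance of their per-drug
    profiles. Leaf order is the deterministic scipy ordering for the given
    input order.
    """
    if ddss.shape[0] < 2 or ddss.shape[1] < 2:
        raise ValueError("need >= 2 drugs and >= 2 pairs to cluster")
    mat = ddss.to_numpy(float)
    if np.isnan(mat).any():
        raise ValueError("dDSS matrix has missing values; drop or impute first")
    ddrug = _spearman_distance(mat)
    drug_link = sch.linkage(squareform(ddrug, checks=False), method="complete")
    sample_link = sch.linkage(pdist(mat.T, metric="euclidean"), method="complete")
    drug_order = [ddss.index[i] for i in sch.leaves_list(drug_link)]
    sample_order = [ddss.columns[i] for i in sch.leaves_list(sample_link)]
    ordered = ddss.loc[drug_order, sample_order]
    return ClusterResult(
        drug_linkage=drug_link,
        sample_linkage=sample_link,
        drug_order=drug_order,
        sample_order=sample_order,
        ordered=ordered,
        drug_distance=pd.DataFrame(ddrug, index=ddss.index, columns=ddss.index),
    )


def _rank_matrix(ddss: pd.DataFrame, direction: str) -> np.ndarray:
    """Per-pair drug ranks: rank 1 = strongest in the given direction."""
    mat = ddss.to_numpy(float)
    sign = -1.0 if direction == "sensitizing" else 1.0
    return np.apply_along_axis(rankdata, 0, sign * mat)  # ties -> average


def rank_product(
    ddss: pd.DataFrame,
    direction: str,
    n_permutations: int = 10_000,
    seed: int | None = None,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Rank-product test for consistently differential drugs across pairs.

    Per pair, drugs are ranked by dDSS (descending for "sensitizing",
    ascending for "co-resistant"; ties get average ranks). RP is the
    geometric mean of a drug's ranks. The p-value is permutation-based:
    within each pair the observed rank column is shuffled independently,
    p = (1 + #{permuted RP <= observed}) / (B + 1). q-values are
    Benjamini-Hochberg across the direction's drugs; q < 0.05 is the
    conventional significance call.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if ddss.shape[1] < 2:
        raise ValueError("rank product needs >= 2 pairs")
    if n_permutations < 1:
        raise ValueError("need >= 1 permutation")
    keep = ddss.dropna(axis=0)
    dropped = set(ddss.index) - set(keep.index)
    if dropped:
        logger.warning("excluding %d drug(s) with missing dDSS: %s", len(dropped), sorted(dropped))
    if keep.shape[0] < 2:
        raise ValueError("need >= 2 drugs with complete profiles")

    ranks = _rank_matrix(keep, direction)  # (n_drugs, k)
    n, k = ranks.shape
    log_rp_obs = np.log(ranks).sum(axis=1) / k
    rng = np.random.default_rng(seed)

    counts = np.zeros(n, dtype=np.int64)
    # chunked to bound memory at large B
    chunk = max(1, min(n_permutations, 20_000_000 // max(n, 1)))
    done = 0
    log_ranks = np.log(ranks)
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perm_sum = np.zeros((b, n))
        for j in range(k):
            col = log_ranks[:, j]
            idx = np.argsort(rng.random((b, n)), axis=1)  # b independent shuffles
            perm_sum += col[idx]
        counts += (perm_sum / k <= log_rp_obs[None, :]).sum(axis=0)
        done += b

    p = (1.0 + counts) / (n_permutations + 1.0)
    q = multipletests(p, method=fdr_method)[1]
    out = pd.DataFrame(
        {
            "drug_id": keep.index,
            "direction": direction,
            "rank_product": np.exp(log_rp_obs),
            "p_value": p,
            "q_value": q,
            "n_permutations": n_permutations,
        }
    )
    for j, pair in enumerate(keep.columns):
        out[f"rank_{pair}"] = ranks[:, j]
    return out.sort_values("rank_product", ignore_index=True)


def overlap_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """Venn-style overlap of per-pair hit sets, by direction.

    For every direction and every non-empty combination of pairs, reports
    the drugs hit in all pairs of the combination (intersection) and the
    drugs hit in exactly that combination (exclusive region).
    """
    rows = []
    for direction in DIRECTIONS:
        sub = hits[hits.direction == direction]
        sets = {p: set(g.drug_id) for p, g in sub.groupby("pair_id")}
        pairs = sorted(sets)
        for r in range(1, len(pairs) + 1):
            for combo in combinations(pairs, r):
                inter = set.intersection(*(sets[p] for p in combo))
                others = set().union(*(sets[p] for p in pairs if p not in combo)) if len(combo) < len(pairs) else set()
                exclusive = inter - others
                rows.append(
                    {
                        "direction": direction,
                        "pairs": "&".join(combo),
                        "n_pairs": r,
                        "intersection_size": len(inter),
                        "exclusive_size": len(exclusive),
                        "intersection": ";".join(sorted(map(str, inter))),
                        "exclusive": ";".join(sorted(map(str, exclusive))),
                    }
                )
    return pd.DataFrame(rows)
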