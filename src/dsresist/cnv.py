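"""Exome off-target copy-number pipeline: counts -> log2 ratios -> segments -> gene calls.

Copy number is inferred from capture-region read counts of a resistant
(sample) / parental (reference) pair. Capture regions closer than 76 bp are
merged; per-region abundance is RPKM (reads per kilobase of region per
million mapped reads) and approximate coverage is count * read_length /
region_length. Regions below 25x coverage in either member are dropped, the
remaining log2(RPKM ratio) track is segmented per chromosome with circular
binary segmentation (CBS), and genes receive the segment value via an
"extreme" assignment rule before categorical calling at fixed log2 limits:
<= -1.2 homozygous deletion, <= -0.4 heterozygous deletion, >= +0.5 gain,
>= +1.3 amplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "merge_regions",
    "region_metrics",
    "build_log2_track",
    "Segment",
    "cbs_segment",
    "segments_frame",
    "CallThresholds",
    "gene_copy_call",
]

logger = logging.getLogger(__name__)

MERGE_GAP_BP = 76
MIN_COVERAGE = 25.0
LOG2_EPSILON = 0.01  # RPKM pseudo-value guarding log2(0)


def merge_regions(regions: pd.DataFrame, gap_bp: int = MERGE_GAP_BP) -> pd.DataFrame:
    """Merge capture target regions separated by less than ``gap_bp``.

    Intervals are BED-style 0-based half-open. The merge is strict: a gap of
    exactly ``gap_bp`` is kept separate. Idempotent; output regions get
    sequential ``region_id`` values of the form ``chrom:start-end``.
    """
    req = {"chrom", "start", "end"}
    if not req <= set(regions.columns):
        raise ValueError(f"regions need columns {sorted(req)}")
    if (regions.end <= regions.start).any():
        bad = regions[regions.end <= regions.start]
        raise ValueError(f"malformed intervals (end <= start): {len(bad)} rows")
    rows = []
    for chrom, grp in regions.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_start = cur_end = None
        for start, end in zip(grp.start, grp.end):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start - cur_end < gap_bp:  # strictly less than -> merge
                cur_end = max(cur_end, end)
            else:
                rows.append((chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["region_id"] = [f"{c}:{s}-{e}" for c, s, e in zip(out.chrom, out.start, out.end)]
    return out


def region_metrics(
    counts: pd.DataFrame,
    regions: pd.DataFrame,
    total_mapped_reads: int | None = None,
    read_length_bp: int = 100,
) -> pd.DataFrame:
    """Per-region RPKM and approximate coverage from read counts.

    RPKM = count / ((length/1000) * (total/1e6)); coverage(x) = count *
    read_length / length. ``total_mapped_reads`` defaults to the sum of the
    supplied counts (on-target total).
    """
    df = regions.merge(counts[["region_id", "count"]], on="region_id", how="left", validate="1:1")
    if df["count"].isna().any():
        raise ValueError("counts missing for some regions")
    if read_length_bp <= 0:
        raise ValueError("read_length_bp must be positive")
    length = (df.end - df.start).to_numpy(float)
    if (length <= 0).any():
        raise ValueError("zero-length region")
    total = float(total_mapped_reads if total_mapped_reads is not None else df["count"].sum())
    if total <= 0:
        raise ValueError("total_mapped_reads must be positive")
    c = df["count"].to_numpy(float)
    df["rpkm"] = c / ((length / 1e3) * (total / 1e6))
    df["coverage"] = c * read_length_bp / length
    return df


def build_log2_track(
    sample_metrics: pd.DataFrame,
    reference_metrics: pd.DataFrame,
    min_coverage: float = MIN_COVERAGE,
    epsilon: float = LOG2_EPSILON,
    median_center: bool = False,
) -> pd.DataFrame:
    """Per-region log2(sample RPKM / reference RPKM) with the coverage filter.

    Regions with coverage below ``min_coverage`` in *either* member of the
    pair are removed (a ratio is unreliable if either side is). A pseudo-RPKM
    ``epsilon`` guards against log2(0).
    """
    s = sample_metrics.set_index("region_id")
    r = reference_metrics.set_index("region_id")
    if not s.index.equals(r.index):
        raise ValueError("sample and reference metrics must cover identical regions")
    keep = (s.coverage >= min_coverage) & (r.coverage >= min_coverage)
    track = s.loc[keep, ["chrom", "start", "end"]].copy()
    track["rpkm_sample"] = s.loc[keep, "rpkm"]
    track["rpkm_reference"] = r.loc[keep, "rpkm"]
    track["coverage_sample"] = s.loc[keep, "coverage"]
    track["coverage_reference"] = r.loc[keep, "coverage"]
    track["log2_ratio"] = np.log2((track.rpkm_sample + epsilon) / (track.rpkm_reference + epsilon))
    if median_center:
        track["log2_ratio"] -= track["log2_ratio"].median()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("coverage filter removed %d/%d regions", n_drop, len(keep))
    for chrom in s.chrom.unique():
        if chrom not in set(track.chrom):
            logger.warning("chromosome %s: no region passed the coverage filter", chrom)
    return track.reset_index()


@dataclass
class Segment:
    """A constant-mean run of consecutive retained regions."""

    chrom: str
    start_index: int  # first region index within the chromosome (inclusive)
    end_index: int  # past-the-end region index
    start: int  # genomic bp of first region start
    end: int  # genomic bp of last region end
    mean_log2: float
    n_regions: int
    p_value: float | None  # permutation p of the split that created it


def _arc_tstats(x: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """|t| between arc (i, j] and its complement, for all candidate arcs."""
    n = len(x)
    p = np.concatenate(([0.0], np.cumsum(x)))
    q = np.concatenate(([0.0], np.cumsum(x * x)))
    k = (j_idx - i_idx).astype(float)
    s_arc = p[j_idx] - p[i_idx]
    ss_arc = q[j_idx] - q[i_idx]
    nk = n - k
    s_rest = p[n] - s_arc
    ss_rest = q[n] - ss_arc
    var = (ss_arc - s_arc**2 / k) + (ss_rest - s_rest**2 / nk)
    var = np.maximum(var / (n - 2), 0.0)
    se = np.sqrt(var * (1.0 / k + 1.0 / nk))
    diff = np.abs(s_arc / k - s_rest / nk)
    # cancellation dust on (near-)constant data is not a real mean shift
    tol = 1e-10 * (np.abs(x).max() + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff > tol, np.inf, 0.0))
    return t


def _candidate_arcs(n: int, min_width: int):
    i_list, j_list = [], []
    for w in range(min_width, n - min_width + 1):
        i = np.arange(0, n - w + 1)
        i_list.append(i)
        j_list.append(i + w)
    if not i_list:
        return None, None
    return np.concatenate(i_list), np.concatenate(j_list)


def _split_once(x, alpha, n_permutations, rng, min_width):
    """Best circular-arc split of x; returns (i, j, p) if significant else None."""
    n = len(x)
    if np.ptp(x) == 0.0:
        return None
    i_idx, j_idx = _candidate_arcs(n, min_width)
    if i_idx is None:
        return None
    t = _arc_tstats(x, i_idx, j_idx)
    best = int(np.argmax(t))
    t_obs = t[best]
    if not np.isfinite(t_obs) and t_obs > 0:
        return int(i_idx[best]), int(j_idx[best]), 1.0 / (n_permutations + 1.0)
    if t_obs == 0.0:
        return None
    # permutation null of the max statistic; early stop once p >= alpha is certain
    reject_limit = int(np.ceil(alpha * (n_permutations + 1) - 1))
    count = 0
    for b in range(n_permutations):
        xp = rng.permutation(x)
        if _arc_tstats(xp, i_idx, j_idx).max() >= t_obs:
            count += 1
            if count > reject_limit:
                return None
    p = (1.0 + count) / (n_permutations + 1.0)
    if p < alpha:
        return int(i_idx[best]), int(j_idx[best]), p
    return None


def cbs_segment(
    track: pd.DataFrame,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int | None = None,
    min_width: int = 2,
) -> list[Segment]:
    """Circular binary segmentation of the log2 track, per chromosome.

    Recursively finds the arc (i, j] maximizing the two-sample t-statistic
    between arc and complement, accepts the split when its permutation
    p-value (B shuffles of region order within the segment) is below
    ``alpha``, and recurses on the resulting pieces. Segments narrower than
    ``min_width`` regions are never created. Deterministic given ``seed``.
    No pruning/undo heuristic is applied.
    """
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom, grp in track.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        x = grp.log2_ratio.to_numpy(float)
        starts = grp.start.to_numpy()
        ends = grp.end.to_numpy()
        pieces = [(0, len(x), None)]  # (lo, hi, p of split that made it)
        final = []
        while pieces:
            lo, hi, pval = pieces.pop()
            sub = x[lo:hi]
            res = _split_once(sub, alpha, n_permutations, rng, min_width) if hi - lo >= 2 * min_width else None
            if res is None:
                final.append((lo, hi, pval))
                continue
            i, j, p = res
            cuts = [lo, lo + i, lo + j, hi]
            for a, b in zip(cuts, cuts[1:]):
                if b > a:
                    pieces.append((a, b, p))
        for lo, hi, pval in sorted(final):
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start_index=lo,
                    end_index=hi,
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    mean_log2=float(x[lo:hi].mean()),
                    n_regions=hi - lo,
                    p_value=pval,
                )
            )
    return segments


def segments_frame(segments: list[Segment], sample_id: str = "sample") -> pd.DataFrame:
    """SEG-style table of CBS segments."""
    return pd.DataFrame(
        {
            "sample": sample_id,
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_regions": [s.n_regions for s in segments],
            "mean_log2": [s.mean_log2 for s in segments],
        }
    )


@dataclass(frozen=True)
class CallThresholds:
    """log2 limits for categorical copy-number calls (all inclusive)."""

    homozygous_deletion: float = -1.2
    heterozygous_deletion: float = -0.4
    gain: float = 0.5
    amplification: float = 1.3
    extreme_low: float = -0.6  # segment value pulling the gene to the minimum
    extreme_high: float = 0.5  # segment value pulling the gene to the maximum


def _categorize(v: float, th: CallThresholds) -> str:
    if v <= th.homozygous_deletion:
        return "homozygous_deletion"
    if v <= th.heterozygous_deletion:
        return "heterozygous_deletion"
    if v >= th.amplification:
        return "amplification"
    if v >= th.gain:
        return "gain"
    return "neutral"


def gene_copy_call(
    genes: pd.DataFrame,
    segments: list[Segment] | pd.DataFrame,
    thresholds: CallThresholds = CallThresholds(),
) -> pd.DataFrame:
    """Gene-level log2 assignment and categorical copy-number call.

    A gene overlapping (>= 1 bp) a single segment takes its mean log2. Over
    multiple segments an extreme rule applies: if any overlapped segment is
    <= extreme_low, the gene takes the *lowest* segment value; if any is
    >= extreme_high, the *highest*; otherwise the median of the overlapped
    values. A gene overlapping both an extreme-low and an extreme-high
    segment is contradictory under that rule; we assign the value of larger
    absolute magnitude (tie -> the deletion) and flag it. Genes with no
    overlapping segment yield no call.
    """
    if isinstance(segments, list):
        seg = segments_frame(segments)
    else:
        seg = segments.copy()
    rows = []
    seg_by_chrom = {c: g for c, g in seg.groupby("chrom")}
    for gene in genes.itertuples(index=False):
        sub = seg_by_chrom.get(gene.chrom)
        if sub is None:
            logger.info("gene %s: no segments on %s", gene.gene_id, gene.chrom)
            continue
        ov = sub[(sub.start < gene.end) & (sub.end > gene.start)]
        if ov.empty:
            logger.info("gene %s: overlaps no segment", gene.gene_id)
            continue
        vals = ov.mean_log2.to_numpy(float)
        has_low = bool((vals <= thresholds.extreme_low).any())
        has_high = bool((vals >= thresholds.extreme_high).any())
        conflict = False
        if has_low and has_high:
            conflict = True
            vmin, vmax = vals.min(), vals.max()
            assigned = vmin if abs(vmin) >= abs(vmax) else vmax
        elif has_low:
            assigned = vals.min()
        elif has_high:
            assigned = vals.max()
        else:
            assigned = float(np.median(vals))
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "start": gene.start,
                "end": gene.end,
                "assigned_log2": float(assigned),
                "category": _categorize(float(assigned), thresholds),
                "n_overlapping_segments": len(ov),
                "extreme_conflict": conflict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "assigned_log2",
            "category", "n_overlapping_segments", "extreme_conflict",
        ],
    )
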