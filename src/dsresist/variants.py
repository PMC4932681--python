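"""Somatic point-mutation statistic and post-calling filters on paired counts.

Variants come as paired allele-count rows (parental line as the matched
"normal", resistant line as the "tumor"). The somatic statistic is a
one-tailed Fisher's exact test for alt-allele enrichment in the resistant
sample, computed as an exact hypergeometric tail. Downstream filtering
mirrors standard somatic-calling practice on such tables: minimum depths
(normal >= 8, tumor >= 6), minimum resistant-sample VAF (>= 0.05), a strand
bias filter, removal of known population (dbSNP-style) variants and of
non-protein-altering effect classes. Variants with p < 0.05 and resistant
VAF > 0.30 are flagged high confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["FilterParams", "somatic_test", "somatic_test_table", "apply_filters"]

logger = logging.getLogger(__name__)

#: protein-altering effect classes retained by the non-synonymous filter
NONSYNONYMOUS = {
    "missense",
    "nonsense",
    "splice_site",
    "frameshift",
    "inframe_indel",
    "start_lost",
    "stop_lost",
    "stop_gained",
}

#: classes positively known to be silent/non-coding, removed by the filter
SILENT = {
    "synonymous",
    "intron",
    "intergenic",
    "utr_5",
    "utr_3",
    "upstream",
    "downstream",
    "noncoding",
}


def somatic_test(
    normal_ref: int, normal_alt: int, tumor_ref: int, tumor_alt: int
) -> float:
    """One-tailed Fisher's exact p for alt enrichment in the tumor sample.

    Exact hypergeometric upper tail on the 2x2 table
    [[normal_ref, normal_alt], [tumor_ref, tumor_alt]]:
    p = P(X >= tumor_alt) where X is the number of alt reads falling in the
    tumor sample under random assignment given the margins.
    """
    counts = (normal_ref, normal_alt, tumor_ref, tumor_alt)
    if any(c < 0 for c in counts):
        raise ValueError("allele counts must be non-negative")
    if normal_ref + normal_alt == 0 or tumor_ref + tumor_alt == 0:
        raise ValueError("total reads must be positive in both samples")
    total = sum(counts)
    alt_total = normal_alt + tumor_alt
    tumor_total = tumor_ref + tumor_alt
    return float(hypergeom.sf(tumor_alt - 1, total, alt_total, tumor_total))


def somatic_test_table(df: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`somatic_test` over a variant table."""
    nr = df.normal_ref.to_numpy(int)
    na = df.normal_alt.to_numpy(int)
    tr = df.tumor_ref.to_numpy(int)
    ta = df.tumor_alt.to_numpy(int)
    if (nr + na == 0).any() or (tr + ta == 0).any():
        raise ValueError("total reads must be positive in both samples")
    if (np.concatenate([nr, na, tr, ta]) < 0).any():
        raise ValueError("allele counts must be non-negative")
    return hypergeom.sf(ta - 1, nr + na + tr + ta, na + ta, tr + ta)


@dataclass
class FilterParams:
    """Thresholds of the sequential somatic-variant filter chain."""

    min_coverage_normal: int = 8
    min_coverage_tumor: int = 6
    min_var_freq: float = 0.05  # resistant-sample VAF, inclusive
    strand_fraction: float = 0.90  # > this fraction on one strand is biased
    strand_min_alt: int = 4  # bias only assessed at >= this many alt reads
    high_conf_p: float = 0.05  # strict <
    high_conf_vaf: float = 0.30  # strict >
    blacklist: frozenset = field(default_factory=frozenset)  # (chrom, pos, ref, alt)


def apply_filters(records: pd.DataFrame, params: FilterParams = FilterParams()):
    """Run the sequential somatic filter chain with per-step tallies.

    Steps, in order: (1) normal depth >= min_coverage_normal; (2) tumor
    depth >= min_coverage_tumor; (3) tumor VAF >= min_var_freq; (4) strand
    bias (removed if > strand_fraction of tumor alt reads sit on one strand
    and alt reads >= strand_min_alt); (5) dbSNP-listed variants removed;
    (6) known silent effect classes removed (unknown classes are retained
    and logged); (7) optional blacklist. Depth is ref + alt. The surviving
    records get ``somatic_p``, ``tumor_vaf``, ``filter_status`` = "PASS" and
    a ``high_confidence`` flag (p < 0.05 and VAF > 0.30).

    Returns
    -------
    (passed, tally)
        ``passed``: surviving annotated records; ``tally``: ordered dict of
        step -> number removed, plus input/output totals.
    """
    df = records.copy()
    n_in = len(df)
    df["normal_depth"] = df.normal_ref + df.normal_alt
    df["tumor_depth"] = df.tumor_ref + df.tumor_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        df["tumor_vaf"] = np.where(
            df.tumor_depth > 0, df.tumor_alt / df.tumor_depth, 0.0
        )
    if "somatic_p" not in df.columns or df["somatic_p"].isna().any():
        ok = (df.normal_depth > 0) & (df.tumor_depth > 0)
        p = np.ones(len(df))
        if ok.any():
            p[ok.to_numpy()] = somatic_test_table(df[ok])
        df["somatic_p"] = p

    tally: dict[str, int] = {"input": n_in}

    def step(name: str, keep: pd.Series) -> None:
        nonlocal df
        tally[name] = int((~keep).sum())
        df = df[keep]

    step("min_coverage_normal", df.normal_depth >= params.min_coverage_normal)
    step("min_coverage_tumor", df.tumor_depth >= params.min_coverage_tumor)
    step("min_var_freq", df.tumor_vaf >= params.min_var_freq)

    if {"tumor_alt_fwd", "tumor_alt_rev"} <= set(df.columns):
        alt = df.tumor_alt_fwd + df.tumor_alt_rev
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(alt > 0, np.maximum(df.tumor_alt_fwd, df.tumor_alt_rev) / alt, 0.0)
        biased = (frac > params.strand_fraction) & (alt >= params.strand_min_alt)
        step("strand_filter", ~pd.Series(biased, index=df.index))
    else:
        tally["strand_filter"] = 0

    step("dbsnp", ~df.in_dbsnp.astype(bool))

    known = df.effect_class.isin(NONSYNONYMOUS | SILENT)
    unknown = df.loc[~known, "effect_class"].unique()
    if len(unknown):
        logger.warning("unclassified effect classes retained: %s", sorted(map(str, unknown)))
    step("effect_class", ~df.effect_class.isin(SILENT))

    if params.blacklist:
        key = list(zip(df.chrom, df.pos, df.ref, df.alt))
        step("blacklist", ~pd.Series([k in params.blacklist for k in key], index=df.index))
    else:
        tally["blacklist"] = 0

    df = df.copy()
    df["filter_status"] = "PASS"
    df["high_confidence"] = (df.somatic_p < params.high_conf_p) & (
        df.tumor_vaf > params.high_conf_vaf
    )
    tally["output"] = len(df)
    return df.reset_index(drop=True), tally
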