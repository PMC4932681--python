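"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data a tamoxifen-resistance pharmacogenomic
study consumes, at desk scale and with explicit truth objects:

* a 384-well viability screen: five concentrations per drug spanning a
  10,000-fold range, vehicle (negative) and full-kill (positive) control
  wells, raw signals from a 4PL inhibition curve plus multiplicative noise;
* an exome capture read-count pair (parental reference vs resistant sample)
  with piecewise-constant embedded copy-number segments and a paired
  somatic/germline variant table with strand-resolved allele counts;
* a drug-target bioactivity table whose designated specific targets are
  recoverable by construction under the KIBA threshold rule.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose_response import logistic4

__all__ = [
    "ScreenConfig",
    "ScreenTruth",
    "default_screen_truth",
    "paired_screen_truth",
    "generate_screen",
    "ExomeConfig",
    "GenomeTruth",
    "generate_exome_pair",
    "BioactivityConfig",
    "BioactivityTruth",
    "generate_bioactivity",
]

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24


def _well_names():
    return [f"{r}{c:02d}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]


@dataclass(frozen=True)
class ScreenConfig:
    """Layout and noise model of a synthetic multi-dose viability screen."""

    concentrations: tuple = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5)  # molar, 10^4 range
    noise_cv: float = 0.05  # multiplicative noise, typical luminescence CV
    neg_mean: float = 100_000.0  # vehicle-control raw signal
    pos_mean: float = 5_000.0  # full-kill control raw signal
    drugs_per_plate: int = 72  # 72*5 + 16 + 8 = 384 wells
    n_neg_ctrl: int = 16
    n_pos_ctrl: int = 8

    def validate(self) -> None:
        c = np.asarray(self.concentrations, float)
        if len(c) != 5:
            raise ValueError("exactly 5 concentrations per drug")
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")
        if not np.isclose(c.max() / c.min(), 1e4):
            raise ValueError("max/min concentration ratio must be 10^4")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.neg_mean <= self.pos_mean:
            raise ValueError("negative-control mean must exceed positive-control mean")
        if self.drugs_per_plate * 5 + self.n_neg_ctrl + self.n_pos_ctrl > 384:
            raise ValueError("plate layout exceeds 384 wells")


@dataclass
class ScreenTruth:
    """True 4PL parameters behind a generated screen."""

    params: pd.DataFrame  # drug_id, cell_line_id, bottom, top, log10_ic50, hill_slope
    config: ScreenConfig
    seed: int

    def validate(self) -> None:
        if (self.params.bottom > self.params.top).any():
            raise ValueError("bottom must be <= top")
        if (self.params.hill_slope <= 0).any():
            raise ValueError("hill slopes must be positive")


def default_screen_truth(
    n_drugs: int = 279,
    cell_lines=("parental", "resistant"),
    config: ScreenConfig = ScreenConfig(),
    seed: int = 0,
) -> ScreenTruth:
    """Random screen truth: a drug library with a realistic activity mix.

    Roughly half the library is active (top inhibition 40-100%), the rest
    near-inactive; IC50s fall inside the tested window; Hill slopes 0.5-2.
    Parameters are drawn independently per drug x cell line.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(config.concentrations, float)
    x1, x2 = np.log10(c.min()), np.log10(c.max())
    rows = []
    for line in cell_lines:
        active = rng.random(n_drugs) < 0.5
        top = np.where(active, rng.uniform(40, 100, n_drugs), rng.uniform(0, 15, n_drugs))
        rows.append(
            pd.DataFrame(
                {
                    "drug_id": [f"drug{i:04d}" for i in range(n_drugs)],
                    "cell_line_id": line,
                    "bottom": 0.0,
                    "top": top,
                    "log10_ic50": rng.uniform(x1 + 0.5, x2 - 0.5, n_drugs),
                    "hill_slope": rng.uniform(0.5, 2.0, n_drugs),
                }
            )
        )
    truth = ScreenTruth(pd.concat(rows, ignore_index=True), config, seed)
    truth.validate()
    return truth


def potency_recovery_truth(
    n_drugs: int = 200,
    config: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    cell_line: str = "parental",
) -> ScreenTruth:
    """Truth for IC50-recovery benchmarking: identifiable curves only.

    A five-point design can pin log10 IC50 tightly only when the curve
    expresses most of its dynamic range inside the tested window: here top
    inhibition 70-100%, Hill slope 0.8-2 and IC50 at least one decade from
    either window edge. Weak or very shallow responses carry little IC50
    information at realistic noise and are assessed via DSS instead.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(config.concentrations, float)
    x1, x2 = np.log10(c.min()), np.log10(c.max())
    params = pd.DataFrame(
        {
            "drug_id": [f"drug{i:04d}" for i in range(n_drugs)],
            "cell_line_id": cell_line,
            "bottom": 0.0,
            "top": rng.uniform(70, 100, n_drugs),
            "log10_ic50": rng.uniform(x1 + 1.0, x2 - 1.0, n_drugs),
            "hill_slope": rng.uniform(0.8, 2.0, n_drugs),
        }
    )
    truth = ScreenTruth(params, config, seed)
    truth.validate()
    return truth


def paired_screen_truth(
    n_drugs: int = 72,
    n_sensitizing: int = 5,
    n_coresistant: int = 3,
    config: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    parental_id: str = "parental",
    resistant_id: str = "resistant",
) -> tuple[ScreenTruth, dict[str, list[str]]]:
    """Truth for one resistant/parental pair with designated differential drugs.

    The first ``n_sensitizing`` drugs are potent only in the resistant line,
    the next ``n_coresistant`` only in the parental line; the remainder have
    identical parameters in both lines, so only the designated drugs carry a
    large true dDSS.
    """
    if n_sensitizing + n_coresistant > n_drugs:
        raise ValueError("more designated drugs than drugs")
    rng = np.random.default_rng(seed)
    c = np.asarray(config.concentrations, float)
    x1, x2 = np.log10(c.min()), np.log10(c.max())
    ids = [f"drug{i:04d}" for i in range(n_drugs)]
    m = rng.uniform(x1 + 0.5, x2 - 1.0, n_drugs)
    s = rng.uniform(0.8, 1.5, n_drugs)
    base_top = rng.uniform(0, 12, n_drugs)
    rows = []
    sens = ids[:n_sensitizing]
    cores = ids[n_sensitizing : n_sensitizing + n_coresistant]
    for line in (parental_id, resistant_id):
        top = base_top.copy()
        for i, d in enumerate(ids):
            if d in sens and line == resistant_id:
                top[i] = rng.uniform(80, 100)
            elif d in cores and line == parental_id:
                top[i] = rng.uniform(80, 100)
        rows.append(
            pd.DataFrame(
                {
                    "drug_id": ids,
                    "cell_line_id": line,
                    "bottom": 0.0,
                    "top": top,
                    "log10_ic50": m,
                    "hill_slope": s,
                }
            )
        )
    truth = ScreenTruth(pd.concat(rows, ignore_index=True), config, seed)
    truth.validate()
    return truth, {"sensitizing": sens, "co-resistant": cores}


def generate_screen(truth: ScreenTruth, seed: int | None = None):
    """Raw plate readouts from a screen truth.

    Signal model: signal = neg_mean - inhibition/100 * (neg_mean -
    pos_mean), then multiplied by (1 + noise_cv * z), z ~ N(0,1); the same
    noise applies to control wells, so plate normalization inverts the
    transform exactly at noise 0. Each cell line fills its own plates, each
    with at least 16 negative and 8 positive control wells.

    Returns (readout DataFrame, ScreenTruth).
    """
    cfg = truth.config
    cfg.validate()
    truth.validate()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    conc = np.asarray(cfg.concentrations, float)
    logc = np.log10(conc)
    wells = _well_names()
    frames = []
    for line, grp in truth.params.groupby("cell_line_id", sort=True):
        grp = grp.reset_index(drop=True)
        for p0 in range(0, len(grp), cfg.drugs_per_plate):
            plate = grp.iloc[p0 : p0 + cfg.drugs_per_plate]
            plate_id = f"{line}_p{p0 // cfg.drugs_per_plate + 1:02d}"
            rows = []
            w = 0
            for drug in plate.itertuples(index=False):
                inh = logistic4(logc, drug.bottom, drug.top, drug.log10_ic50, drug.hill_slope)
                sig = cfg.neg_mean - inh / 100.0 * (cfg.neg_mean - cfg.pos_mean)
                for cc, s in zip(conc, sig):
                    rows.append((plate_id, wells[w], line, drug.drug_id, cc, s, "drug"))
                    w += 1
            for _ in range(cfg.n_neg_ctrl):
                rows.append((plate_id, wells[w], line, "DMSO", np.nan, cfg.neg_mean, "neg_ctrl"))
                w += 1
            for _ in range(cfg.n_pos_ctrl):
                rows.append(
                    (plate_id, wells[w], line, "benzethonium", np.nan, cfg.pos_mean, "pos_ctrl")
                )
                w += 1
            frames.append(
                pd.DataFrame(
                    rows,
                    columns=[
                        "plate_id", "well", "cell_line_id", "drug_id",
                        "concentration_M", "signal", "well_type",
                    ],
                )
            )
    readout = pd.concat(frames, ignore_index=True)
    if cfg.noise_cv > 0:
        z = rng.standard_normal(len(readout))
        readout["signal"] = readout["signal"] * (1.0 + cfg.noise_cv * z)
    return readout, truth


# ---------------------------------------------------------------------------
# exome pair


@dataclass(frozen=True)
class ExomeConfig:
    """Layout of a synthetic exome capture pair with embedded CNV segments."""

    chromosomes: tuple = (("chr1", 200), ("chr2", 200), ("chr3", 200))
    region_length: tuple = (120, 400)  # bp, uniform
    region_gap: tuple = (100, 2000)  # bp between consecutive regions
    mean_coverage: float = 100.0  # x, parental expected coverage
    read_length_bp: int = 100
    #: (chrom, first_region, past_last_region, true log2) blocks, resistant vs parental
    cnv_segments: tuple = (("chr2", 60, 120, -1.0), ("chr3", 40, 80, 1.0))
    n_somatic: int = 20
    n_germline: int = 30
    somatic_vaf: tuple = (0.2, 0.6)
    variant_error_rate: float = 0.001  # background alt rate in the parental sample
    frac_silent: float = 0.2  # fraction of somatic variants with a silent effect class

    def validate(self) -> None:
        if len(self.chromosomes) < 2:
            raise ValueError("need >= 2 chromosomes")
        if any(n < 50 for _, n in self.chromosomes):
            raise ValueError("need >= 50 regions per chromosome")
        sizes = dict(self.chromosomes)
        for chrom, a, b, _ in self.cnv_segments:
            if chrom not in sizes or not 0 <= a < b <= sizes[chrom]:
                raise ValueError(f"invalid CNV block on {chrom}: [{a}, {b})")


@dataclass
class GenomeTruth:
    """Ground truth behind a generated exome pair."""

    regions: pd.DataFrame  # chrom, start, end, region_id, true_log2
    variants: pd.DataFrame  # truth rows incl. true_vaf, is_somatic, gene
    germline: frozenset  # (chrom, pos, ref, alt) membership, dbSNP stand-in
    config: ExomeConfig
    seed: int


def generate_exome_pair(config: ExomeConfig = ExomeConfig(), seed: int = 0):
    """Paired per-region read counts plus a paired-count variant table.

    Parental counts are Poisson with mean coverage * length / read_length;
    resistant counts are Poisson with that mean scaled by 2^(true log2) of
    the embedded segment covering the region. Somatic variants carry
    binomial alt counts at their true VAF in the resistant sample only;
    germline variants sit near VAF 0.5 in both samples and are listed in
    the dbSNP stand-in membership set.

    Returns (sample_counts, reference_counts, variant_table, GenomeTruth).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    reg_rows = []
    for chrom, n_regions in config.chromosomes:
        pos = 10_000
        for i in range(n_regions):
            length = int(rng.integers(*config.region_length))
            reg_rows.append((chrom, pos, pos + length))
            pos += length + int(rng.integers(*config.region_gap))
    regions = pd.DataFrame(reg_rows, columns=["chrom", "start", "end"])
    regions["region_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(regions.chrom, regions.start, regions.end)
    ]
    true_log2 = np.zeros(len(regions))
    offsets = {}
    off = 0
    for chrom, n_regions in config.chromosomes:
        offsets[chrom] = off
        off += n_regions
    for chrom, a, b, l2 in config.cnv_segments:
        true_log2[offsets[chrom] + a : offsets[chrom] + b] = l2
    regions["true_log2"] = true_log2

    length = (regions.end - regions.start).to_numpy(float)
    mean_ref = config.mean_coverage * length / config.read_length_bp
    ref_counts = rng.poisson(mean_ref)
    smp_counts = rng.poisson(mean_ref * np.power(2.0, true_log2))
    reference = pd.DataFrame({"region_id": regions.region_id, "count": ref_counts})
    sample = pd.DataFrame({"region_id": regions.region_id, "count": smp_counts})

    # variants: somatic (resistant-only) and germline (shared, dbSNP-listed)
    bases = np.array(list("ACGT"))
    effect_pool_ns = ["missense", "nonsense", "splice_site", "frameshift"]
    var_rows = []
    n_total = config.n_somatic + config.n_germline
    reg_pick = rng.integers(0, len(regions), n_total)
    depth = config.mean_coverage
    for v in range(n_total):
        somatic = v < config.n_somatic
        reg = regions.iloc[reg_pick[v]]
        pos = int(rng.integers(reg.start, reg.end)) + 1  # 1-based
        ref, alt = rng.choice(bases, size=2, replace=False)
        if somatic:
            vaf = float(rng.uniform(*config.somatic_vaf))
            silent = rng.random() < config.frac_silent
            effect = "synonymous" if silent else str(rng.choice(effect_pool_ns))
            n_vaf = config.variant_error_rate
        else:
            vaf = 0.5
            effect = str(rng.choice(effect_pool_ns + ["synonymous"]))
            n_vaf = 0.5
        nd = max(int(rng.poisson(depth)), 1)
        td = max(int(rng.poisson(depth)), 1)
        n_alt = int(rng.binomial(nd, n_vaf))
        t_alt = int(rng.binomial(td, vaf))
        fwd = int(rng.binomial(t_alt, 0.5)) if t_alt else 0
        var_rows.append(
            {
                "chrom": reg.chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": f"GENE{v:03d}",
                "effect_class": effect,
                "normal_ref": nd - n_alt,
                "normal_alt": n_alt,
                "tumor_ref": td - t_alt,
                "tumor_alt": t_alt,
                "tumor_alt_fwd": fwd,
                "tumor_alt_rev": t_alt - fwd,
                "in_dbsnp": not somatic,
                "true_vaf": vaf,
                "is_somatic": somatic,
            }
        )
    variant_columns = [
        "chrom", "pos", "ref", "alt", "gene", "effect_class",
        "normal_ref", "normal_alt", "tumor_ref", "tumor_alt",
        "tumor_alt_fwd", "tumor_alt_rev", "in_dbsnp", "true_vaf", "is_somatic",
    ]
    truth_variants = pd.DataFrame(var_rows, columns=variant_columns)
    germline = frozenset(
        (r.chrom, r.pos, r.ref, r.alt)
        for r in truth_variants[~truth_variants.is_somatic].itertuples()
    )
    variant_table = truth_variants.drop(columns=["true_vaf", "is_somatic"])
    truth = GenomeTruth(regions, truth_variants, germline, config, seed)
    return sample, reference, variant_table, truth


# ---------------------------------------------------------------------------
# bioactivities


@dataclass(frozen=True)
class BioactivityConfig:
    """Shape of a synthetic drug-target bioactivity table."""

    drug_ids: tuple = tuple(f"drug{i:04d}" for i in range(12))
    n_true_targets: tuple = (1, 3)  # inclusive range per drug
    n_decoys: tuple = (1, 4)
    frac_scaled_branch: float = 0.5  # drugs whose best score is < 0.1
    ic50_adjustment: float = 2.0  # must match the integration setting

    def validate(self) -> None:
        if not self.drug_ids:
            raise ValueError("need at least one drug")
        if self.n_true_targets[0] < 1:
            raise ValueError("every drug needs >= 1 true target")


@dataclass
class BioactivityTruth:
    """Designated specific-target sets behind a generated bioactivity table."""

    specific: dict  # drug_id -> frozenset of true specific targets
    thresholds: dict  # drug_id -> (threshold, branch)
    scores: pd.DataFrame  # drug_id, target_gene, true_score, is_specific
    config: BioactivityConfig
    seed: int


def _emit_measurements(rng, drug, target, score, ic50_adjustment):
    """Rows whose per-type medians integrate exactly back to ``score``."""
    style = rng.integers(0, 4)
    if style == 0:
        return [(drug, target, "Ki", score)]
    if style == 1:
        return [(drug, target, "Kd", score)]
    if style == 2:
        return [(drug, target, "IC50", score * ic50_adjustment)]
    return [
        (drug, target, "Ki", score),
        (drug, target, "IC50", score * ic50_adjustment),
    ]


def generate_bioactivity(config: BioactivityConfig = BioactivityConfig(), seed: int = 0):
    """Bioactivity table with designated, recoverable specific targets.

    For each drug a branch of the specificity rule is chosen: either the
    best score is drawn below 0.1 (threshold = 50x it) or all scores sit at
    or above 0.1 (threshold = 3). True targets score strictly below the
    resulting threshold, decoys well above it, and measurements are emitted
    so that per-type medians (IC50 divided by the adjustment factor)
    integrate exactly back to the intended score.

    Returns (bioactivity DataFrame, BioactivityTruth).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows, score_rows = [], []
    specific, thresholds = {}, {}
    for drug in config.drug_ids:
        n_true = int(rng.integers(config.n_true_targets[0], config.n_true_targets[1] + 1))
        n_dec = int(rng.integers(config.n_decoys[0], config.n_decoys[1] + 1))
        scaled = rng.random() < config.frac_scaled_branch
        if scaled:
            k_min = float(rng.uniform(0.005, 0.09))
            thr = 50.0 * k_min
            branch = "scaled_50x"
        else:
            k_min = float(rng.uniform(0.12, 2.0))
            thr = 3.0
            branch = "absolute_3"
        true_scores = [k_min] + list(
            rng.uniform(k_min, min(0.9 * thr, max(k_min, 0.9 * thr)), n_true - 1)
        )
        decoy_scores = list(rng.uniform(1.5 * thr, 100.0 + 1.5 * thr, n_dec))
        names_true = [f"{drug}_T{i}" for i in range(n_true)]
        names_dec = [f"{drug}_D{i}" for i in range(n_dec)]
        for name, sc, is_spec in zip(
            names_true + names_dec,
            true_scores + decoy_scores,
            [True] * n_true + [False] * n_dec,
        ):
            rows.extend(_emit_measurements(rng, drug, name, sc, config.ic50_adjustment))
            score_rows.append(
                {"drug_id": drug, "target_gene": name, "true_score": sc, "is_specific": is_spec}
            )
        specific[drug] = frozenset(names_true)
        thresholds[drug] = (thr, branch)
    bio = pd.DataFrame(rows, columns=["drug_id", "target_gene", "assay_type", "value_uM"])
    truth = BioactivityTruth(specific, thresholds, pd.DataFrame(score_rows), config, seed)
    return bio, truth
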