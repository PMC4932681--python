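"""KIBA-style bioactivity integration, specific-target selection and
effector drug -> target tables annotated with genomic lesions.

Drug-target bioactivities (Ki, Kd, IC50 in µM) are integrated into a single
KIBA-like score per drug-target pair: the per-assay-type medians are
combined after dividing the IC50 median by a fixed adjustment factor
(default 2, standing in for the learned offsets of the full KIBA scheme).
Low score = tight binding. A drug's *specific* targets are those below a
drug-wise threshold: 50x its lowest score when that minimum is < 0.1,
otherwise an absolute 3 score units. Effector drugs (|dDSS| above cutoff)
are then joined with their specific targets and annotated with copy-number
calls and high-confidence mutations; a pair x direction needs at least
three effector drugs to produce a table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "integrate_kiba",
    "SpecificTargetSet",
    "specific_targets",
    "specific_targets_all",
    "effector_tables",
]

logger = logging.getLogger(__name__)

ASSAY_TYPES = ("Ki", "Kd", "IC50")
IC50_ADJUSTMENT = 2.0
SCALED_BRANCH_MIN = 0.1
SCALED_FACTOR = 50.0
ABSOLUTE_THRESHOLD = 3.0
MIN_EFFECTORS = 3


def integrate_kiba(
    bioactivities: pd.DataFrame, ic50_adjustment: float = IC50_ADJUSTMENT
) -> pd.DataFrame:
    """Integrate per-assay bioactivities into one score per drug-target pair.

    Per (drug, target): the median of each assay type's values; the IC50
    median is divided by ``ic50_adjustment`` before combining; the
    integrated score is the mean of the available adjusted per-type medians.
    Pairs without measurements are simply absent.
    """
    req = {"drug_id", "target_gene", "assay_type", "value_uM"}
    if not req <= set(bioactivities.columns):
        raise ValueError(f"bioactivity table needs columns {sorted(req)}")
    if (bioactivities.value_uM <= 0).any():
        raise ValueError("bioactivity values must be positive (µM)")
    bad = set(bioactivities.assay_type) - set(ASSAY_TYPES)
    if bad:
        raise ValueError(f"unknown assay types: {sorted(bad)}")
    med = (
        bioactivities.groupby(["drug_id", "target_gene", "assay_type"])["value_uM"]
        .median()
        .reset_index()
    )
    med["adjusted"] = np.where(
        med.assay_type == "IC50", med.value_uM / ic50_adjustment, med.value_uM
    )
    out = (
        med.groupby(["drug_id", "target_gene"])
        .agg(
            score=("adjusted", "mean"),
            n_assay_types=("assay_type", "nunique"),
            assay_types_used=("assay_type", lambda s: ",".join(sorted(s))),
        )
        .reset_index()
    )
    n_meas = (
        bioactivities.groupby(["drug_id", "target_gene"])
        .size()
        .rename("n_measurements")
        .reset_index()
    )
    return out.merge(n_meas, on=["drug_id", "target_gene"])


@dataclass
class SpecificTargetSet:
    """Targets a drug binds below its specificity threshold."""

    drug_id: str
    threshold: float
    rule_branch: str  # "scaled_50x" | "absolute_3"
    target_genes: frozenset


def specific_targets(scores: pd.DataFrame) -> SpecificTargetSet:
    """Apply the specific-target threshold rule to one drug's scores.

    If the tightest-binding target scores below 0.1, the threshold is 50x
    that minimum; otherwise it is 3 score units. Targets strictly below the
    threshold are specific.
    """
    if scores.empty:
        raise ValueError("no scored targets for drug")
    drugs = scores.drug_id.unique()
    if len(drugs) != 1:
        raise ValueError("specific_targets expects scores for exactly one drug")
    k_min = float(scores.score.min())
    if k_min < SCALED_BRANCH_MIN:
        threshold, branch = SCALED_FACTOR * k_min, "scaled_50x"
    else:
        threshold, branch = ABSOLUTE_THRESHOLD, "absolute_3"
    kept = frozenset(scores.loc[scores.score < threshold, "target_gene"])
    return SpecificTargetSet(str(drugs[0]), threshold, branch, kept)


def specific_targets_all(kiba: pd.DataFrame) -> dict[str, SpecificTargetSet]:
    """Per-drug specific-target sets from an integrated score table."""
    return {
        str(drug): specific_targets(grp)
        for drug, grp in kiba.groupby("drug_id", sort=True)
    }


def effector_tables(
    hits: pd.DataFrame,
    specific: dict[str, SpecificTargetSet],
    gene_calls: pd.DataFrame | None = None,
    mutated_genes: set | None = None,
    min_effectors: int = MIN_EFFECTORS,
):
    """Build per-pair, per-direction effector drug -> target tables.

    A (pair, direction) with fewer than ``min_effectors`` hit drugs is
    skipped (logged). Each retained effector drug contributes one row per
    specific target, annotated with the gene's copy-number category (if
    called non-neutral) and a mutated flag (if a high-confidence
    protein-altering mutation hits the gene). Drugs without target data stay
    in the table with an empty target, flagged, so the drug list remains
    faithful even when it cannot be displayed in a network.

    Returns
    -------
    (tables, nodes, edges, skipped)
        ``tables``: {(pair_id, direction): DataFrame}; ``nodes``/``edges``:
        flat network export across all tables; ``skipped``: list of
        (pair_id, direction, n_effectors) below the minimum.
    """
    cnv_map: dict[str, str] = {}
    if gene_calls is not None and len(gene_calls):
        cnv_map = dict(zip(gene_calls.gene_id, gene_calls.category))
    mutated = set(mutated_genes or ())

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    skipped: list[tuple[str, str, int]] = []
    node_rows, edge_rows = [], []
    for (pair, direction), grp in hits.groupby(["pair_id", "direction"], sort=True):
        drugs = grp.sort_values("drug_id")
        if len(drugs) < min_effectors:
            skipped.append((str(pair), str(direction), len(drugs)))
            logger.info(
                "pair %s / %s: %d effector drug(s) < %d, no table built",
                pair, direction, len(drugs), min_effectors,
            )
            continue
        rows = []
        for drug in drugs.itertuples(index=False):
            spec = specific.get(str(drug.drug_id))
            targets = sorted(spec.target_genes) if spec is not None else []
            if not targets:
                logger.info("drug %s: no specific targets known", drug.drug_id)
                rows.append(
                    {
                        "drug_id": drug.drug_id,
                        "ddss": drug.ddss,
                        "target_gene": None,
                        "cnv_category": None,
                        "mutated": False,
                    }
                )
                continue
            for gene in targets:
                cat = cnv_map.get(gene)
                rows.append(
                    {
                        "drug_id": drug.drug_id,
                        "ddss": drug.ddss,
                        "target_gene": gene,
                        "cnv_category": cat,
                        "mutated": gene in mutated,
                    }
                )
                edge_rows.append(
                    {
                        "pair_id": pair,
                        "direction": direction,
                        "drug": drug.drug_id,
                        "target": gene,
                        "ddss": drug.ddss,
                    }
                )
                node_rows.append(
                    {"id": gene, "kind": "target", "cnv_category": cat, "mutated": gene in mutated}
                )
            node_rows.append(
                {"id": drug.drug_id, "kind": "drug", "cnv_category": None, "mutated": False}
            )
        tables[(str(pair), str(direction))] = pd.DataFrame(rows)
    nodes = (
        pd.DataFrame(node_rows).drop_duplicates(subset=["id", "kind"]).reset_index(drop=True)
        if node_rows
        else pd.DataFrame(columns=["id", "kind", "cnv_category", "mutated"])
    )
    edges = (
        pd.DataFrame(edge_rows)
        if edge_rows
        else pd.DataFrame(columns=["pair_id", "direction", "drug", "target", "ddss"])
    )
    return tables, nodes, edges, skipped
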