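"""DEG handling and the candidate-regulator scan.

A focal transcription factor (NAM-A1-style) is validated by the overlap of
its predicted targets with differentially-expressed-gene (DEG) sets; other
regulators whose shared ratio with the DEGs strictly exceeds the focal
regulator's at one or more timepoints become candidate regulators. Candidates
are annotated with the number of targets shared with the focal regulator and
with senescence fold-change flags from an expression matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .netio import ExpressionMatrix, RegulatoryNetwork, targets_of
from .overlap import shared_ratio

logger = logging.getLogger(__name__)


def filter_degs(table: pd.DataFrame, timepoint: str, q_threshold: float = 0.05) -> set:
    """Genes differentially expressed at a timepoint: q strictly below threshold."""
    if not 0 < q_threshold <= 1:
        raise ConfigurationError(f"q_threshold must be in (0, 1], got {q_threshold}")
    if timepoint not in set(table["timepoint"]):
        raise ConfigurationError(f"unknown timepoint {timepoint!r}")
    at_tp = table[table["timepoint"] == timepoint]
    return set(at_tp.loc[at_tp["q_value"] < q_threshold, "gene_id"])


def ranked_quartile_positions(
    table: pd.DataFrame,
    timepoint: str,
    subset,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Where a gene subset falls in the q-ranked DEG list, by quartile bin.

    DEGs at the timepoint are sorted by ascending q-value (ties broken by
    gene id for determinism) and split into four equal-size rank bins, any
    remainder going to the earlier bins. Returns counts and fractions of the
    subset per bin; subset members that are not DEGs are an error.
    """
    subset = set(subset)
    degs = filter_degs(table, timepoint, q_threshold)
    offenders = subset - degs
    if offenders:
        raise ValidationError(
            f"subset members not in the DEG list at {timepoint}: {sorted(offenders)[:10]}"
        )
    at_tp = table[table["timepoint"] == timepoint]
    ranked = (
        at_tp[at_tp["gene_id"].isin(degs)]
        .sort_values(["q_value", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    n = len(ranked)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    bounds = np.cumsum([0] + sizes)
    ranks = ranked.index[ranked["gene_id"].isin(subset)].to_numpy()
    counts = [int(((ranks >= bounds[i]) & (ranks < bounds[i + 1])).sum()) for i in range(4)]
    total = len(subset)
    return pd.DataFrame(
        {
            "quartile": ["Q1", "Q2", "Q3", "Q4"],
            "bin_size": sizes,
            "count": counts,
            "fraction": [c / total if total else 0.0 for c in counts],
        }
    )


def shared_with_focal(
    network: RegulatoryNetwork,
    tf_id: str,
    focal_tf: str,
    genome_filter=None,
    annotation=None,
) -> int:
    """Number of predicted targets shared between a regulator and the focal one."""
    a = targets_of(network, tf_id, genome_filter=genome_filter, annotation=annotation)
    b = targets_of(network, focal_tf, genome_filter=genome_filter, annotation=annotation)
    return len(a & b)


def scan_candidate_regulators(
    network: RegulatoryNetwork,
    deg_sets: dict,
    focal_tf: str,
    genome_filter=None,
    annotation=None,
) -> pd.DataFrame:
    """Regulators whose shared ratio with a DEG set strictly exceeds the
    focal regulator's at one or more timepoints.

    ``deg_sets`` maps timepoint → gene set. Each candidate row carries its
    per-timepoint ratios, boolean exceeds flags, the label of which
    timepoints it exceeds at ("both" or the single timepoint), and the count
    of targets shared with the focal regulator. The result's ``attrs`` hold
    ``n_tfs``, ``n_candidates`` and ``percentage`` (of the whole frame).
    The focal regulator can never be its own candidate (strict inequality).
    """
    focal_targets = targets_of(
        network, focal_tf, genome_filter=genome_filter, annotation=annotation
    )
    if not focal_targets:
        raise ConfigurationError(
            f"focal regulator {focal_tf!r} has no (filtered) targets in the network"
        )
    timepoints = list(deg_sets)
    focal_ratio = {
        tp: shared_ratio(focal_targets, deg_sets[tp]).ratio for tp in timepoints
    }
    rows = []
    frame = network.regulators
    for tf in frame:
        tgts = targets_of(network, tf, genome_filter=genome_filter, annotation=annotation)
        if not tgts:
            continue
        ratios = {tp: shared_ratio(tgts, deg_sets[tp]).ratio for tp in timepoints}
        exceeds = {tp: ratios[tp] > focal_ratio[tp] for tp in timepoints}
        if not any(exceeds.values()):
            continue
        exceeded_at = [tp for tp in timepoints if exceeds[tp]]
        row = {"tf_id": tf}
        if annotation is not None and tf in annotation.index:
            fam = annotation.loc[tf, "family"]
            row["family"] = fam if pd.notna(fam) else ""
        for tp in timepoints:
            row[f"ratio_{tp}"] = ratios[tp]
            row[f"exceeds_{tp}"] = exceeds[tp]
        row["exceeds_at"] = "both" if len(exceeded_at) == len(timepoints) > 1 else (
            "+".join(exceeded_at)
        )
        row["shared_with_focal"] = len(tgts & focal_targets)
        rows.append(row)
    result = pd.DataFrame(rows)
    result.attrs["focal_tf"] = focal_tf
    result.attrs["focal_ratio"] = focal_ratio
    result.attrs["n_tfs"] = len(frame)
    result.attrs["n_candidates"] = len(result)
    result.attrs["percentage"] = round(100 * len(result) / len(frame), 1) if frame else 0.0
    return result


def senescence_fold_change(
    expr: ExpressionMatrix,
    gene_ids,
    epsilon: float = 0.01,
    average_tissues: bool = True,
) -> pd.DataFrame:
    """Fold change of expression between senescing and non-senescing samples.

    fold = (mean TPM over senescent samples + ε) / (mean over non-senescent
    samples + ε), with ε a small pseudocount in TPM units guarding against
    zero baselines. When ``average_tissues`` is set, replicate samples of the
    same tissue are averaged before the group means, so each tissue
    contributes equally. Flags: ``upregulated`` (fold > 1), ``twofold``
    (fold ≥ 2) and ``twofold_strict`` (fold > 2). Genes absent from the
    matrix get an undefined (NaN) fold and all-False flags.
    """
    meta = expr.metadata
    if not meta["senescent"].any() or meta["senescent"].all():
        raise ConfigurationError(
            "need at least one senescent and one non-senescent sample"
        )
    if average_tissues:
        by_tissue = expr.values.T.groupby(
            [meta["tissue"], meta["senescent"]]
        ).mean()
        senescent_flags = by_tissue.index.get_level_values(1).to_numpy(dtype=bool)
        profiles = by_tissue.to_numpy()
    else:
        senescent_flags = meta["senescent"].to_numpy()
        profiles = expr.values.T.to_numpy()
    sen_mean = pd.Series(
        profiles[senescent_flags].mean(axis=0), index=expr.values.index
    )
    non_mean = pd.Series(
        profiles[~senescent_flags].mean(axis=0), index=expr.values.index
    )
    rows = []
    for g in gene_ids:
        if g not in expr.values.index:
            logger.warning("gene %s absent from expression matrix", g)
            rows.append(
                {"gene_id": g, "fold_change": np.nan, "upregulated": False,
                 "twofold": False, "twofold_strict": False}
            )
            continue
        fold = (sen_mean[g] + epsilon) / (non_mean[g] + epsilon)
        rows.append(
            {
                "gene_id": g,
                "fold_change": float(fold),
                "upregulated": bool(fold > 1),
                "twofold": bool(fold >= 2),
                "twofold_strict": bool(fold > 2),
            }
        )
    return pd.DataFrame(rows)
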