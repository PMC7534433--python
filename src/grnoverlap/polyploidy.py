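"""Homeolog-triad analyses for a polyploid regulatory network.

Hexaploid wheat carries three related subgenomes (A, B, D); a syntenic 1:1:1
triad holds one gene copy per subgenome. This module measures how strongly
homeologous transcription factors share predicted targets (three pairwise
shared ratios per triad), compares that sharing across expression-movement
categories (Dynamic / Mid 80 / Stable), and tests whether a regulator's
targets are enriched on its own genome of origin.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyAnalysisError
from .netio import GENOMES, MOVEMENT_CATEGORIES, RegulatoryNetwork, targets_of
from .overlap import shared_ratio, summarize_distribution

logger = logging.getLogger(__name__)

PAIR_LABELS = ("A-B", "A-D", "B-D")


def triad_pairwise_ratios(
    network: RegulatoryNetwork,
    triads: pd.DataFrame,
    syntenic_only: bool = True,
) -> pd.DataFrame:
    """Three pairwise shared ratios (A-B, A-D, B-D) for each triad.

    Triads with any member absent from the network (empty target set) are
    dropped with a logged count, so the output always holds exactly
    3 × (retained triads) rows. No genome filter is applied: all three
    subgenomes are needed.
    """
    frame = triads[triads["syntenic"]] if syntenic_only else triads
    target_sets = network.target_sets()
    rows = []
    dropped = 0
    for _, tri in frame.iterrows():
        members = {
            "A": tri["gene_a"],
            "B": tri["gene_b"],
            "D": tri["gene_d"],
        }
        sets = {g: target_sets.get(m, set()) for g, m in members.items()}
        if any(not s for s in sets.values()):
            dropped += 1
            continue
        movement = tri.get("movement", "Unclassified")
        for g1, g2 in itertools.combinations(GENOMES, 2):
            rec = shared_ratio(sets[g1], sets[g2], id_a=members[g1], id_b=members[g2])
            rows.append(
                {
                    "triad_id": tri["triad_id"],
                    "pair": f"{g1}-{g2}",
                    **rec.__dict__,
                    "movement": movement,
                }
            )
    if dropped:
        logger.warning("dropped %d triad(s) with an empty-target member", dropped)
    if not rows:
        raise EmptyAnalysisError("no triads retained; cannot analyze homeolog sharing")
    return pd.DataFrame(rows)


def compare_movement_categories(
    records: pd.DataFrame,
    alternative: str = "two-sided",
    method: str = "auto",
):
    """Rank-sum comparisons of homeolog shared ratios across movement classes.

    For each pair of movement categories (Stable vs Mid80, Stable vs Dynamic,
    Mid80 vs Dynamic) a Mann-Whitney/Wilcoxon rank-sum test is run on the
    per-comparison ratios; two-sided by default (``method`` is passed through
    to the rank-sum implementation). Returns ``(tests, summaries)``
    where ``summaries`` holds one six-number summary row per category.
    Categories with fewer than 2 records are skipped with a warning.
    """
    cats = [c for c in MOVEMENT_CATEGORIES if c in set(records["movement"])]
    groups = {c: records.loc[records["movement"] == c, "ratio"].to_numpy() for c in cats}
    summaries = pd.DataFrame(
        [
            {"category": c, **summarize_distribution(g).as_row()}
            for c, g in groups.items()
            if g.size
        ]
    )
    tests = []
    order = [("Stable", "Mid80"), ("Stable", "Dynamic"), ("Mid80", "Dynamic")]
    for g1, g2 in order:
        if g1 not in groups or g2 not in groups:
            continue
        x, y = groups[g1], groups[g2]
        if len(x) < 2 or len(y) < 2:
            logger.warning("skipping %s vs %s: a group has < 2 records", g1, g2)
            continue
        res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
        tests.append(
            {
                "group1": g1,
                "group2": g2,
                "n1": len(x),
                "n2": len(y),
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(tests), summaries


def target_genome_proportions(
    network: RegulatoryNetwork,
    annotation: pd.DataFrame,
    tf_frame=None,
) -> pd.DataFrame:
    """Per-regulator proportions of targets on each subgenome.

    Only targets with a known genome enter the denominator; regulators with
    zero annotated targets, or whose own genome is unknown, are dropped with
    a warning. Proportions sum to 1 per retained regulator.
    """
    genome = annotation["genome"]
    frame = list(tf_frame) if tf_frame is not None else network.regulators
    rows = []
    dropped = 0
    for tf in frame:
        tf_genome = genome.get(tf, "unknown")
        if tf_genome not in GENOMES:
            dropped += 1
            continue
        counts = {g: 0 for g in GENOMES}
        for t in targets_of(network, tf):
            g = genome.get(t, "unknown")
            if g in counts:
                counts[g] += 1
        n = sum(counts.values())
        if n == 0:
            dropped += 1
            continue
        rows.append(
            {
                "tf_id": tf,
                "tf_genome": tf_genome,
                "n_targets": n,
                "prop_a": counts["A"] / n,
                "prop_b": counts["B"] / n,
                "prop_d": counts["D"] / n,
            }
        )
    if dropped:
        logger.warning("dropped %d regulator(s) without usable genome annotation", dropped)
    if not rows:
        raise EmptyAnalysisError("no regulators with annotated targets")
    return pd.DataFrame(rows)


def genome_origin_association(
    proportions: pd.DataFrame,
    movement_stratify: bool = False,
) -> pd.DataFrame:
    """Two-sample KS tests for genome-of-origin target bias, BH-adjusted.

    For each target-genome proportion (A, B, D) and each pair of TF-origin
    groups (A vs B, A vs D, B vs D), a two-sample Kolmogorov-Smirnov test
    compares the per-regulator proportion distributions. All tests in one
    invocation form a single Benjamini-Hochberg family; with
    ``movement_stratify`` the analysis repeats, and adjusts, within each
    movement category (requires a ``movement`` column).
    """
    strata: list[tuple[str, pd.DataFrame]]
    if movement_stratify:
        if "movement" not in proportions.columns:
            raise EmptyAnalysisError("movement_stratify requires a 'movement' column")
        strata = [
            (cat, proportions[proportions["movement"] == cat])
            for cat in MOVEMENT_CATEGORIES
            if (proportions["movement"] == cat).any()
        ]
    else:
        strata = [("all", proportions)]

    out = []
    for stratum, df in strata:
        rows = []
        for g1, g2 in itertools.combinations(GENOMES, 2):
            grp1 = df[df["tf_genome"] == g1]
            grp2 = df[df["tf_genome"] == g2]
            for tg in GENOMES:
                if len(grp1) < 2 or len(grp2) < 2:
                    logger.warning(
                        "skipping %s vs %s (target genome %s) in stratum %s: "
                        "a group has < 2 members",
                        g1, g2, tg, stratum,
                    )
                    continue
                col = f"prop_{tg.lower()}"
                res = stats.ks_2samp(grp1[col].to_numpy(), grp2[col].to_numpy())
                rows.append(
                    {
                        "stratum": stratum,
                        "target_genome": tg,
                        "group1": g1,
                        "group2": g2,
                        "n1": len(grp1),
                        "n2": len(grp2),
                        "statistic": float(res.statistic),
                        "p": float(res.pvalue),
                    }
                )
        if rows:
            block = pd.DataFrame(rows)
            block["p_adjusted"] = multipletests(block["p"], method="fdr_bh")[1]
            out.append(block)
    if not out:
        raise EmptyAnalysisError("no genome-origin comparisons could be run")
    return pd.concat(out, ignore_index=True)


def category_counts_consistent(records: pd.DataFrame) -> bool:
    """Internal consistency: classified category rows partition the records."""
    classified = records[records["movement"].isin(MOVEMENT_CATEGORIES)]
    per_cat = classified.groupby("movement").size().sum()
    unclassified = (records["movement"] == "Unclassified").sum()
    return int(per_cat + unclassified) == len(records)


def _summary_row(values: np.ndarray, label: str) -> dict:
    return {"category": label, **summarize_distribution(values).as_row()}
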