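"""Synthetic data with planted, recoverable structure.

Every pipeline stage can be exercised without external downloads by
generating a sparse regulator→target network, gene annotation, syntenic
triads with movement categories, a differential-expression table, and a TPM
expression matrix — all with known ground truth:

* background regulators draw targets uniformly from a large gene pool, so
  two random regulators share almost no targets (expected pairwise ratio
  ≈ targets²/n_genes, near zero at sparse settings);
* each homeolog triad shares a common "core" of targets sized to a per-triad
  overlap drawn around its movement category's planted mean, and the
  non-core targets of the three members are mutually disjoint, so the
  pairwise shared ratio equals core/|targets| exactly;
* the DEG sets contain a planted fraction of a causal regulator's targets
  (plus optional planted exceeding candidates), with q-values from a
  near-zero Beta component for DEGs over a uniform background;
* senescent samples of upregulated genes carry a planted fold change.

A single seed makes the full bundle byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .netio import (
    GENOMES,
    ExpressionMatrix,
    RegulatoryNetwork,
    targets_of,
    write_edge_list,
)

DEFAULT_FAMILIES = (
    "NAC", "C2C2_Dof", "MYB", "WRKY", "bZIP", "AP2-EREBP", "HSF", "CCAAT_HAP3",
)


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Defaults follow the scale of the real analysis: ~3,000 regulators over a
    ~20,000-gene pool (sparse enough that random regulators share ≈ no
    targets), triad counts per movement category equal to the published
    comparison counts (132 / 1,590 / 156 pairwise comparisons → 44 / 530 / 52
    triads), planted category overlap means 0.41 / 0.39 / 0.35, a causal
    regulator overlapping the DEGs at 0.15, and DEG set sizes 866 (12DAA)
    and 130 (22DAA).
    """

    n_background_tfs: int = 3000
    n_genes: int = 20000
    targets_per_tf: tuple = (30, 80)
    triads_per_category: dict = field(
        default_factory=lambda: {"Stable": 44, "Mid80": 530, "Dynamic": 52}
    )
    category_overlap_mean: dict = field(
        default_factory=lambda: {"Stable": 0.41, "Mid80": 0.39, "Dynamic": 0.35}
    )
    #: Beta concentration of the per-triad overlap around its category mean;
    #: 4.0 reproduces the published interquartile spread. None → no spread.
    overlap_concentration: float | None = 4.0
    genome_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    families: tuple = DEFAULT_FAMILIES
    causal_overlap: float = 0.15
    n_deg: dict = field(default_factory=lambda: {"12DAA": 866, "22DAA": 130})
    #: Beta(a, b) component for DEG q-values (enriched peak near zero).
    q_beta: tuple = (0.5, 20.0)
    n_planted_candidates: int = 3
    candidate_overlap: float = 0.3
    expression_fold: float = 2.5
    expression_noise: float = 0.1
    n_replicates_per_tissue: int = 3
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.targets_per_tf
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"bad targets_per_tf range {self.targets_per_tf}")
        if hi * 3 > self.n_genes:
            raise ConfigurationError("gene pool too small for disjoint triad targets")
        for cat, m in self.category_overlap_mean.items():
            if not 0 <= m <= 1:
                raise ConfigurationError(f"overlap mean for {cat} outside [0, 1]: {m}")
        for name, v in (("causal_overlap", self.causal_overlap),
                        ("candidate_overlap", self.candidate_overlap)):
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} outside [0, 1]: {v}")
        if any(n < 0 for n in self.triads_per_category.values()):
            raise ConfigurationError("negative triad count")
        if abs(sum(self.genome_proportions) - 1) > 1e-9:
            raise ConfigurationError("genome proportions must sum to 1")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_network(config: SimulationConfig, rng=None):
    """Generate (RegulatoryNetwork, annotation, triads) with planted overlap.

    Triad members draw a common target core of ``round(ρ·t)`` genes, with ρ
    per triad from Beta(mean·κ, (1−mean)·κ), and mutually disjoint non-core
    targets, so each within-triad pairwise shared ratio is exactly
    ``round(ρ·t)/t``. Edge weights are positive draws from an exponential
    distribution (the ranking is arbitrary but valid for top-N trimming).
    """
    config.validate()
    rng = _as_rng(config.seed if rng is None else rng)
    genes = np.array([f"TaGene{i:05d}" for i in range(config.n_genes)])
    lo, hi = config.targets_per_tf

    regulators: list[str] = []
    edge_targets: list[np.ndarray] = []
    ann_rows = []
    triad_rows = []

    triad_idx = 0
    for cat, count in config.triads_per_category.items():
        mean = config.category_overlap_mean[cat]
        for _ in range(count):
            t = int(rng.integers(lo, hi + 1))
            if config.overlap_concentration is None:
                rho = mean
            elif mean in (0.0, 1.0):
                rho = mean
            else:
                k = config.overlap_concentration
                rho = float(rng.beta(mean * k, (1 - mean) * k))
            core = int(round(rho * t))
            if core > t:
                raise ConfigurationError("planted core larger than target-set size")
            draw = rng.choice(config.n_genes, size=core + 3 * (t - core), replace=False)
            core_genes = genes[draw[:core]]
            family = config.families[triad_idx % len(config.families)]
            triad_id = f"Triad{triad_idx:04d}"
            member_ids = {}
            for m, g in enumerate(GENOMES):
                tf = f"TaTF{triad_idx:04d}{g}"
                member_ids[g] = tf
                extra = genes[draw[core + m * (t - core): core + (m + 1) * (t - core)]]
                regulators.append(tf)
                edge_targets.append(np.concatenate([core_genes, extra]))
                ann_rows.append(
                    {"gene_id": tf, "is_tf": True, "family": family,
                     "genome": g, "triad_id": triad_id}
                )
            triad_rows.append(
                {"triad_id": triad_id, "gene_a": member_ids["A"],
                 "gene_b": member_ids["B"], "gene_d": member_ids["D"],
                 "syntenic": True, "movement": cat}
            )
            triad_idx += 1

    for i in range(config.n_background_tfs):
        tf = f"TaTFbg{i:04d}"
        t = int(rng.integers(lo, hi + 1))
        regulators.append(tf)
        edge_targets.append(genes[rng.choice(config.n_genes, size=t, replace=False)])
        ann_rows.append(
            {"gene_id": tf, "is_tf": True,
             "family": str(rng.choice(config.families)),
             "genome": str(rng.choice(GENOMES, p=config.genome_proportions)),
             "triad_id": None}
        )

    gene_genomes = rng.choice(GENOMES, size=config.n_genes, p=config.genome_proportions)
    for g, gen in zip(genes, gene_genomes):
        ann_rows.append(
            {"gene_id": g, "is_tf": False, "family": None, "genome": gen,
             "triad_id": None}
        )

    reg_col = np.repeat(regulators, [len(t) for t in edge_targets])
    tgt_col = np.concatenate(edge_targets)
    weights = rng.exponential(1.0, size=len(tgt_col)) + 1e-9
    network = RegulatoryNetwork(
        pd.DataFrame({"regulator": reg_col, "target": tgt_col, "weight": weights})
    )
    annotation = pd.DataFrame(ann_rows).set_index("gene_id")
    triads = pd.DataFrame(
        triad_rows,
        columns=["triad_id", "gene_a", "gene_b", "gene_d", "syntenic", "movement"],
    )
    return network, annotation, triads


def simulate_deg_table(
    network: RegulatoryNetwork,
    causal_tf: str,
    r,
    n_deg,
    universe,
    timepoints=("12DAA", "22DAA"),
    rng=None,
    planted: dict | None = None,
    q_beta: tuple = (0.5, 20.0),
):
    """Generate a DEG table whose membership overlaps a causal regulator's
    targets at a planted rate.

    Per timepoint, ``round(r·|targets|)`` causal targets are made DEGs; the
    remaining DEG slots are filled from the universe excluding the causal
    (and any planted regulators') targets, so the planted overlaps are exact
    before q-value noise. ``planted`` maps timepoint → {tf_id: fraction} for
    regulators that should exceed the causal overlap (``ceil(fraction·t)``
    of their targets become DEGs). DEGs draw q from Beta(a, b) (peak near 0);
    every other universe gene draws q from Uniform(0, 1).

    Returns ``(table, truth)`` where ``truth`` records the realized planted
    sets and ratios per timepoint.
    """
    rng = _as_rng(rng)
    universe = np.asarray(sorted(set(universe)))
    causal_targets = sorted(targets_of(network, causal_tf))
    if not causal_targets:
        raise ConfigurationError(f"causal regulator {causal_tf!r} has no targets")
    r_map = r if isinstance(r, dict) else {tp: r for tp in timepoints}
    n_map = n_deg if isinstance(n_deg, dict) else {tp: n_deg for tp in timepoints}
    planted = planted or {}
    a, b = q_beta

    frames = []
    truth: dict = {"causal_tf": causal_tf, "timepoints": {}}
    for tp in timepoints:
        n_shared = int(round(r_map[tp] * len(causal_targets)))
        shared = set(rng.choice(causal_targets, size=n_shared, replace=False)) \
            if n_shared else set()
        excluded = set(causal_targets)
        planted_here = planted.get(tp, {})
        planted_picks: dict[str, set] = {}
        for tf, frac in planted_here.items():
            tf_targets = sorted(set(targets_of(network, tf)) - set(causal_targets))
            k = int(np.ceil(frac * (len(tf_targets) + len(
                set(targets_of(network, tf)) & set(causal_targets)))))
            k = min(k, len(tf_targets))
            picks = set(rng.choice(tf_targets, size=k, replace=False)) if k else set()
            planted_picks[tf] = picks
            excluded |= set(targets_of(network, tf))
        members = shared | set().union(*planted_picks.values()) if planted_picks \
            else set(shared)
        n_fill = n_map[tp] - len(members)
        if n_fill < 0:
            raise ConfigurationError(
                f"planted DEG members exceed n_deg={n_map[tp]} at {tp}"
            )
        pool = np.array(sorted(set(universe) - members - excluded))
        if n_fill > len(pool):
            raise ConfigurationError(f"universe too small to fill {n_map[tp]} DEGs")
        members |= set(rng.choice(pool, size=n_fill, replace=False))
        is_deg = np.isin(universe, sorted(members))
        q = rng.uniform(0, 1, size=len(universe))
        q[is_deg] = rng.beta(a, b, size=int(is_deg.sum()))
        frames.append(
            pd.DataFrame({"gene_id": universe, "q_value": q, "timepoint": tp})
        )
        truth["timepoints"][tp] = {
            "n_deg": int(n_map[tp]),
            "shared_with_causal": sorted(shared),
            "causal_ratio": n_shared / len(causal_targets),
            "planted_candidates": {tf: sorted(p) for tf, p in planted_picks.items()},
        }
    return pd.concat(frames, ignore_index=True), truth


def simulate_expression(
    genes,
    samples: pd.DataFrame,
    upregulated,
    fold: float = 2.5,
    noise_sigma: float = 0.1,
    rng=None,
    baseline_log_mean: float = np.log(10.0),
    baseline_log_sigma: float = 1.0,
) -> ExpressionMatrix:
    """TPM matrix with a planted senescence fold change.

    Each gene gets a lognormal baseline; senescent samples of ``upregulated``
    genes are multiplied by ``fold``; multiplicative lognormal noise with
    ``noise_sigma`` applies per cell (0 → noise-free).
    """
    if fold <= 0:
        raise ConfigurationError(f"fold must be > 0, got {fold}")
    rng = _as_rng(rng)
    genes = list(genes)
    upregulated = set(upregulated)
    baseline = rng.lognormal(baseline_log_mean, baseline_log_sigma, size=len(genes))
    senescent = samples["senescent"].to_numpy(dtype=bool)
    up = np.array([g in upregulated for g in genes])
    values = np.outer(baseline, np.ones(len(samples)))
    values[np.ix_(up, senescent)] *= fold
    if noise_sigma > 0:
        values *= rng.lognormal(0.0, noise_sigma, size=values.shape)
    mat = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                       columns=samples["sample_id"])
    meta = samples.set_index("sample_id")[["tissue", "senescent"]]
    return ExpressionMatrix(mat, meta)


def default_samples(n_replicates: int = 3) -> pd.DataFrame:
    """Sample sheet: one senescing flag-leaf tissue and three non-senescing
    tissues, ``n_replicates`` samples each."""
    rows = []
    for tissue, senescent in [("flag_leaf_senescent", True), ("leaf", False),
                              ("root", False), ("spike", False)]:
        for i in range(n_replicates):
            rows.append(
                {"sample_id": f"{tissue}_rep{i + 1}", "tissue": tissue,
                 "senescent": senescent}
            )
    return pd.DataFrame(rows)


def simulate_all(config: SimulationConfig, out_dir, seed: int | None = None) -> dict:
    """Write the full synthetic input bundle plus a ground-truth manifest.

    Files (netio dialects): network.tsv, annotation.tsv, triads.tsv, one
    movement_<Category>.txt gene list per category, degs.tsv, expression.tsv,
    samples.tsv, and manifest.json with every planted parameter. Identical
    config and seed reproduce the bundle byte-for-byte.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    network, annotation, triads = simulate_network(config, rng)
    causal_tf = triads["gene_a"].iloc[0] if len(triads) else network.regulators[0]
    background = [tf for tf in network.regulators if tf.startswith("TaTFbg")]
    planted_ids = (
        [str(x) for x in rng.choice(background, size=config.n_planted_candidates,
                                    replace=False)]
        if config.n_planted_candidates and background else []
    )
    planted = {
        tp: {tf: config.candidate_overlap for tf in planted_ids}
        for tp in config.n_deg
    }
    genes = sorted(annotation.index[~annotation["is_tf"]])
    degs, truth = simulate_deg_table(
        network, causal_tf, config.causal_overlap, config.n_deg, genes,
        timepoints=tuple(config.n_deg), rng=rng, planted=planted,
        q_beta=config.q_beta,
    )
    samples = default_samples(config.n_replicates_per_tissue)
    tf_genes = sorted(annotation.index[annotation["is_tf"]])
    upregulated = set(planted_ids) | {causal_tf}
    expr = simulate_expression(
        tf_genes, samples, upregulated, fold=config.expression_fold,
        noise_sigma=config.expression_noise, rng=rng,
    )

    write_edge_list(network, out / "network.tsv")
    annotation.reset_index().to_csv(out / "annotation.tsv", sep="\t", index=False)
    triads.drop(columns=["movement"]).to_csv(out / "triads.tsv", sep="\t", index=False)
    movement_files = {}
    for cat in config.triads_per_category:
        members = triads.loc[triads["movement"] == cat,
                             ["gene_a", "gene_b", "gene_d"]].to_numpy().ravel()
        path = out / f"movement_{cat}.txt"
        path.write_text("".join(f"{g}\n" for g in members))
        movement_files[cat] = path.name
    degs.to_csv(out / "degs.tsv", sep="\t", index=False)
    expr.values.to_csv(out / "expression.tsv", sep="\t")
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": int(config.seed if seed is None else seed),
        "causal_tf": causal_tf,
        "planted_candidates": planted_ids,
        "candidate_overlap": config.candidate_overlap,
        "deg_truth": truth,
        "upregulated_genes": sorted(upregulated),
        "expression_fold": config.expression_fold,
        "movement_files": movement_files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
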