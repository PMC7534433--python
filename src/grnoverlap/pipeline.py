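"""End-to-end orchestration: load inputs, run every analysis, write reports.

A single :class:`RunConfig` (YAML file or keyword construction) drives the
full analysis set: focal-regulator DEG validation with a resampling null and
sign test; the summary table of shared-ratio distributions (all regulators,
per family, homeologs, per movement category); movement-category rank-sum
tests; genome-of-origin KS tests; and the candidate-regulator scan with
senescence fold-change flags.

One pseudorandom generator is seeded once per run and consumed in a fixed,
documented stage order (DEG nulls by timepoint → all-TF pairs → per-family
pairs), so a single seed reproduces every output byte-for-byte. Every output
file starts with ``#``-prefixed provenance lines (version, seed, config
hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .candidates import (
    filter_degs,
    scan_candidate_regulators,
    senescence_fold_change,
)
from .errors import ConfigurationError
from .netio import (
    EdgeListDialect,
    read_annotation,
    read_deg_table,
    read_edge_list,
    read_expression,
    read_movement_lists,
    read_triads,
    assign_movement,
    targets_of,
    trim_top_edges,
)
from .overlap import (
    null_ratio_distribution,
    pairwise_ratio_distribution,
    sample_tf_pairs,
    shared_ratio,
    sign_test_exceeds,
    summarize_distribution,
)
from .polyploidy import (
    compare_movement_categories,
    genome_origin_association,
    target_genome_proportions,
    triad_pairwise_ratios,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, dialects and analysis parameters for one pipeline run."""

    network: str
    out_dir: str
    annotation: str | None = None
    triads: str | None = None
    movement_files: dict = field(default_factory=dict)
    degs: str | None = None
    expression: str | None = None
    samples: str | None = None
    edge_dialect: dict = field(default_factory=dict)
    top_n: int | None = None
    genome_filter: list | None = None
    timepoints: list = field(default_factory=lambda: ["12DAA", "22DAA"])
    q_threshold: float = 0.05
    n_null_samples: int = 1000
    n_pair_samples: int = 1000
    focal_tf: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        try:
            config = cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        config.validate()
        return config

    def validate(self) -> None:
        paths = [self.network, self.annotation, self.triads, self.degs,
                 self.expression, self.samples, *self.movement_files.values()]
        missing = [p for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"input file(s) not found: {missing}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"# grnoverlap {__version__}",
        f"# seed={config.seed}",
        f"# config_hash={config.config_hash()}",
    ]


def _write_tsv(df: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: RunConfig) -> dict:
    dialect = EdgeListDialect(**config.edge_dialect) if config.edge_dialect \
        else EdgeListDialect()
    network = read_edge_list(config.network, dialect)
    if config.top_n:
        network = trim_top_edges(network, config.top_n)
    inputs = {"network": network}
    inputs["annotation"] = (
        read_annotation(config.annotation) if config.annotation else None
    )
    if config.triads:
        movement = (
            {cat: path for cat, path in config.movement_files.items()}
            if config.movement_files else None
        )
        inputs["triads"] = read_triads(config.triads, movement_files=movement)
    else:
        inputs["triads"] = None
    inputs["degs"] = read_deg_table(config.degs) if config.degs else None
    if config.expression and config.samples:
        inputs["expression"] = read_expression(config.expression, config.samples)
    else:
        inputs["expression"] = None
    return inputs


def run_deg_validation(config: RunConfig, inputs: dict | None = None,
                       rng: np.random.Generator | None = None) -> dict:
    """Focal-regulator validation against the DEG sets (the Fig-1-style run).

    Per timepoint: the focal shared-ratio record, the null distribution over
    ``n_null_samples`` random regulators, and the sign-test p-value
    (one-sided, "greater": the focal ratio exceeds the null median).
    """
    if config.focal_tf is None or config.degs is None:
        raise ConfigurationError("DEG validation needs focal_tf and a DEG table")
    inputs = inputs or _load_inputs(config)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    network, annotation = inputs["network"], inputs["annotation"]
    gfilter = tuple(config.genome_filter) if config.genome_filter else None
    if gfilter and annotation is None:
        raise ConfigurationError("genome_filter requires an annotation table")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    focal_targets = targets_of(network, config.focal_tf, gfilter, annotation)
    if not focal_targets:
        raise ConfigurationError(
            f"focal regulator {config.focal_tf!r} has no (filtered) targets"
        )
    report = {"focal_tf": config.focal_tf, "timepoints": {}}
    focal_rows, null_rows = [], []
    for tp in config.timepoints:
        deg_set = filter_degs(inputs["degs"], tp, config.q_threshold)
        rec = shared_ratio(focal_targets, deg_set, id_a=config.focal_tf, id_b=tp)
        records, summary = null_ratio_distribution(
            network, deg_set, config.n_null_samples, rng,
            genome_filter=gfilter, annotation=annotation,
        )
        p = sign_test_exceeds(rec.ratio, [r.ratio for r in records], "greater")
        report["timepoints"][tp] = {
            "focal_ratio": rec.ratio,
            "focal_record": rec.__dict__,
            "null_summary": summary.__dict__,
            "sign_test_p": p,
        }
        focal_rows.append({"timepoint": tp, **rec.__dict__, "sign_test_p": p})
        null_rows.append({"timepoint": tp, **summary.as_row()})
    header = _provenance(config)
    _write_tsv(pd.DataFrame(focal_rows), out / "focal_overlap.tsv", header)
    _write_tsv(pd.DataFrame(null_rows), out / "null_summary.tsv", header)
    lines = header + [
        f"Focal regulator: {config.focal_tf}",
        f"Genome filter: {','.join(gfilter) if gfilter else 'none'}",
    ]
    for tp, info in report["timepoints"].items():
        rec = info["focal_record"]
        lines.append(
            f"{tp}: shared {rec['intersection']}/{min(rec['size_a'], rec['size_b'])} "
            f"targets ({100 * info['focal_ratio']:.1f}%), "
            f"null median {info['null_summary']['median']:.3f}, "
            f"sign test P = {info['sign_test_p']:.3g}"
        )
    (out / "deg_validation.txt").write_text("\n".join(lines) + "\n")
    return report


def run_full_suite(config: RunConfig) -> dict:
    """Run every analysis section the provided inputs support.

    Sections with missing optional inputs are skipped with a warning and
    listed in the report's ``skipped`` entry. Outputs: focal_overlap.tsv,
    null_summary.tsv, summary_table.tsv, triad_ratios.tsv,
    movement_tests.tsv, genome_tests.tsv, candidates.tsv.
    """
    inputs = _load_inputs(config)
    rng = np.random.default_rng(config.seed)
    network, annotation = inputs["network"], inputs["annotation"]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    report: dict = {"skipped": [], "sections": {}}
    gfilter = tuple(config.genome_filter) if config.genome_filter else None

    # 1. Focal DEG validation (consumes rng first: one null per timepoint).
    if config.focal_tf and config.degs:
        report["sections"]["deg_validation"] = run_deg_validation(
            config, inputs=inputs, rng=rng
        )
    else:
        logger.warning("skipping DEG validation (needs focal_tf and degs)")
        report["skipped"].append("deg_validation")

    # 2. Shared-ratio distribution table (all TFs, per family, homeologs,
    #    movement categories).
    summary_rows = []
    frame = network.regulators
    if len(frame) >= 2:
        pairs = sample_tf_pairs(frame, config.n_pair_samples, rng)
        _, summary = pairwise_ratio_distribution(network, pairs)
        summary_rows.append({"category": "All TFs", **summary.as_row()})
    if annotation is not None:
        tf_ann = annotation[annotation["is_tf"] & annotation["family"].notna()]
        in_net = set(frame)
        for family in sorted(tf_ann["family"].unique()):
            members = sorted(set(tf_ann.index[tf_ann["family"] == family]) & in_net)
            if len(members) < 2:
                continue
            pairs = sample_tf_pairs(members, config.n_pair_samples, rng)
            _, summary = pairwise_ratio_distribution(network, pairs)
            summary_rows.append({"category": family, **summary.as_row()})
    triad_records = None
    if inputs["triads"] is not None:
        triad_records = triad_pairwise_ratios(network, inputs["triads"])
        summary_rows.append(
            {"category": "Homeologs",
             **summarize_distribution(triad_records["ratio"]).as_row()}
        )
        tests, cat_summaries = compare_movement_categories(triad_records)
        for _, row in cat_summaries.iterrows():
            summary_rows.append(dict(row))
        _write_tsv(triad_records, out / "triad_ratios.tsv", header)
        _write_tsv(tests, out / "movement_tests.tsv", header)
        report["sections"]["movement_tests"] = tests.to_dict("records")
    else:
        logger.warning("skipping triad analyses (no triad table)")
        report["skipped"].extend(["triad_ratios", "movement_tests"])
    if summary_rows:
        _write_tsv(pd.DataFrame(summary_rows), out / "summary_table.tsv", header)
        report["sections"]["summary_table"] = summary_rows

    # 3. Genome-of-origin association.
    if annotation is not None:
        try:
            props = target_genome_proportions(network, annotation)
            genome_tests = genome_origin_association(props)
            _write_tsv(genome_tests, out / "genome_tests.tsv", header)
            report["sections"]["genome_tests"] = genome_tests.to_dict("records")
        except Exception as exc:  # degenerate annotations: skip, don't abort
            logger.warning("skipping genome tests: %s", exc)
            report["skipped"].append("genome_tests")
    else:
        report["skipped"].append("genome_tests")

    # 4. Candidate-regulator scan.
    if config.focal_tf and config.degs:
        deg_sets = {
            tp: filter_degs(inputs["degs"], tp, config.q_threshold)
            for tp in config.timepoints
        }
        cands = scan_candidate_regulators(
            network, deg_sets, config.focal_tf,
            genome_filter=gfilter, annotation=annotation,
        )
        scan_stats = {
            "n_tfs": cands.attrs.get("n_tfs"),
            "n_candidates": len(cands),
            "percentage": cands.attrs.get("percentage"),
        }
        if inputs["expression"] is not None and len(cands):
            fc = senescence_fold_change(inputs["expression"], cands["tf_id"])
            cands = cands.merge(
                fc.rename(columns={"gene_id": "tf_id"}), on="tf_id", how="left"
            )
        _write_tsv(cands, out / "candidates.tsv", header)
        report["sections"]["candidates"] = scan_stats
    else:
        report["skipped"].append("candidates")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
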