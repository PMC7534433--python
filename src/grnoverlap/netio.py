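"""Input/output for the regulatory network and its companion tables.

The network is a weighted regulator→target edge list (the output of a
network-inference method such as GENIE3, consumed here as data).  Companion
tables are: a gene annotation (TF flag, TF super-family, genome of origin,
triad membership), a syntenic-triad table with movement categories, a
differential-expression table (gene, q-value, timepoint), and a TPM
expression matrix with sample metadata.

All tables are plain TSV/CSV with headers; column names and delimiters are
configurable through small dialect objects so that externally produced files
can be ingested without rewriting them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

GENOMES = ("A", "B", "D")
MOVEMENT_CATEGORIES = ("Dynamic", "Mid80", "Stable")

_REFSEQ_GENOME_RE = re.compile(r"^TraesCS\d([ABD])\d{2}G\d+")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryNetwork:
    """Weighted regulator→target edge table.

    Invariants (enforced at construction): no duplicate (regulator, target)
    pairs; all weights finite and strictly positive.
    """

    edges: pd.DataFrame  # columns: regulator, target, weight
    _target_index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = ["regulator", "target", "weight"]
        missing = [c for c in required if c not in self.edges.columns]
        if missing:
            raise ConfigurationError(f"edge table missing columns: {missing}")
        self.edges = self.edges[required].reset_index(drop=True)
        w = pd.to_numeric(self.edges["weight"], errors="coerce")
        bad = ~np.isfinite(w) | (w <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-finite or non-positive weight at edge row {row}: "
                f"{self.edges.iloc[row].tolist()}"
            )
        self.edges["weight"] = w.astype(float)
        dup = self.edges.duplicated(subset=["regulator", "target"])
        if dup.any():
            pair = self.edges.loc[dup.idxmax(), ["regulator", "target"]].tolist()
            raise ValidationError(f"duplicate edge for (regulator, target) = {tuple(pair)}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def regulators(self) -> list[str]:
        """Regulator ids with at least one edge, in sorted order."""
        return sorted(self.edges["regulator"].unique())

    def target_sets(self) -> dict[str, set]:
        """Mapping regulator → set of its targets (cached)."""
        if self._target_index is None:
            self._target_index = {
                reg: set(grp) for reg, grp in self.edges.groupby("regulator")["target"]
            }
        return self._target_index


@dataclass
class ExpressionMatrix:
    """Gene × sample TPM matrix plus per-sample metadata (tissue, senescent)."""

    values: pd.DataFrame  # index gene_id, columns sample_id
    metadata: pd.DataFrame  # index sample_id; columns tissue, senescent

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative TPM value in expression matrix")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        self.metadata = self.metadata.loc[list(self.values.columns)]
        self.metadata["senescent"] = self.metadata["senescent"].astype(bool)


# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeListDialect:
    """Column mapping for an edge-list file.

    The canonical dialect is tab-separated ``regulator<TAB>target<TAB>weight``
    with a header row.
    """

    regulator: str = "regulator"
    target: str = "target"
    weight: str = "weight"
    sep: str = "\t"


CANONICAL_DIALECT = EdgeListDialect()


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------

def read_edge_list(path, dialect: EdgeListDialect = CANONICAL_DIALECT) -> RegulatoryNetwork:
    """Read and validate a weighted edge list.

    Duplicate (regulator, target) rows and non-numeric or non-positive weights
    are errors, never silently repaired.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    for col in (dialect.regulator, dialect.target, dialect.weight):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} (have {list(df.columns)})"
            )
    df = df.rename(
        columns={dialect.regulator: "regulator", dialect.target: "target",
                 dialect.weight: "weight"}
    )
    w = pd.to_numeric(df["weight"], errors="coerce")
    bad = w.isna() | ~np.isfinite(w) | (w <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"invalid weight {df['weight'].iloc[row]!r} at data row {row + 1} of {path}"
        )
    df["weight"] = w.astype(float)
    return RegulatoryNetwork(df)


def write_edge_list(network: RegulatoryNetwork, path) -> None:
    """Write in the canonical dialect; round-trips weights bit-exactly."""
    network.edges.to_csv(path, sep="\t", index=False)


def trim_top_edges(network: RegulatoryNetwork, n: int) -> RegulatoryNetwork:
    """Keep the ``n`` highest-weight edges.

    Ties at the cut weight are broken by lexicographic (regulator, target)
    order so the trim is deterministic. Idempotent for fixed ``n``.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    ordered = network.edges.sort_values(
        ["weight", "regulator", "target"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return RegulatoryNetwork(ordered.head(n).reset_index(drop=True))


def targets_of(
    network: RegulatoryNetwork,
    regulator_id: str,
    genome_filter=None,
    annotation: pd.DataFrame | None = None,
) -> set:
    """Target set of a regulator, optionally restricted by target genome.

    A regulator absent from the network yields the empty set with a logged
    warning. ``genome_filter`` is a subset of {A, B, D} and requires an
    annotation table; targets missing from the annotation are treated as
    unknown genome and excluded by any filter.
    """
    if genome_filter is not None and annotation is None:
        raise ConfigurationError("genome_filter requires an annotation table")
    targets = network.target_sets().get(regulator_id)
    if targets is None:
        logger.warning("regulator %s not present in network; empty target set", regulator_id)
        return set()
    if genome_filter is None:
        return set(targets)
    allowed = set(genome_filter)
    bad = allowed - set(GENOMES)
    if bad:
        raise ConfigurationError(f"unknown genomes in filter: {sorted(bad)}")
    genome = annotation["genome"]
    return {t for t in targets if genome.get(t, "unknown") in allowed}


# ---------------------------------------------------------------------------
# Companion tables
# ---------------------------------------------------------------------------

def read_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Gene annotation: gene_id, is_tf, family, genome, triad_id.

    Returned indexed by gene_id. Genome values outside {A, B, D} become
    "unknown". Family must only be present for TF rows.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"gene_id", "is_tf"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"annotation missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id in annotation: {dup}")
    df["is_tf"] = df["is_tf"].str.lower().isin(["true", "1", "yes", "t"])
    for col in ("family", "genome", "triad_id"):
        if col not in df.columns:
            df[col] = pd.NA
    df["genome"] = df["genome"].where(df["genome"].isin(GENOMES), "unknown")
    offenders = df[~df["is_tf"] & df["family"].notna()]
    if len(offenders):
        raise ValidationError(
            f"family set for non-TF gene(s), e.g. {offenders['gene_id'].iloc[0]}"
        )
    return df.set_index("gene_id")


def genome_from_refseq_id(gene_id: str) -> str:
    """Convenience parser for RefSeq-style wheat ids (opt-in only).

    Extracts the subgenome letter from identifiers like ``TraesCS6A02G108300``.
    Never applied implicitly; genome assignment normally comes from the
    annotation table.
    """
    m = _REFSEQ_GENOME_RE.match(gene_id)
    return m.group(1) if m else "unknown"


def read_triads(
    path,
    movement_files: dict | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Triad table: triad_id, gene_a, gene_b, gene_d, syntenic [+ movement].

    ``movement_files`` maps a category name (Dynamic / Mid80 / Stable) to a
    plain-text gene-list file; a triad is labelled with the category of any
    member. Conflicting memberships are validation errors; triads in no list
    are ``Unclassified``.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"triad_id", "gene_a", "gene_b", "gene_d"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"triad table missing columns: {sorted(missing)}")
    if "syntenic" in df.columns:
        df["syntenic"] = df["syntenic"].str.lower().isin(["true", "1", "yes", "t"])
    else:
        df["syntenic"] = True
    members = df[["gene_a", "gene_b", "gene_d"]]
    if (members.nunique(axis=1) != 3).any():
        bad = df.loc[members.nunique(axis=1) != 3, "triad_id"].iloc[0]
        raise ValidationError(f"triad {bad} has non-distinct members")
    flat = members.to_numpy().ravel()
    if len(set(flat)) != len(flat):
        seen: set = set()
        dup = next(g for g in flat if g in seen or seen.add(g))
        raise ValidationError(f"gene {dup} belongs to more than one triad")
    if movement_files:
        df["movement"] = assign_movement(df, read_movement_lists(movement_files))
    elif "movement" not in df.columns:
        df["movement"] = "Unclassified"
    return df.reset_index(drop=True)


def read_movement_lists(movement_files: dict) -> dict:
    """Read one gene-list file per movement category; lists must be disjoint."""
    lists: dict[str, set] = {}
    for category, path in movement_files.items():
        with open(path) as fh:
            genes = {line.strip() for line in fh if line.strip()}
        lists[category] = genes
    cats = list(lists)
    for i, c1 in enumerate(cats):
        for c2 in cats[i + 1:]:
            both = lists[c1] & lists[c2]
            if both:
                raise ValidationError(
                    f"gene {sorted(both)[0]} appears in both {c1!r} and {c2!r} lists"
                )
    return lists


def assign_movement(triads: pd.DataFrame, lists: dict) -> pd.Series:
    """Label each triad by the movement category of its member genes."""
    labels = []
    for _, row in triads.iterrows():
        cats = {
            cat
            for cat, genes in lists.items()
            if {row["gene_a"], row["gene_b"], row["gene_d"]} & genes
        }
        if len(cats) > 1:
            raise ValidationError(
                f"triad {row['triad_id']} has members in conflicting categories {sorted(cats)}"
            )
        labels.append(cats.pop() if cats else "Unclassified")
    return pd.Series(labels, index=triads.index)


def read_deg_table(path, sep: str = "\t") -> pd.DataFrame:
    """Differential-expression table: gene_id, q_value, timepoint."""
    df = pd.read_csv(path, sep=sep, dtype={"gene_id": str, "timepoint": str})
    required = {"gene_id", "q_value", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"DEG table missing columns: {sorted(missing)}")
    q = pd.to_numeric(df["q_value"], errors="coerce")
    if q.isna().any() or (q < 0).any() or (q > 1).any():
        row = int(np.flatnonzero((q.isna() | (q < 0) | (q > 1)).to_numpy())[0])
        raise ValidationError(f"q_value outside [0, 1] at data row {row + 1}")
    df["q_value"] = q.astype(float)
    if df.duplicated(subset=["gene_id", "timepoint"]).any():
        raise ValidationError("duplicate (gene_id, timepoint) in DEG table")
    return df.reset_index(drop=True)


def read_expression(values_path, metadata_path, sep: str = "\t") -> ExpressionMatrix:
    """Expression matrix (genes × samples TSV, gene ids in the first column)
    plus a sample metadata TSV (sample_id, tissue, senescent)."""
    values = pd.read_csv(values_path, sep=sep, index_col=0)
    meta = pd.read_csv(metadata_path, sep=sep, dtype=str)
    required = {"sample_id", "tissue", "senescent"}
    missing = required - set(meta.columns)
    if missing:
        raise ConfigurationError(f"sample metadata missing columns: {sorted(missing)}")
    meta["senescent"] = meta["senescent"].str.lower().isin(["true", "1", "yes", "t"])
    return ExpressionMatrix(values, meta.set_index("sample_id"))
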