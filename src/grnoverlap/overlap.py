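"""Shared-ratio overlap statistics and resampling null distributions.

The core statistic is the *shared ratio* of two gene sets A and B,

    shared ratio = |A ∩ B| / min(|A|, |B|),

a normalized overlap coefficient: 1 when the smaller set is contained in the
larger, 0 when the sets are disjoint. Observed ratios (e.g. a transcription
factor's predicted targets against a differentially-expressed-gene set) are
compared against resampling nulls built from randomly selected regulators or
regulator pairs, with significance from an exact binomial sign test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateTestError,
    EmptyAnalysisError,
    UndefinedRatioError,
)
from .netio import RegulatoryNetwork, targets_of

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SharedRatioRecord:
    """One pairwise overlap measurement between two labelled gene sets."""

    id_a: str
    id_b: str
    size_a: int
    size_b: int
    intersection: int
    ratio: float


@dataclass(frozen=True)
class DistributionSummary:
    """Six-number summary plus count for a collection of ratios."""

    n: int
    minimum: float
    q1: float
    median: float
    mean: float
    q3: float
    maximum: float

    def as_row(self) -> dict:
        return {
            "Minimum": self.minimum,
            "1st Quartile": self.q1,
            "Median": self.median,
            "Mean": self.mean,
            "3rd Quartile": self.q3,
            "Maximum": self.maximum,
            "Number of Comparisons": self.n,
        }


def shared_ratio(set_a, set_b, id_a: str = "A", id_b: str = "B") -> SharedRatioRecord:
    """Shared ratio |A∩B| / min(|A|, |B|) of two gene sets.

    Symmetric in its arguments. Two empty sets have no defined ratio; one
    empty set gives ratio 0 with sizes recorded.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a and not set_b:
        raise UndefinedRatioError("shared ratio of two empty sets is undefined")
    inter = len(set_a & set_b)
    denom = min(len(set_a), len(set_b))
    ratio = inter / denom if denom > 0 else 0.0
    return SharedRatioRecord(id_a, id_b, len(set_a), len(set_b), inter, ratio)


def summarize_distribution(ratios) -> DistributionSummary:
    """Six-number summary (min, Q1, median, mean, Q3, max) plus count.

    Quartiles use linear interpolation between order statistics (the "type 7"
    convention of R's default ``quantile``).
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ConfigurationError("cannot summarize an empty collection of ratios")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return DistributionSummary(
        n=int(arr.size),
        minimum=float(arr.min()),
        q1=float(q1),
        median=float(med),
        mean=float(arr.mean()),
        q3=float(q3),
        maximum=float(arr.max()),
    )


def sign_test_exceeds(observed: float, null_samples, alternative: str = "greater") -> float:
    """Exact binomial sign test of an observed value against a null sample.

    Ties (null samples exactly equal to the observed value) are discarded;
    the remaining below/above counts are referred to Binomial(n, 1/2).
    ``alternative="greater"`` tests that the observed value exceeds the null
    median (i.e. that most null samples fall below it).
    """
    arr = np.asarray(list(null_samples), dtype=float)
    if arr.size == 0:
        raise ConfigurationError("null_samples must be non-empty")
    below = int((arr < observed).sum())
    above = int((arr > observed).sum())
    n = below + above
    if n == 0:
        raise DegenerateTestError(
            "all null samples tie with the observed value; sign test undefined"
        )
    if alternative not in ("greater", "less", "two_sided"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    scipy_alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[alternative]
    return float(stats.binomtest(below, n, 0.5, alternative=scipy_alt).pvalue)


def sample_tf_pairs(tf_frame, n_pairs: int, rng) -> list[tuple]:
    """Sample unique ordered pairs of distinct regulators without replacement.

    A frame of N regulators admits N·(N−1) ordered pairs; when ``n_pairs``
    exceeds that, every pair is returned (the maximum number of unique pairs).
    Reproducible given the generator state; the frame order matters.
    """
    frame = list(tf_frame)
    n = len(frame)
    if n < 2:
        raise ConfigurationError("need at least 2 regulators to form pairs")
    if len(set(frame)) != n:
        raise ConfigurationError("tf_frame contains duplicate ids")
    if n_pairs < 1:
        raise ConfigurationError(f"n_pairs must be >= 1, got {n_pairs}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    population = n * (n - 1)

    def decode(k: int) -> tuple:
        i, j = divmod(k, n - 1)
        if j >= i:
            j += 1
        return frame[i], frame[j]

    if n_pairs >= population:
        return [decode(k) for k in range(population)]
    # Rejection sampling with a seen-set: O(n_pairs) regardless of frame size.
    chosen: list[int] = []
    seen: set[int] = set()
    while len(chosen) < n_pairs:
        draw = rng.integers(0, population, size=n_pairs - len(chosen))
        for k in map(int, draw):
            if k not in seen:
                seen.add(k)
                chosen.append(k)
                if len(chosen) == n_pairs:
                    break
    return [decode(k) for k in chosen]


def null_ratio_distribution(
    network: RegulatoryNetwork,
    reference_set,
    n_samples: int,
    rng,
    tf_frame=None,
    exclude=None,
    genome_filter=None,
    annotation=None,
    replace: bool = False,
):
    """Null distribution of shared ratios between random regulators' target
    sets and a fixed reference set (e.g. the DEGs at one timepoint).

    Regulators are drawn from ``tf_frame`` (default: every regulator in the
    network, sorted) without replacement unless ``replace``. ``exclude``
    removes ids (e.g. the focal regulator) from the frame before sampling.

    Returns ``(records, summary)``; fully reproducible given the generator.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    frame = list(tf_frame) if tf_frame is not None else network.regulators
    if exclude:
        excluded = set(exclude)
        frame = [tf for tf in frame if tf not in excluded]
    if not frame:
        raise ConfigurationError("tf_frame is empty after exclusions")
    if not replace and n_samples > len(frame):
        raise ConfigurationError(
            f"n_samples={n_samples} exceeds frame size {len(frame)} "
            "when sampling without replacement"
        )
    reference_set = set(reference_set)
    idx = rng.choice(len(frame), size=n_samples, replace=replace)
    records = []
    for i in idx:
        tf = frame[int(i)]
        tgts = targets_of(network, tf, genome_filter=genome_filter, annotation=annotation)
        records.append(shared_ratio(tgts, reference_set, id_a=tf, id_b="reference"))
    summary = summarize_distribution([r.ratio for r in records])
    return records, summary


def pairwise_ratio_distribution(
    network: RegulatoryNetwork,
    pairs,
    genome_filter=None,
    annotation=None,
):
    """Shared ratios for a list of regulator pairs.

    Pairs with a member whose (possibly genome-filtered) target set is empty
    are dropped with a logged count; returns ``(records, summary)``.
    """
    records = []
    dropped = 0
    cache: dict[str, set] = {}

    def tgts(tf: str) -> set:
        if tf not in cache:
            cache[tf] = targets_of(
                network, tf, genome_filter=genome_filter, annotation=annotation
            )
        return cache[tf]

    for a, b in pairs:
        ta, tb = tgts(a), tgts(b)
        if not ta or not tb:
            dropped += 1
            continue
        records.append(shared_ratio(ta, tb, id_a=a, id_b=b))
    if dropped:
        logger.warning("dropped %d pair(s) with an empty target set", dropped)
    if not records:
        raise EmptyAnalysisError("no pairs retained; cannot form a distribution")
    summary = summarize_distribution([r.ratio for r in records])
    return records, summary


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate SharedRatioRecords for TSV output."""
    return pd.DataFrame([r.__dict__ for r in records])
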