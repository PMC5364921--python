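"""Replicate-pair taxonomy for the indexed-primer x sequencing-run design.

Every unordered pair of samples is simultaneously classified along two axes:
same/different indexed primer (``within_primer`` / ``between_primer``) and
same/different sequencing run (``within_run`` / ``between_run``).  With one
sample per primer-by-run cell, within-primer pairs are necessarily
between-run pairs: within-primer dissimilarity isolates random sampling
during sequencing, while the other classes mix sampling with indexed-PCR
artefacts.  Pair classes overlap by design; they are not a four-way
partition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .table import OTUTable
from .diversity import DistanceMatrix

__all__ = [
    "PairClass",
    "ClassSummary",
    "ReplicateDesign",
    "classify_pair",
    "summarize_by_class",
    "richness_per_sample",
    "welch_t",
]


class PairClass(str, enum.Enum):
    WITHIN_PRIMER = "within_primer"
    BETWEEN_PRIMER = "between_primer"
    WITHIN_RUN = "within_run"
    BETWEEN_RUN = "between_run"


def classify_pair(meta_a, meta_b) -> set[PairClass]:
    """Classify an unordered sample pair by its (primer_index, run) labels.

    Returns exactly one of {within_primer, between_primer} and one of
    {within_run, between_run}.  ``meta_a``/``meta_b`` are (primer_index, run)
    tuples or mappings with those keys; comparing a sample with itself is an
    error.
    """
    pa, ra = _as_labels(meta_a)
    pb, rb = _as_labels(meta_b)
    if (pa, ra) == (pb, rb):
        raise ValueError("cannot classify a sample paired with itself")
    return {
        PairClass.WITHIN_PRIMER if pa == pb else PairClass.BETWEEN_PRIMER,
        PairClass.WITHIN_RUN if ra == rb else PairClass.BETWEEN_RUN,
    }


def _as_labels(meta) -> tuple[int, int]:
    if isinstance(meta, dict):
        return int(meta["primer_index"]), int(meta["run"])
    if isinstance(meta, pd.Series):
        return int(meta["primer_index"]), int(meta["run"])
    p, r = meta
    return int(p), int(r)


@dataclass(frozen=True)
class ClassSummary:
    pair_class: PairClass
    n_pairs: int
    values: tuple[float, ...]
    min: float
    mean: float
    max: float
    sd: float

    def __post_init__(self) -> None:
        if self.n_pairs != len(self.values):
            raise ValueError("n_pairs must equal the number of values")
        if not (self.min - 1e-12 <= self.mean <= self.max + 1e-12):
            raise ValueError("min <= mean <= max violated")


@dataclass(frozen=True)
class ReplicateDesign:
    """Per-sample (primer_index, run) labels."""

    meta: pd.DataFrame  # index sample_id; columns primer_index, run

    def __post_init__(self) -> None:
        required = {"primer_index", "run"}
        if not required <= set(self.meta.columns):
            raise ValueError(f"design metadata needs columns {sorted(required)}")

    @classmethod
    def from_table(cls, table: OTUTable) -> "ReplicateDesign":
        return cls(table.sample_meta.copy())

    def labels(self, sample_id: str) -> tuple[int, int]:
        if sample_id not in self.meta.index:
            raise KeyError(f"sample {sample_id!r} has no design metadata")
        row = self.meta.loc[sample_id]
        return int(row["primer_index"]), int(row["run"])

    def pair_values(self, dm: DistanceMatrix) -> dict[str, list[float]]:
        """Group every unordered pair's dissimilarity by the classes it holds.

        A pair contributes to both of its classes (one primer-axis, one
        run-axis label), so class lists overlap.
        """
        missing = [s for s in dm.ids if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples without design metadata: {missing}")
        out: dict[str, list[float]] = {c.value: [] for c in PairClass}
        ids = dm.ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                classes = classify_pair(self.labels(ids[i]), self.labels(ids[j]))
                for c in classes:
                    out[c.value].append(float(dm.values[i, j]))
        return out


def summarize_by_class(dm: DistanceMatrix, design: ReplicateDesign) -> list[ClassSummary]:
    """Min/mean/max/sd of pairwise dissimilarities per replicate class."""
    grouped = design.pair_values(dm)
    summaries = []
    for cls in PairClass:
        vals = grouped[cls.value]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        summaries.append(
            ClassSummary(
                cls,
                len(vals),
                tuple(float(v) for v in vals),
                float(arr.min()),
                float(arr.mean()),
                float(arr.max()),
                float(arr.std(ddof=1)) if len(vals) > 1 else 0.0,
            )
        )
    return summaries


def richness_per_sample(table: OTUTable, subset: str = "all") -> pd.Series:
    """OTUs detected (count > 0) per sample, optionally restricted to the
    target or non-target subset."""
    if subset == "all":
        cols = table.otu_ids
    elif subset == "target":
        cols = table.target_ids()
    elif subset in ("non_target", "nontarget"):
        cols = table.nontarget_ids()
    else:
        raise ValueError(f"unknown subset {subset!r}; use all|target|non_target")
    sub = table.counts[cols] if cols else table.counts.iloc[:, :0]
    return (sub > 0).sum(axis=1).rename(f"richness_{subset}")


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t-test: returns (t, df, p).

    df by Welch-Satterthwaite; identical zero-variance groups give t=0, p=1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float(np.inf) * np.sign(x.mean() - y.mean()), float(len(x) + len(y) - 2), 0.0
    res = _stats.ttest_ind(x, y, equal_var=False)
    se2x, se2y = vx / len(x), vy / len(y)
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (len(x) - 1) + se2y**2 / (len(y) - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)
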