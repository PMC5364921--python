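"""Beta-diversity metrics, rarefaction, abundance filtering and sweeps.

Jaccard (presence-absence) and Bray-Curtis (read-abundance) dissimilarities,
pairwise distance matrices, hypergeometric rarefaction to a common depth, a
dataset-wide rare-OTU abundance filter and the threshold sweep that removes
progressively less-rare OTUs while tracking per-replicate-class
dissimilarities, plus detection-frequency and rank-abundance summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import distance as _sdist

from .table import OTUTable

__all__ = [
    "DistanceMatrix",
    "SweepResult",
    "DetectionRecord",
    "jaccard",
    "bray_curtis",
    "pairwise_distances",
    "rarefy",
    "abundance_filter",
    "threshold_sweep",
    "detection_frequency",
    "rank_abundance",
    "observed_vs_expected",
]

METRICS = ("jaccard", "bray_curtis")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix among samples, metric-tagged."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))

    def __getitem__(self, pair) -> float:
        a, b = pair
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.values[ia, ib])

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index.astype(str)), df.to_numpy(float), metric)


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be one-dimensional and of equal length")
    return x, y


def jaccard(x, y) -> float:
    """Jaccard dissimilarity 1 - |intersection|/|union| on presence-absence.

    Count vectors are reduced to presence (count > 0).  Two empty samples are
    defined as identical (0) rather than NaN so filtered matrices stay total.
    """
    x, y = _check_pair(x, y)
    px, py = x > 0, y > 0
    union = np.sum(px | py)
    if union == 0:
        return 0.0
    return float(1.0 - np.sum(px & py) / union)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|xi-yi| / sum(xi+yi) on read counts."""
    x, y = _check_pair(x, y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    denom = np.sum(x + y)
    if denom == 0:
        return 0.0
    return float(np.sum(np.abs(x - y)) / denom)


def pairwise_distances(table: OTUTable, metric: str) -> DistanceMatrix:
    """All unordered pairwise dissimilarities among the table's samples."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if table.n_samples < 2:
        raise ValueError("need at least two samples for pairwise distances")
    mat = table.counts.to_numpy(dtype=float)
    empty = mat.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty sample(s) in distance computation; "
            "empty-vs-empty dissimilarity defined as 0",
            stacklevel=2,
        )
    if metric == "jaccard":
        pres = mat > 0
        # scipy's boolean jaccard yields 0 for two all-false rows, matching
        # the empty-vs-empty convention
        cond = _sdist.pdist(pres, metric="jaccard")
    else:
        cond = _sdist.pdist(mat, metric="braycurtis")
        cond = np.nan_to_num(cond, nan=0.0)  # empty-vs-empty
    return DistanceMatrix(tuple(table.sample_ids), _sdist.squareform(cond), metric)


def rarefy(table: OTUTable, depth: int, seed) -> OTUTable:
    """Subsample every sample WITHOUT replacement to exactly ``depth`` reads.

    Multivariate-hypergeometric draw per sample; reproducible given ``seed``
    (an int or a ``numpy.random.Generator``).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_totals()
    low = totals[totals < depth]
    if len(low):
        raise ValueError(
            f"depth {depth} exceeds total reads of sample(s) {list(low.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, sid in enumerate(table.sample_ids):
        row = table.counts.loc[sid].to_numpy()
        out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return table.with_counts(counts)


def abundance_filter(table: OTUTable, min_total: int) -> OTUTable:
    """Keep OTUs whose summed reads across ALL samples are >= ``min_total``.

    ``min_total = t`` therefore removes OTUs "represented by less than t
    sequences" dataset-wide.  Samples are never dropped; a sample may become
    empty after filtering.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.otu_totals() >= min_total
    kept = table.counts.loc[:, keep[keep].index]
    if kept.shape[1] == 0:
        raise ValueError(f"abundance filter at {min_total} removed every OTU")
    return OTUTable(kept, table.sample_meta.copy(), table.otu_meta.loc[kept.columns].copy(),
                    allow_empty_samples=True)


@dataclass(frozen=True)
class SweepResult:
    """Per-threshold, per-replicate-class pairwise dissimilarities."""

    metric: str
    thresholds: tuple[int, ...]
    # threshold -> class name -> array of pairwise values
    values: dict[int, dict[str, np.ndarray]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for tau in self.thresholds:
            for cls, vals in self.values[tau].items():
                rows.append(
                    {
                        "threshold": tau,
                        "pair_class": cls,
                        "n_pairs": len(vals),
                        "min": float(np.min(vals)),
                        "mean": float(np.mean(vals)),
                        "max": float(np.max(vals)),
                    }
                )
        return pd.DataFrame(rows)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for tau in self.thresholds:
            for cls, vals in self.values[tau].items():
                for v in vals:
                    rows.append({"threshold": tau, "pair_class": cls, "dissimilarity": v})
        return pd.DataFrame(rows)


def threshold_sweep(table: OTUTable, thresholds, metric: str, design) -> SweepResult:
    """Recompute pairwise dissimilarities after removing OTUs below each
    abundance threshold, grouped by replicate pair class.

    ``thresholds`` must be strictly increasing; each threshold t removes OTUs
    with fewer than t reads dataset-wide (typically from the rarefied table).
    """
    thresholds = tuple(int(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    out: dict[int, dict[str, np.ndarray]] = {}
    for tau in thresholds:
        filtered = abundance_filter(table, tau)
        dm = pairwise_distances(filtered, metric)
        out[tau] = {
            cls: np.asarray(vals, dtype=float)
            for cls, vals in design.pair_values(dm).items()
        }
    return SweepResult(metric, thresholds, out)


@dataclass(frozen=True)
class DetectionRecord:
    """How consistently one OTU appears across a run's indexed-PCR trials."""

    otu_id: str
    run: int
    trials_detected: int
    n_trials: int
    total_reads_in_run: int

    def __post_init__(self) -> None:
        if not 0 <= self.trials_detected <= self.n_trials:
            raise ValueError("trials_detected outside [0, n_trials]")
        if self.total_reads_in_run < self.trials_detected:
            raise ValueError("total reads cannot be below the number of detections")


def detection_frequency(table: OTUTable, design=None) -> list[DetectionRecord]:
    """Per OTU and per run: trials with count > 0 and the run's total reads."""
    runs = sorted(table.sample_meta["run"].unique())
    records = []
    for run in runs:
        samples = table.sample_meta.index[table.sample_meta["run"] == run]
        sub = table.counts.loc[samples]
        detected = (sub > 0).sum(axis=0)
        totals = sub.sum(axis=0)
        for oid in table.otu_ids:
            records.append(
                DetectionRecord(oid, int(run), int(detected[oid]), len(samples), int(totals[oid]))
            )
    return records


def rank_abundance(table: OTUTable) -> pd.DataFrame:
    """OTUs ordered by descending dataset-wide total; ties broken by otu_id."""
    totals = table.otu_totals()
    df = pd.DataFrame(
        {
            "otu_id": totals.index,
            "total_reads": totals.to_numpy(),
            "is_target": table.otu_meta["is_target"].to_numpy(),
        }
    )
    df = df.sort_values(["total_reads", "otu_id"], ascending=[False, True], kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def observed_vs_expected(
    table: OTUTable,
    expected_proportions: pd.Series | dict,
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Observed vs expected read proportions among target OTUs.

    ``expected_proportions`` maps target otu_id -> expected fraction (summing
    to 1, e.g. 1/34 each for an equimolar pool).  Observed proportions use
    reads of those OTUs only.  ``groups`` optionally maps otu_id to a group
    label (e.g. phylum) for a roll-up; returns (per-OTU frame, per-group frame
    or None).
    """
    exp = pd.Series(expected_proportions, dtype=float)
    if abs(exp.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected proportions sum to {exp.sum()}, not 1")
    missing = set(exp.index) - set(table.otu_ids)
    if missing:
        raise ValueError(f"expected proportions reference unknown OTUs: {sorted(missing)}")
    totals = table.counts[list(exp.index)].sum(axis=0)
    obs = totals / totals.sum() if totals.sum() > 0 else totals.astype(float)
    per_otu = pd.DataFrame(
        {
            "otu_id": exp.index,
            "observed": obs[exp.index].to_numpy(),
            "expected": exp.to_numpy(),
        }
    )
    per_otu["ratio"] = per_otu["observed"] / per_otu["expected"]
    per_group = None
    if groups is not None:
        per_otu["group"] = [groups.get(o, "unassigned") for o in per_otu["otu_id"]]
        per_group = (
            per_otu.groupby("group")[["observed", "expected"]].sum().reset_index()
        )
        per_group["ratio"] = per_group["observed"] / per_group["expected"]
    return per_otu, per_group
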