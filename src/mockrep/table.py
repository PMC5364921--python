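"""OTU contingency tables: the pipeline's central container.

An :class:`OTUTable` holds an integer read-count matrix (samples x OTUs)
together with per-sample metadata (indexed-primer label, sequencing run) and
per-OTU metadata (target flag, free-text taxonomy label).  External files may
be oriented either way (public contingency tables are usually OTU-rows);
readers normalize to the internal samples-x-OTUs convention.

Supported on-disk formats: tab-separated contingency table (first column OTU
or sample IDs, detected from a header convention or from metadata IDs) and
BIOM-JSON 1.0 (dense or sparse).
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "TargetReference",
    "OTUTableError",
    "read_otu_table",
    "write_otu_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_target_reference",
    "annotate_targets",
]

#: header tokens that mark a TSV whose rows are OTUs (observation-major)
_OTU_ROW_TOKENS = {"#otu id", "#otu_id", "otu id", "otu_id", "otu"}
_SAMPLE_ROW_TOKENS = {"#sample id", "#sample_id", "sample id", "sample_id", "sample"}


class OTUTableError(ValueError):
    """Raised when a contingency table violates its invariants."""


@dataclass(frozen=True)
class TargetReference:
    """The identifiers of the taxa deliberately pooled into the mock sample."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise OTUTableError("target reference must be non-empty")
        if len(set(self.ids)) != len(self.ids):
            raise OTUTableError("target reference identifiers must be unique")

    def __len__(self) -> int:
        return len(self.ids)


def _normalize_label(s: str) -> str:
    return " ".join(str(s).strip().split()).casefold()


@dataclass
class OTUTable:
    """Samples-x-OTUs read-count matrix with sample and OTU metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample_id with OTU ids as columns; non-negative
        integers.
    sample_meta
        DataFrame indexed by sample_id with columns ``primer_index`` and
        ``run`` (small integer labels).  Optional; filled with -1 when absent.
    otu_meta
        DataFrame indexed by otu_id with columns ``is_target`` (bool) and
        ``label`` (str).  Optional; defaults to non-target with the otu_id as
        label.
    allow_empty_samples
        Permit samples whose total read count is zero (needed for simulator
        edge cases); rejected by default.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    otu_meta: pd.DataFrame | None = None
    allow_empty_samples: bool = False

    def __post_init__(self) -> None:
        c = self.counts
        if not isinstance(c, pd.DataFrame):
            raise OTUTableError("counts must be a pandas DataFrame")
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise OTUTableError("counts matrix must have at least one sample and one OTU")
        if c.index.has_duplicates:
            raise OTUTableError("duplicate sample ids in counts")
        if c.columns.has_duplicates:
            raise OTUTableError("duplicate OTU ids in counts")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise OTUTableError("counts must be numeric")
        if np.any(arr < 0):
            raise OTUTableError("negative read counts are not allowed")
        if not np.allclose(arr, np.round(arr)):
            raise OTUTableError("read counts must be integers")
        c = c.astype(np.int64)
        c.index = c.index.astype(str)
        c.columns = c.columns.astype(str)
        object.__setattr__(self, "counts", c)

        if self.sample_meta is None:
            sm = pd.DataFrame(
                {"primer_index": -1, "run": -1}, index=c.index.copy()
            )
        else:
            sm = self.sample_meta.copy()
            sm.index = sm.index.astype(str)
            missing = set(c.index) - set(sm.index)
            if missing:
                raise OTUTableError(f"samples without metadata: {sorted(missing)}")
            sm = sm.loc[c.index, ["primer_index", "run"]].astype(int)
        object.__setattr__(self, "sample_meta", sm)

        if self.otu_meta is None:
            om = pd.DataFrame(
                {"is_target": False, "label": c.columns.astype(str)},
                index=c.columns.copy(),
            )
        else:
            om = self.otu_meta.copy()
            om.index = om.index.astype(str)
            missing = set(c.columns) - set(om.index)
            if missing:
                raise OTUTableError(f"OTUs without metadata: {sorted(missing)}")
            om = om.loc[c.columns, ["is_target", "label"]]
            om["is_target"] = om["is_target"].astype(bool)
            om["label"] = om["label"].astype(str)
        object.__setattr__(self, "otu_meta", om)

        totals = self.counts.sum(axis=1)
        if not self.allow_empty_samples and (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise OTUTableError(
                f"samples with zero reads: {empty} (pass allow_empty_samples=True to keep them)"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def target_ids(self) -> list[str]:
        return list(self.otu_meta.index[self.otu_meta["is_target"]])

    def nontarget_ids(self) -> list[str]:
        return list(self.otu_meta.index[~self.otu_meta["is_target"]])

    def with_counts(self, counts: pd.DataFrame, allow_empty_samples: bool | None = None) -> "OTUTable":
        """New table with replaced counts, metadata subset to the new axes."""
        sm = self.sample_meta.loc[counts.index.astype(str)]
        om = self.otu_meta.loc[counts.columns.astype(str)]
        if allow_empty_samples is None:
            allow_empty_samples = self.allow_empty_samples
        return OTUTable(counts, sm, om, allow_empty_samples=allow_empty_samples)

    def select_otus(self, otu_ids, allow_empty_samples: bool = True) -> "OTUTable":
        return self.with_counts(self.counts[list(otu_ids)], allow_empty_samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.sample_meta.equals(other.sample_meta)
            and self.otu_meta["is_target"].equals(other.otu_meta["is_target"])
            and self.otu_meta["label"].equals(other.otu_meta["label"])
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _orient_samples_by_otus(df: pd.DataFrame, sample_meta: pd.DataFrame | None,
                            index_name: str | None) -> pd.DataFrame:
    """Return the matrix as samples x OTUs, auto-detecting orientation."""
    token = _normalize_label(index_name) if index_name else ""
    if token in _OTU_ROW_TOKENS:
        return df.T
    if token in _SAMPLE_ROW_TOKENS:
        return df
    if sample_meta is not None:
        known = set(sample_meta.index.astype(str))
        if set(df.columns.astype(str)) <= known:
            return df.T
        if set(df.index.astype(str)) <= known:
            return df
    # deposited contingency tables are conventionally OTU-rows
    return df.T


def _read_tsv(path, sample_meta: pd.DataFrame | None) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header[1:]) != len(set(header[1:])):
        raise OTUTableError(f"duplicate column ids in {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except Exception as exc:  # pragma: no cover - pandas names the line itself
        raise OTUTableError(f"malformed contingency table {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise OTUTableError(f"duplicate row ids in {path}")
    if df.columns.has_duplicates:
        raise OTUTableError(f"duplicate column ids in {path}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise OTUTableError(f"non-numeric count at row {row!r}, column {col!r} in {path}")
    return _orient_samples_by_otus(df, sample_meta, df.index.name)


def _read_biom_json(path) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise OTUTableError(f"malformed BIOM-JSON {path}: line {exc.lineno}: {exc.msg}") from exc
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise OTUTableError(f"BIOM-JSON {path} missing required field {key!r}")
    n_obs, n_samp = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    if len(otu_ids) != n_obs or len(sample_ids) != n_samp:
        raise OTUTableError(f"BIOM-JSON {path}: shape does not match rows/columns")
    mat = np.zeros((n_obs, n_samp))
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise OTUTableError(f"BIOM-JSON {path}: unknown matrix_type {doc['matrix_type']!r}")
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)

    sm = om = None
    if all(c.get("metadata") for c in doc["columns"]):
        sm = pd.DataFrame(
            {
                "primer_index": [int(c["metadata"].get("primer_index", -1)) for c in doc["columns"]],
                "run": [int(c["metadata"].get("run", -1)) for c in doc["columns"]],
            },
            index=sample_ids,
        )
    if all(r.get("metadata") for r in doc["rows"]):
        om = pd.DataFrame(
            {
                "is_target": [bool(r["metadata"].get("is_target", False)) for r in doc["rows"]],
                "label": [str(r["metadata"].get("label", r["id"])) for r in doc["rows"]],
            },
            index=otu_ids,
        )
    return counts, sm, om


def read_otu_table(
    path,
    format_hint: str | None = None,
    sample_meta: pd.DataFrame | None = None,
    otu_meta: pd.DataFrame | None = None,
    allow_empty_samples: bool = False,
) -> OTUTable:
    """Read a contingency table from TSV or BIOM-JSON 1.0.

    ``format_hint`` is ``"tsv"`` or ``"biom"``; when omitted it is inferred
    from the filename extension (``.biom``/``.json`` -> BIOM).  Metadata frames
    given here override any embedded in the file.
    """
    path = str(path)
    if format_hint is None:
        format_hint = "biom" if path.endswith((".biom", ".json")) else "tsv"
    if format_hint == "biom":
        counts, sm, om = _read_biom_json(path)
        sample_meta = sample_meta if sample_meta is not None else sm
        otu_meta = otu_meta if otu_meta is not None else om
    elif format_hint == "tsv":
        counts = _read_tsv(path, sample_meta)
    else:
        raise OTUTableError(f"unknown format hint {format_hint!r}")
    return OTUTable(counts, sample_meta, otu_meta, allow_empty_samples=allow_empty_samples)


def write_otu_table(table: OTUTable, path, format_hint: str | None = None) -> None:
    """Write a table as TSV (OTU-rows, ``#OTU ID`` header) or BIOM-JSON 1.0 (dense)."""
    path = str(path)
    if format_hint is None:
        format_hint = "biom" if path.endswith((".biom", ".json")) else "tsv"
    if format_hint == "tsv":
        out = table.counts.T
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")
    elif format_hint == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "mockrep",
            "date": datetime.datetime.now().isoformat(),
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_otus, table.n_samples],
            "rows": [
                {
                    "id": oid,
                    "metadata": {
                        "is_target": bool(table.otu_meta.at[oid, "is_target"]),
                        "label": str(table.otu_meta.at[oid, "label"]),
                    },
                }
                for oid in table.otu_ids
            ],
            "columns": [
                {
                    "id": sid,
                    "metadata": {
                        "primer_index": int(table.sample_meta.at[sid, "primer_index"]),
                        "run": int(table.sample_meta.at[sid, "run"]),
                    },
                }
                for sid in table.sample_ids
            ],
            "data": table.counts.T.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise OTUTableError(f"unknown format hint {format_hint!r}")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, primer_index, run."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"sample_id", "primer_index", "run"}
    if not required <= set(df.columns):
        raise OTUTableError(f"sample metadata must have columns {sorted(required)}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return df[["primer_index", "run"]].astype(int)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_target_reference(path) -> TargetReference:
    """Read a one-identifier-per-line target reference list."""
    with open(path) as fh:
        ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return TargetReference(tuple(ids))


def annotate_targets(table: OTUTable, reference: TargetReference) -> OTUTable:
    """Flag each OTU as target/non-target by exact normalized identifier match.

    A reference identifier matches an OTU if it equals the OTU id or the OTU
    label after whitespace/case normalization.  Identifiers matching zero OTUs
    and identifiers matching more than one OTU are reported as warnings, never
    silently dropped.
    """
    by_key: dict[str, list[str]] = {}
    for oid in table.otu_ids:
        by_key.setdefault(_normalize_label(oid), []).append(oid)
        lab = _normalize_label(table.otu_meta.at[oid, "label"])
        if lab != _normalize_label(oid):
            by_key.setdefault(lab, []).append(oid)

    flags = pd.Series(False, index=table.counts.columns)
    for ref_id in reference.ids:
        hits = by_key.get(_normalize_label(ref_id), [])
        if len(hits) == 0:
            warnings.warn(f"target reference id {ref_id!r} matched no OTU", stacklevel=2)
        elif len(set(hits)) > 1:
            warnings.warn(
                f"target reference id {ref_id!r} matched multiple OTUs: {sorted(set(hits))}",
                stacklevel=2,
            )
            flags[list(set(hits))] = True
        else:
            flags[hits[0]] = True

    om = table.otu_meta.copy()
    om["is_target"] = flags.astype(bool).to_numpy()
    return OTUTable(table.counts.copy(), table.sample_meta.copy(), om,
                    allow_empty_samples=table.allow_empty_samples)
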