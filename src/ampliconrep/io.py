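"""OTU count tables and sample metadata: containers, readers, writers.

The universal currency of the package is the :class:`CountTable`: an integer
samples x OTUs read-count matrix with aligned per-sample metadata.  Tables are
exchanged as UTF-8 tab-separated text in either orientation (samples as rows
or OTUs as rows — both are common in the wild, so the orientation is an
explicit argument, never guessed).  A dense BIOM-style JSON dialect can be
read behind a flag.

Missing cells are an error, not implicit zeros: silent zero-filling hides
upstream corruption.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMeta",
    "CountTableFormatError",
    "CountTableValidationError",
    "read_count_table",
    "write_count_table",
    "attach_metadata",
]

REQUIRED_METADATA_COLUMNS = ("sample_id", "source_id", "pool_size", "platform", "group")


class CountTableFormatError(ValueError):
    """Malformed table file (duplicate identifiers, ragged rows, ...)."""


class CountTableValidationError(ValueError):
    """Well-formed file whose content violates a CountTable invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample experimental metadata.

    ``source_id`` names the underlying biological sample (e.g. a soil core);
    several sequencing libraries (technical replicates, pooling treatments)
    may share one source.  ``pool_size`` is the number of independent PCR
    reactions pooled before sequencing; ``group`` is the ecological grouping
    (site or bioregion) used by between-sample analyses.
    """

    sample_id: str
    source_id: str
    pool_size: int
    platform: str
    group: str
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if int(self.pool_size) < 1:
            raise CountTableValidationError(
                f"pool_size must be >= 1, got {self.pool_size} for {self.sample_id}"
            )
        object.__setattr__(self, "pool_size", int(self.pool_size))
        object.__setattr__(self, "replicate_index", int(self.replicate_index))


@dataclass
class CountTable:
    """Samples x OTUs integer read-count matrix with aligned metadata.

    Invariants (enforced at construction): counts are non-negative integers;
    row order matches ``sample_ids`` and column order matches ``otu_ids``;
    identifiers are unique.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    metadata: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise CountTableValidationError("counts must be integers")
        counts = counts.astype(np.int64).reshape(len(self.sample_ids), len(self.otu_ids))
        if counts.size and counts.min() < 0:
            raise CountTableValidationError("counts must be non-negative")
        self.counts = counts
        for name, ids in (("otu", self.otu_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise CountTableFormatError(f"duplicate {name} identifiers: {dupes}")
        extra = set(self.metadata) - set(self.sample_ids)
        if extra:
            raise CountTableValidationError(f"metadata for unknown samples: {sorted(extra)}")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """The count vector (over ``otu_ids``) for one sample."""
        return self.counts[self.sample_ids.index(sample_id)]

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def subset_samples(self, keep: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in keep]
        meta = {s: self.metadata[s] for s in keep if s in self.metadata}
        return CountTable(list(self.otu_ids), list(keep), self.counts[idx], meta)

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed by sample_id (samples lacking
        metadata are absent)."""
        rows = [vars(m) for s, m in self.metadata.items()]
        if not rows:
            return pd.DataFrame(columns=list(REQUIRED_METADATA_COLUMNS))
        return pd.DataFrame(rows).set_index("sample_id", drop=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and self.metadata == other.metadata
        )


# -- readers / writers -----------------------------------------------------


def _parse_cell(raw: str, row_id: str, col_id: str) -> int:
    try:
        value = float(raw)
    except ValueError as exc:
        raise CountTableFormatError(
            f"non-numeric cell {raw!r} at ({row_id}, {col_id})"
        ) from exc
    if not float(value).is_integer():
        raise CountTableValidationError(
            f"fractional count {raw!r} at ({row_id}, {col_id})"
        )
    if value < 0:
        raise CountTableValidationError(
            f"negative count {raw!r} at ({row_id}, {col_id})"
        )
    return int(value)


def read_count_table(
    path: str | Path,
    orientation: str = "samples-as-rows",
    format: str = "tsv",
) -> CountTable:
    """Read a count table from tab-separated text (or dense BIOM JSON).

    ``orientation`` declares how the *file* is laid out; the returned table is
    always normalized to samples-as-rows.  The first header cell (commonly
    ``#OTU_ID``) is ignored.  Set ``format="biom-json"`` to read the dense
    BIOM JSON dialect instead.
    """
    if format == "biom-json":
        return _read_biom_json(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    if orientation not in ("samples-as-rows", "otus-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CountTableFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        raise CountTableFormatError(f"{path}: duplicate column identifiers")
    row_ids: list[str] = []
    body: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise CountTableFormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        row_ids.append(cells[0])
        body.append([_parse_cell(c, cells[0], col_ids[j]) for j, c in enumerate(cells[1:])])
    if len(set(row_ids)) != len(row_ids):
        raise CountTableFormatError(f"{path}: duplicate row identifiers")

    matrix = np.asarray(body, dtype=np.int64).reshape(len(row_ids), len(col_ids))
    if orientation == "samples-as-rows":
        return CountTable(col_ids, row_ids, matrix)
    return CountTable(row_ids, col_ids, matrix.T)


def _read_biom_json(path: str | Path) -> CountTable:
    """Dense BIOM-style JSON: rows are observations (OTUs), columns samples."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("matrix_type") != "dense":
        raise CountTableFormatError("only dense BIOM JSON is supported")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    data = np.asarray(doc["data"], dtype=float)
    return CountTable(otu_ids, sample_ids, data.T)


def write_count_table(
    table: CountTable,
    path: str | Path,
    orientation: str = "samples-as-rows",
) -> None:
    """Write a table as UTF-8 TSV; inverse of :func:`read_count_table`."""
    if orientation not in ("samples-as-rows", "otus-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "samples-as-rows":
        corner, cols, rows, matrix = "sample_id", table.otu_ids, table.sample_ids, table.counts
    else:
        corner, cols, rows, matrix = "#OTU_ID", table.sample_ids, table.otu_ids, table.counts.T
    out = ["\t".join([corner, *cols])]
    for rid, row in zip(rows, matrix):
        out.append("\t".join([rid, *(str(int(v)) for v in row)]))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def write_metadata(table: CountTable, path: str | Path) -> None:
    """Write the sample metadata sheet as TSV (columns as required by
    :func:`attach_metadata`)."""
    frame = table.meta_frame()
    cols = ["sample_id", "source_id", "pool_size", "platform", "group", "replicate_index"]
    frame.to_csv(path, sep="\t", index=False, columns=cols)


def attach_metadata(table: CountTable, metadata_path: str | Path) -> CountTable:
    """Join a TSV metadata sheet (keyed by ``sample_id``) onto a table.

    Every sample in the table must appear in the sheet; extra metadata rows
    are ignored with a warning.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise CountTableValidationError(f"metadata missing columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise CountTableFormatError(f"duplicate metadata sample_ids: {dupes}")
    meta = meta.set_index("sample_id", drop=False)
    absent = [s for s in table.sample_ids if s not in meta.index]
    if absent:
        raise CountTableValidationError(f"samples missing from metadata: {absent}")
    extra = [s for s in meta.index if s not in table.sample_ids]
    if extra:
        warnings.warn(f"metadata rows for unknown samples ignored: {extra}", stacklevel=2)

    out: dict[str, SampleMeta] = {}
    for sid in table.sample_ids:
        row = meta.loc[sid]
        try:
            pool = int(row["pool_size"])
        except (TypeError, ValueError) as exc:
            raise CountTableValidationError(
                f"pool_size for {sid} is not an integer: {row['pool_size']!r}"
            ) from exc
        rep = row.get("replicate_index", 0)
        out[sid] = SampleMeta(
            sample_id=sid,
            source_id=str(row["source_id"]),
            pool_size=pool,
            platform=str(row["platform"]),
            group=str(row["group"]),
            replicate_index=int(rep) if not pd.isna(rep) else 0,
        )
    return replace(table, metadata=out)
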