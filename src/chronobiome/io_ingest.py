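"""Reading abundance and metadata tables and assembling per-source time series.

Two abundance dialects are supported: the QIIME-classic OTU table (a TSV whose
header line starts with ``#OTU ID`` and whose last column may hold semicolon
delimited taxonomy lineages) and a plain TSV with row identifiers in the first
column.  Metadata is a four-column TSV (``sample_id``, ``source``, ``time``,
``condition``) mapping every sample to a subject/environment, a numeric time
stamp and a condition label.

The central container, :class:`TimeSeriesDataset`, holds the taxa-by-timepoint
abundance matrix of a single source with its columns sorted by time.  All
downstream analyses (diversity, stationarity, warping distances, causality,
community states) operate on this container and treat the time stamps as
ordinal positions; the recorded spacing is informational only, and a warning is
raised when it is non-uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "MetadataTable",
    "TimeSeriesDataset",
    "read_abundance_table",
    "read_metadata",
    "build_dataset",
    "aggregate_to_level",
    "write_dataset",
    "read_dataset",
]

#: header cells recognised as the taxonomy column of a QIIME-classic table
_TAXONOMY_COLUMNS = {"Consensus Lineage", "taxonomy", "Taxonomy"}
_QIIME_HEADERS = ("#OTU ID", "#OTU_ID")

UNCLASSIFIED = "Unclassified"


class ParseError(ValueError):
    """Malformed input file (bad header, non-numeric cell, ...)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass
class AbundanceTable:
    """Taxa-by-sample count matrix with optional taxonomy lineages."""

    row_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_rows, n_samples), non-negative
    lineages: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row identifiers in abundance table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers in abundance table")
        if self.lineages is not None and len(self.lineages) != len(self.row_ids):
            raise ValidationError("lineages must have one entry per row")
        bad = np.argwhere(self.counts < 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"negative abundance at row {self.row_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )


@dataclass
class MetadataTable:
    """Per-sample source, time stamp and condition label."""

    frame: pd.DataFrame  # columns: sample_id, source, time, condition

    def __post_init__(self) -> None:
        required = ["sample_id", "source", "time", "condition"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ParseError(f"metadata missing required column(s): {missing}")
        dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate sample_id in metadata: {sorted(set(dup))}")
        if not np.issubdtype(self.frame["time"].dtype, np.number):
            raise ParseError("metadata time column is not numeric")

    def sources(self) -> list[str]:
        return sorted(self.frame["source"].unique())


@dataclass
class TimeSeriesDataset:
    """Abundances of one source's taxa across time-ordered samples.

    ``normalization`` is one of ``"none"``, ``"relative"`` or
    ``"rarefied:<depth>"`` and records how the matrix columns were scaled.
    """

    source: str
    taxa: list[str]
    times: np.ndarray  # strictly increasing, length T
    conditions: list[str]
    abundance: np.ndarray  # (len(taxa), T)
    normalization: str = "none"
    lineages: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"time stamps must be strictly increasing within source "
                f"{self.source!r}"
            )
        if self.abundance.shape != (len(self.taxa), len(self.times)):
            raise ValidationError("abundance shape does not match taxa x times")
        if len(self.conditions) != len(self.times):
            raise ValidationError("conditions must have one entry per time point")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def copy_with(self, **kwargs) -> "TimeSeriesDataset":
        return replace(self, **kwargs)

    def series(self, taxon: str) -> np.ndarray:
        return self.abundance[self.taxa.index(taxon)]


def _parse_numeric_cell(value: str, row_id: str, col: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"non-numeric abundance {value!r} at row {row_id!r}, column {col!r}"
        ) from None
    if x < 0:
        raise ValidationError(
            f"negative abundance {value!r} at row {row_id!r}, column {col!r}"
        )
    return x


def read_abundance_table(path, format: str = "qiime_classic") -> AbundanceTable:
    """Parse an OTU/taxon abundance table.

    Parameters
    ----------
    path
        TSV file.  ``qiime_classic`` requires a header line beginning
        ``#OTU ID`` (or ``#OTU_ID``); a trailing taxonomy column named
        ``Consensus Lineage`` / ``taxonomy`` / ``Taxonomy`` is stored as
        lineages.  ``tsv`` treats the first column as row id and every other
        column as a numeric sample.
    """
    if format not in ("qiime_classic", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header_idx = 0
    if format == "qiime_classic":
        # tolerate QIIME's leading "# Constructed from biom file" comment
        while header_idx < len(lines) and not lines[header_idx].startswith(_QIIME_HEADERS):
            if not lines[header_idx].startswith("#"):
                raise ParseError(
                    f"{path}: expected a header starting with '#OTU ID', got "
                    f"{lines[header_idx].splitlines()[0]!r}"
                )
            header_idx += 1
        if header_idx == len(lines):
            raise ParseError(f"{path}: no '#OTU ID' header line found")
    header = lines[header_idx].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: header has no sample columns: {header!r}")
    tax_col = None
    if format == "qiime_classic" and header[-1].strip() in _TAXONOMY_COLUMNS:
        tax_col = len(header) - 1
    sample_ids = [h.strip() for h in header[1 : tax_col if tax_col else len(header)]]

    row_ids: list[str] = []
    lineages: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[header_idx + 1 :]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{path}: row {parts[0]!r} has {len(parts)} fields, "
                f"header has {len(header)}"
            )
        rid = parts[0].strip()
        row_ids.append(rid)
        if tax_col is not None:
            lineages.append(parts[tax_col].strip())
            values = parts[1:tax_col]
        else:
            values = parts[1:]
        rows.append(
            [_parse_numeric_cell(v, rid, sample_ids[j]) for j, v in enumerate(values)]
        )
    return AbundanceTable(
        row_ids=row_ids,
        sample_ids=sample_ids,
        counts=np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids))),
        lineages=lineages if tax_col is not None else None,
    )


def read_metadata(path) -> MetadataTable:
    """Parse the sample metadata TSV (sample_id, source, time, condition)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "source": str})
    if "time" in frame.columns:
        try:
            frame["time"] = pd.to_numeric(frame["time"])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric time value ({exc})") from None
    if "condition" in frame.columns:
        frame["condition"] = frame["condition"].astype(str)
    return MetadataTable(frame=frame)


def build_dataset(
    table: AbundanceTable, meta: MetadataTable, source: str
) -> TimeSeriesDataset:
    """Assemble a time-ordered dataset for one source.

    Columns of ``table`` are selected by the metadata rows of ``source`` and
    reordered by ascending time stamp; condition labels are carried through.
    """
    sel = meta.frame[meta.frame["source"] == source]
    if sel.empty:
        raise ValidationError(
            f"source {source!r} not present in metadata "
            f"(available: {meta.sources()})"
        )
    if sel["time"].duplicated().any():
        dup_t = sorted(sel["time"][sel["time"].duplicated()].unique())
        raise ValidationError(
            f"source {source!r} has tied time stamps {dup_t}; one observation "
            "per time point is required"
        )
    sel = sel.sort_values("time")
    missing = [s for s in sel["sample_id"] if s not in table.sample_ids]
    if missing:
        raise ValidationError(
            f"metadata samples missing from abundance table: {missing}"
        )
    col_index = [table.sample_ids.index(s) for s in sel["sample_id"]]
    times = sel["time"].to_numpy(dtype=float)
    if len(times) > 2:
        steps = np.diff(times)
        if not np.allclose(steps, steps[0]):
            warnings.warn(
                f"source {source!r}: non-uniform time spacing; all analyses "
                "treat time points as equally spaced ordinals",
                stacklevel=2,
            )
    return TimeSeriesDataset(
        source=source,
        taxa=list(table.row_ids),
        times=times,
        conditions=list(sel["condition"]),
        abundance=table.counts[:, col_index],
        lineages=list(table.lineages) if table.lineages is not None else None,
        sample_ids=list(sel["sample_id"]),
    )


def _lineage_prefix(lineage: str, level: int) -> str:
    """Join the first ``level``+1 ranks; blank ranks become Unclassified."""
    ranks = [r.strip() for r in lineage.split(";")]
    ranks = ranks[: level + 1]
    while len(ranks) < level + 1:
        ranks.append("")
    cleaned = []
    for r in ranks:
        # greengenes-style empty ranks look like 'g__' or are blank
        if not r or r.endswith("__"):
            cleaned.append(UNCLASSIFIED)
        else:
            cleaned.append(r)
    return ";".join(cleaned)


def aggregate_to_level(dataset: TimeSeriesDataset, level: int) -> TimeSeriesDataset:
    """Sum rows sharing a lineage prefix up to rank index ``level`` (0-based).

    Column totals are conserved; rows lacking a label at the requested rank
    are pooled under ``Unclassified``.  Aggregated row labels keep the last
    rank of the prefix (e.g. ``g__Dorea``) when it is informative.
    """
    if dataset.lineages is None:
        raise ValidationError(
            "dataset has no lineage information; supply a QIIME-classic table "
            "with a taxonomy column, or use a plain TSV whose row ids already "
            "are taxa at the desired level"
        )
    groups: dict[str, list[int]] = {}
    for i, lineage in enumerate(dataset.lineages):
        groups.setdefault(_lineage_prefix(lineage, level), []).append(i)
    ordered = sorted(groups)
    matrix = np.vstack(
        [dataset.abundance[groups[key]].sum(axis=0) for key in ordered]
    )
    labels = []
    for key in ordered:
        last = key.split(";")[-1]
        labels.append(last if last != UNCLASSIFIED else key)
    # de-duplicate labels that collapse (e.g. several Unclassified branches)
    seen: dict[str, int] = {}
    unique_labels = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            lab = f"{lab}__{seen[lab]}"
        else:
            seen[lab] = 0
        unique_labels.append(lab)
    return dataset.copy_with(
        taxa=unique_labels, abundance=matrix, lineages=ordered
    )


def write_dataset(dataset: TimeSeriesDataset, path) -> None:
    """Canonical TSV dump: taxa rows, time-ordered columns, two header rows."""
    with open(path, "w") as fh:
        fh.write("#time\t" + "\t".join(repr(float(t)) for t in dataset.times) + "\n")
        fh.write("#condition\t" + "\t".join(dataset.conditions) + "\n")
        fh.write(f"#source={dataset.source}\tnormalization={dataset.normalization}\n")
        for taxon, row in zip(dataset.taxa, dataset.abundance):
            fh.write(taxon + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_dataset(path) -> TimeSeriesDataset:
    """Inverse of :func:`write_dataset`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3 or not lines[0].startswith("#time"):
        raise ParseError(f"{path}: not a dataset dump (missing '#time' header)")
    times = [float(v) for v in lines[0].split("\t")[1:]]
    conditions = lines[1].split("\t")[1:]
    meta = dict(kv.split("=", 1) for kv in lines[2].lstrip("#").split("\t"))
    taxa, rows = [], []
    for ln in lines[3:]:
        parts = ln.split("\t")
        taxa.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return TimeSeriesDataset(
        source=meta.get("source", ""),
        taxa=taxa,
        times=np.array(times),
        conditions=conditions,
        abundance=np.array(rows),
        normalization=meta.get("normalization", "none"),
    )
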