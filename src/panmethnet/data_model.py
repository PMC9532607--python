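"""Core domain containers and Xena-dialect TSV readers/writers.

Every analysis module operates on four table kinds:

* :class:`OmicsMatrix` — a features × samples numeric matrix (expression on
  the log2(fpkm + 0.001) scale, 450K methylation beta values in [0, 1], or
  RPPA protein levels), carried as a pandas DataFrame with feature ids on the
  index and sample ids on the columns.
* feature annotation — one row per feature: gene grouping, feature class
  (gene / isoform / probeset / protein), isoform biotype, and for probesets
  the gene region (promoter / 1st exon / body / 3'UTR).
* sample metadata — cohort code (tumor-type, e.g. "READ"), tumor/normal
  source, and an optional tumor-group label in 1..9 governing protein-panel
  availability.
* survival records — long-format (sample, endpoint, time, event) rows for
  the OS and PFI endpoints.

The on-disk dialect is the Xena genomicMatrix flavour: tab-separated, first
column holds feature ids, header row holds sample ids, and missing cells are
written as ``NA`` (on read, ``NA`` in any case and the empty string are
missing). Genomic intervals, when present in annotations, use 0-based
half-open (BED) coordinates and are metadata only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("panmethnet")

VALUE_KINDS = ("expression_log2fpkm", "methylation_beta", "protein_rppa")

#: minimum attainable value on the log2(fpkm + 0.001) expression scale
EXPRESSION_FLOOR = math.log2(0.001)

FEATURE_CLASSES = ("gene", "isoform", "probeset", "protein")
BIOTYPES = ("coding", "non_coding", "retained_intron", "not_applicable")
GENE_REGIONS = ("promoter", "first_exon", "body", "utr3", "not_applicable")
#: regions whose methylation is expected to repress vs track transcription
PROMOTER_LIKE_REGIONS = ("promoter", "first_exon")
BODY_LIKE_REGIONS = ("body", "utr3")

ENDPOINTS = ("OS", "PFI")

MISSING_TOKEN = "NA"

ANNOTATION_COLUMNS = (
    "feature_id", "gene_symbol", "feature_class", "biotype", "gene_region",
    "chrom", "chromStart", "chromEnd", "strand",
)
PHENOTYPE_COLUMNS = ("sample_id", "cohort", "source", "tumor_group")
SURVIVAL_COLUMNS = ("sample_id", "endpoint", "time", "event")


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class OmicsMatrix:
    """Features × samples numeric matrix with typed value semantics.

    Parameters
    ----------
    values
        DataFrame with feature ids on the index and sample ids on the
        columns; NaN marks missing measurements.
    value_kind
        One of ``expression_log2fpkm``, ``methylation_beta``,
        ``protein_rppa``. Beta matrices are range-checked to [0, 1].
    """

    values: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"unknown value_kind {self.value_kind!r}; expected one of {VALUE_KINDS}"
            )
        dup = _first_duplicate(self.values.index)
        if dup is not None:
            raise ValueError(f"duplicate feature id: {dup!r}")
        dup = _first_duplicate(self.values.columns)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.values = self.values.astype(float)
        if self.value_kind == "methylation_beta":
            arr = self.values.to_numpy()
            bad = np.argwhere((arr < 0.0) | (arr > 1.0))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    "beta value outside [0, 1] at feature "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}: "
                    f"{arr[i, j]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[:, list(sample_ids)], self.value_kind)

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(feature_ids), :], self.value_kind)

    def equals(self, other: "OmicsMatrix") -> bool:
        return (
            self.value_kind == other.value_kind
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(
                self.values.to_numpy(), other.values.to_numpy(), equal_nan=True
            )
        )


# ---------------------------------------------------------------------------
# genomicMatrix TSV I/O
# ---------------------------------------------------------------------------

def _format_cell(v: float) -> str:
    if isinstance(v, float) and math.isnan(v):
        return MISSING_TOKEN
    return repr(float(v))


def read_matrix(path: str | Path, value_kind: str) -> OmicsMatrix:
    """Read a Xena genomicMatrix TSV (feature ids first column, sample ids
    header). Empty cells and ``NA`` (any case) are missing; duplicates and
    out-of-range beta values are hard errors.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty file, header required")
        sample_ids = header.rstrip("\n").split("\t")[1:]
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"got {len(parts)}"
                )
            feature_ids.append(parts[0])
            row: list[float] = []
            for cell in parts[1:]:
                if cell == "" or cell.upper() == MISSING_TOKEN:
                    row.append(float("nan"))
                else:
                    row.append(float(cell))
            rows.append(row)
    dup = _first_duplicate(feature_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate feature id: {dup!r}")
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample id: {dup!r}")
    frame = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(feature_ids), len(sample_ids)),
        index=feature_ids,
        columns=sample_ids,
    )
    return OmicsMatrix(frame, value_kind)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write the dialect :func:`read_matrix` accepts; missing cells as ``NA``.

    Output is byte-deterministic: cell text is the shortest round-tripping
    float representation.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        arr = matrix.values.to_numpy()
        for i, fid in enumerate(matrix.feature_ids):
            cells = "\t".join(_format_cell(v) for v in arr[i])
            fh.write(fid + ("\t" + cells if matrix.sample_ids else "") + "\n")


def align_samples(
    matrices: Sequence[OmicsMatrix],
    metadata: pd.DataFrame | None = None,
) -> list[OmicsMatrix]:
    """Restrict all matrices to their shared samples, ordered as in the
    first matrix (optionally intersected with ``metadata`` sample ids).

    Idempotent; errors on an empty intersection.
    """
    if not matrices:
        raise ValueError("align_samples requires at least one matrix")
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    if metadata is not None:
        shared &= set(metadata["sample_id"])
    order = [s for s in matrices[0].sample_ids if s in shared]
    if not order:
        raise ValueError("no shared samples across matrices")
    out = []
    for m in matrices:
        dropped = m.shape[1] - len(order)
        if dropped:
            logger.info("align_samples: dropping %d samples from %s matrix",
                        dropped, m.value_kind)
        out.append(m.subset_samples(order))
    return out


# ---------------------------------------------------------------------------
# annotation / phenotype / survival tables
# ---------------------------------------------------------------------------

def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS[:5] if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    dup = _first_duplicate(annotation["feature_id"])
    if dup is not None:
        raise ValueError(f"duplicate annotated feature: {dup!r}")
    bad_class = set(annotation["feature_class"]) - set(FEATURE_CLASSES)
    if bad_class:
        raise ValueError(f"unknown feature_class values: {sorted(bad_class)}")
    bad_region = set(annotation["gene_region"]) - set(GENE_REGIONS)
    if bad_region:
        raise ValueError(f"unknown gene_region values: {sorted(bad_region)}")
    is_probe = annotation["feature_class"] == "probeset"
    if (annotation.loc[is_probe, "gene_region"] == "not_applicable").any():
        bad = annotation.loc[
            is_probe & (annotation["gene_region"] == "not_applicable"), "feature_id"
        ].iloc[0]
        raise ValueError(f"probeset {bad!r} lacks a gene_region")
    if (annotation.loc[~is_probe, "gene_region"] != "not_applicable").any():
        bad = annotation.loc[
            ~is_probe & (annotation["gene_region"] != "not_applicable"), "feature_id"
        ].iloc[0]
        raise ValueError(f"non-probeset {bad!r} carries a gene_region")
    return annotation


def read_annotation(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = frame.rename(columns={"id": "feature_id", "gene": "gene_symbol"})
    for col in ANNOTATION_COLUMNS:
        if col not in frame.columns:
            frame[col] = ""
    return validate_annotation(frame[list(ANNOTATION_COLUMNS)])


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annotation)
    annotation.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS[:3] if c not in metadata.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    dup = _first_duplicate(metadata["sample_id"])
    if dup is not None:
        raise ValueError(f"duplicate sample metadata record: {dup!r}")
    bad = set(metadata["source"]) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown source values: {sorted(bad)}")
    if "tumor_group" in metadata.columns:
        tg = pd.to_numeric(metadata["tumor_group"], errors="coerce")
        present = tg.dropna()
        if ((present < 1) | (present > 9)).any():
            raise ValueError("tumor_group outside 1..9")
    return metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", dtype={"sample": str, "cohort": str, "source": str},
        na_values=[MISSING_TOKEN, ""], keep_default_na=False,
    )
    frame = frame.rename(columns={"sample": "sample_id"})
    if "tumor_group" in frame.columns:
        frame["tumor_group"] = frame["tumor_group"].astype("Int64")
    else:
        frame["tumor_group"] = pd.array([pd.NA] * len(frame), dtype="Int64")
    return validate_metadata(frame[list(PHENOTYPE_COLUMNS)])


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(metadata)
    out = metadata.loc[:, list(PHENOTYPE_COLUMNS)].rename(
        columns={"sample_id": "sample"}
    )
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def validate_survival(survival: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in survival.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    bad = set(survival["endpoint"]) - set(ENDPOINTS)
    if bad:
        raise ValueError(f"unknown endpoints: {sorted(bad)}")
    if (survival["time"] < 0).any():
        raise ValueError("negative survival time")
    if not set(survival["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0 or 1")
    dup = survival.duplicated(subset=["sample_id", "endpoint"])
    if dup.any():
        sid = survival.loc[dup, "sample_id"].iloc[0]
        raise ValueError(f"duplicate survival record for sample {sid!r}")
    return survival


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read the wide survival dialect (sample, OS, OS.time, PFI, PFI.time)
    into long (sample_id, endpoint, time, event) rows."""
    wide = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN, ""],
                       keep_default_na=False)
    wide = wide.rename(columns={"sample": "sample_id"})
    records = []
    for endpoint in ENDPOINTS:
        tcol = f"{endpoint}.time"
        if endpoint not in wide.columns or tcol not in wide.columns:
            continue
        sub = wide[["sample_id", endpoint, tcol]].dropna()
        for _, row in sub.iterrows():
            records.append(
                (row["sample_id"], endpoint, float(row[tcol]), int(row[endpoint]))
            )
    long = pd.DataFrame(records, columns=list(SURVIVAL_COLUMNS))
    return validate_survival(long)


def write_survival(survival: pd.DataFrame, path: str | Path) -> None:
    validate_survival(survival)
    wide = None
    for endpoint in ENDPOINTS:
        sub = survival[survival["endpoint"] == endpoint]
        piece = pd.DataFrame({
            "sample": sub["sample_id"].to_numpy(),
            endpoint: sub["event"].to_numpy(),
            f"{endpoint}.time": sub["time"].to_numpy(),
        })
        wide = piece if wide is None else wide.merge(piece, on="sample", how="outer")
    if wide is None:
        wide = pd.DataFrame(columns=["sample"])
    wide = wide.sort_values("sample", kind="stable").reset_index(drop=True)
    for endpoint in ENDPOINTS:
        if endpoint in wide.columns:
            wide[endpoint] = wide[endpoint].astype("Int64")
    wide.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)
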