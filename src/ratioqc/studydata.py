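"""Data model for multi-batch expression studies and ratio-based reference datasets.

The central objects are :class:`StudyDesign` (per-sample annotations defining the
groups x replicates x batches layout), :class:`ExpressionStudy` (a gene x sample
abundance matrix, optionally with a raw-count layer, bound to a design) and
:class:`ReferenceDataset` (per gene and group-pair consensus log2 fold changes
with an uncertainty budget and DEG labels).

All tabular I/O is plain TSV (tab-delimited, UTF-8, '.' decimal); CSV is
accepted on read via ``sep=","``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "DesignSummary",
    "ExpressionStudy",
    "ReferenceDataset",
    "read_expression_matrix",
    "read_study_design",
    "read_reference_dataset",
    "write_reference_dataset",
    "summarize_design",
]

REQUIRED_DESIGN_COLUMNS = ("sample", "group", "replicate", "batch")
OPTIONAL_DESIGN_COLUMNS = ("protocol", "timepoint", "unit")

#: Canonical reference-dataset column order.
REFERENCE_COLUMNS = (
    "gene",
    "pair",
    "log2fc_ref",
    "n_batches",
    "n_up",
    "n_down",
    "u_char",
    "u_bb",
    "u_s",
    "u_c",
    "k",
    "U",
    "deg_label",
)

DEG_LABELS = ("up", "down", "non-DEG", "unassessed")


class StudyDesign:
    """Per-sample annotations: biological group, replicate index and batch.

    Parameters
    ----------
    table:
        One row per sample with columns ``sample``, ``group``, ``replicate``,
        ``batch`` and optionally ``protocol``, ``timepoint`` and ``unit``.
        Unknown columns are preserved as opaque annotations.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(
                f"design is missing required columns {missing}; "
                f"required columns are {list(REQUIRED_DESIGN_COLUMNS)}"
            )
        table = table.copy()
        table["sample"] = table["sample"].astype(str)
        table["group"] = table["group"].astype(str)
        table["batch"] = table["batch"].astype(str)
        table["replicate"] = table["replicate"].astype(int)
        if (table["replicate"] <= 0).any():
            bad = table.loc[table["replicate"] <= 0, "sample"].tolist()
            raise ValueError(f"replicate indices must be positive; offending samples: {bad}")
        if table["sample"].duplicated().any():
            dup = table.loc[table["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample identifier in design: {dup!r}")
        key = table[["group", "replicate", "batch"]].apply(tuple, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate (group, replicate, batch) triple in design: {dup}")
        if "timepoint" in table.columns:
            table["timepoint"] = pd.to_numeric(table["timepoint"])
            if (table["timepoint"].dropna() < 0).any():
                raise ValueError("timepoints must be non-negative (months)")
        self.table = table.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.table["group"]))

    @property
    def batches(self) -> list[str]:
        return list(dict.fromkeys(self.table["batch"]))

    @property
    def m(self) -> int:
        """Number of biological groups."""
        return len(self.groups)

    def n_per_group(self, batch: str | None = None) -> dict[str, int]:
        """Replicates per group, optionally restricted to one batch."""
        sub = self.table if batch is None else self.table[self.table["batch"] == batch]
        return sub.groupby("group", sort=False)["sample"].count().to_dict()

    def samples_in(self, group: str | None = None, batch: str | None = None) -> list[str]:
        sub = self.table
        if group is not None:
            sub = sub[sub["group"] == group]
        if batch is not None:
            sub = sub[sub["batch"] == batch]
        return sub["sample"].tolist()

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample")["group"]

    def batch_of(self) -> pd.Series:
        return self.table.set_index("sample")["batch"]

    def subset(self, samples: Sequence[str]) -> "StudyDesign":
        keep = self.table[self.table["sample"].isin(set(samples))]
        order = {s: i for i, s in enumerate(samples)}
        keep = keep.sort_values("sample", key=lambda s: s.map(order))
        return StudyDesign(keep)

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StudyDesign({len(self)} samples, {self.m} groups, "
            f"{len(self.batches)} batches)"
        )


@dataclass(frozen=True)
class DesignSummary:
    """Pair-count bookkeeping of a design (drives the SNR prefactor)."""

    m: int
    n_per_group: dict[str, int]
    batches: list[str]
    n_samples: int
    between_pairs: int
    within_pairs: int


def summarize_design(design: StudyDesign) -> DesignSummary:
    """Count within- and between-group sample pairs of a design.

    For a design with group sizes ``n_g`` the within-group pair count is
    ``sum_g C(n_g, 2)`` and the between-group pair count is
    ``C(N, 2) - sum_g C(n_g, 2)``.  The standard 4-group x 3-replicate batch
    yields 54 between-group and 12 within-group pairs.
    """
    if design.m < 2:
        raise ValueError("SNR undefined: design has fewer than 2 groups")
    n_per = design.n_per_group()
    n_total = sum(n_per.values())
    within = sum(math.comb(n, 2) for n in n_per.values())
    between = math.comb(n_total, 2) - within
    return DesignSummary(
        m=design.m,
        n_per_group=n_per,
        batches=design.batches,
        n_samples=n_total,
        between_pairs=between,
        within_pairs=within,
    )


class ExpressionStudy:
    """A gene x sample abundance matrix bound to a study design.

    ``values`` holds non-negative continuous abundances (FPKM-like); ``counts``
    optionally holds raw read counts with identical shape.  Matrix columns are
    reordered to match the design's sample order so every downstream operation
    sees one canonical ordering.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        design: StudyDesign,
        counts: pd.DataFrame | None = None,
    ):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        matrix_samples = set(values.columns)
        design_samples = set(design.samples)
        if matrix_samples != design_samples:
            missing = sorted(design_samples - matrix_samples)
            extra = sorted(matrix_samples - design_samples)
            raise ValueError(
                f"matrix samples do not match design: missing {missing}, extra {extra}"
            )
        values = values[design.samples]
        _check_numeric_nonnegative(values, "values")
        if counts is not None:
            if set(counts.columns) != design_samples or not counts.index.equals(values.index):
                raise ValueError("counts layer must share genes and samples with values")
            counts = counts[design.samples]
            _check_numeric_nonnegative(counts, "counts")
        self.values = values
        self.counts = counts
        self.design = design

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionStudy":
        design = self.design.subset(samples)
        counts = None if self.counts is None else self.counts[design.samples]
        return ExpressionStudy(self.values[design.samples], design, counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        layers = "values+counts" if self.counts is not None else "values"
        return f"ExpressionStudy({len(self.genes)} genes x {len(self.samples)} samples, {layers})"


def _check_numeric_nonnegative(df: pd.DataFrame, layer: str) -> None:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{layer} matrix contains non-numeric cells")
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"missing cell in {layer} matrix at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative value in {layer} matrix at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes-in-rows",
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a delimited expression matrix and return it with genes in rows.

    Parameters
    ----------
    orientation:
        ``"genes-in-rows"`` (first column = gene ids, header = sample ids) or
        ``"samples-in-rows"`` (transposed layout).  The returned frame always
        has genes in rows.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError("orientation must be 'genes-in-rows' or 'samples-in-rows'")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if orientation == "samples-in-rows":
        raw = raw.T
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier in {path}: {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier in {path}: {dup!r}")
    try:
        mat = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for gene in raw.index:
            for sample in raw.columns:
                try:
                    float(raw.at[gene, sample])
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric cell in {path} at gene {gene!r}, sample {sample!r}: "
                        f"{raw.at[gene, sample]!r}"
                    ) from None
        raise
    if mat.isna().any().any():
        g = mat.index[mat.isna().any(axis=1)][0]
        s = mat.columns[mat.isna().any(axis=0)][0]
        raise ValueError(f"missing cell in {path} at gene {g!r}, sample {s!r}")
    if (mat.to_numpy() < 0).any():
        idx = np.argwhere(mat.to_numpy() < 0)[0]
        raise ValueError(
            f"negative value in {path} at gene {mat.index[idx[0]]!r}, "
            f"sample {mat.columns[idx[1]]!r}"
        )
    mat.index.name = "gene"
    mat.columns.name = None
    return mat


def read_study_design(path: str | Path, sep: str = "\t") -> StudyDesign:
    """Read a sample-metadata TSV (columns sample/group/replicate/batch[...])."""
    table = pd.read_csv(path, sep=sep)
    return StudyDesign(table)


class ReferenceDataset:
    """Per (gene, group-pair) consensus reference values with uncertainty budget.

    One record per (gene, pair); ``pair`` is the ordered string
    ``"numerator/denominator"``.  ``U == k * u_c`` holds for every quantified
    record; unquantifiable uncertainty fields are NaN.
    """

    def __init__(self, records: pd.DataFrame, validate: bool = True):
        missing = [c for c in REFERENCE_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"reference dataset missing columns {missing}")
        records = records.loc[:, list(REFERENCE_COLUMNS)].copy()
        records["gene"] = records["gene"].astype(str)
        records["pair"] = records["pair"].astype(str)
        if validate and len(records):
            key = records["gene"] + "::" + records["pair"]
            if key.duplicated().any():
                dup = key[key.duplicated()].iloc[0]
                raise ValueError(f"duplicate (gene, pair) record: {dup}")
            bad_label = ~records["deg_label"].isin(DEG_LABELS)
            if bad_label.any():
                raise ValueError(
                    f"invalid deg_label {records.loc[bad_label, 'deg_label'].iloc[0]!r}; "
                    f"allowed: {DEG_LABELS}"
                )
            quant = records.dropna(subset=["U", "u_c", "k"])
            if len(quant):
                resid = (quant["U"] - quant["k"] * quant["u_c"]).abs()
                scale = quant["U"].abs().clip(lower=1.0)
                if (resid > 1e-9 * scale).any():
                    gene = quant.loc[resid > 1e-9 * scale, "gene"].iloc[0]
                    raise ValueError(
                        f"invariant violation U != k * u_c for gene {gene!r}"
                    )
        self.records = records.reset_index(drop=True)

    @property
    def pairs(self) -> list[str]:
        return list(dict.fromkeys(self.records["pair"]))

    def for_pair(self, pair: str) -> pd.DataFrame:
        """Records of one group pair, indexed by gene."""
        sub = self.records[self.records["pair"] == pair]
        if not len(sub):
            raise KeyError(f"pair {pair!r} not in reference (available: {self.pairs})")
        return sub.set_index("gene")

    def deg_labels(self, pair: str) -> pd.Series:
        return self.for_pair(pair)["deg_label"]

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ReferenceDataset({len(self)} records, pairs={self.pairs})"


def write_reference_dataset(ref: ReferenceDataset, path: str | Path) -> None:
    """Serialize a reference dataset as TSV with a deterministic column order.

    Numeric fields use repr-precision floats so a write -> read round trip is
    lossless to well below 1e-12 relative.
    """
    ref.records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_reference_dataset(path: str | Path) -> ReferenceDataset:
    """Read a reference-dataset TSV written by :func:`write_reference_dataset`."""
    try:
        records = pd.read_csv(
            path,
            sep="\t",
            dtype={"gene": str, "pair": str, "deg_label": str},
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed reference dataset {path}: {exc}") from exc
    for i, col in enumerate(REFERENCE_COLUMNS):
        if col not in records.columns:
            raise ValueError(
                f"malformed reference dataset {path}: line 1 is missing column {col!r}"
            )
    numeric = [c for c in REFERENCE_COLUMNS if c not in ("gene", "pair", "deg_label")]
    for col in numeric:
        try:
            records[col] = pd.to_numeric(records[col])
        except (ValueError, TypeError):
            bad = records[pd.to_numeric(records[col], errors="coerce").isna()
                          & records[col].notna()]
            line = int(bad.index[0]) + 2  # header is line 1
            raise ValueError(
                f"malformed reference dataset {path}: non-numeric {col!r} on line {line}"
            ) from None
    return ReferenceDataset(records)
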