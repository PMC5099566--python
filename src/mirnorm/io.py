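"""Containers and readers/writers for qPCR Cq tables, intensity matrices and
sample annotations.

All matrices are genes (rows) x samples (columns) pandas DataFrames wrapped in
thin validating dataclasses. Missing ("Undetermined") wells are represented as
NaN; how they are handled is an explicit policy of :func:`read_cq_table`, never
an implicit default of downstream analyses.

Tables are UTF-8; the delimiter is inferred from the extension (``.csv`` comma,
anything else tab).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqMatrix",
    "IntensityMatrix",
    "SampleAnnotation",
    "TableFormatError",
    "MissingGeneError",
    "read_cq_table",
    "write_cq_table",
    "read_intensity_table",
    "read_annotation",
    "write_annotation",
    "write_report",
]

#: cell contents (lower-cased, stripped) treated as a missing Cq well
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan", "undetermined", "undet", "null", "none"})


class TableFormatError(ValueError):
    """An input table violates the documented layout (duplicates, bad cells...)."""


class MissingGeneError(KeyError):
    """A requested gene is absent from a matrix; the message lists what exists."""

    def __init__(self, gene: str, available: Iterable[str]):
        self.gene = gene
        self.available = list(available)
        super().__init__(
            f"gene {gene!r} not found; available genes: {', '.join(self.available)}"
        )

    def __str__(self) -> str:  # KeyError would re-quote the whole message
        return self.args[0]


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {what} id(s): {dup}")


@dataclass
class CqMatrix:
    """Quantification-cycle (Cq) values, genes x samples.

    Non-missing Cq must be finite and in ``(0, max_cycles]``; the default 40
    matches a standard 40-cycle qPCR program. Missing wells are NaN.
    """

    values: pd.DataFrame
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(v)
        _check_unique(v.index, "gene")
        _check_unique(v.columns, "sample")
        v = v.astype(float)
        arr = v.to_numpy()
        finite = np.isfinite(arr)
        if np.isinf(arr).any():
            raise TableFormatError("Cq values must be finite or missing (NaN)")
        bad = finite & ((arr <= 0.0) | (arr > self.max_cycles))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise TableFormatError(
                f"Cq {arr[g, s]} for gene {v.index[g]!r}, sample {v.columns[s]!r} "
                f"outside (0, {self.max_cycles}]"
            )
        self.values = v

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_missing(self) -> pd.DataFrame:
        return self.values.isna()

    def complete_genes(self) -> list[str]:
        """Genes with a Cq in every sample."""
        mask = self.values.notna().all(axis=1)
        return list(self.values.index[mask])

    def drop_incomplete_genes(self) -> "CqMatrix":
        return CqMatrix(self.values.loc[self.complete_genes()], self.max_cycles)

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "CqMatrix":
        v = self.values
        if genes is not None:
            for g in genes:
                if g not in v.index:
                    raise MissingGeneError(g, v.index)
            v = v.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in v.columns]
            if missing:
                raise TableFormatError(f"unknown sample id(s): {missing}")
            v = v[list(samples)]
        return CqMatrix(v, self.max_cycles)


@dataclass
class IntensityMatrix:
    """Linear-scale expression intensities (arbitrary units, nonnegative)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(v)
        _check_unique(v.index, "gene")
        _check_unique(v.columns, "sample")
        v = v.astype(float)
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise TableFormatError("intensities must be finite")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative intensity for gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        self.values = v

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleAnnotation:
    """Per-sample group labels plus optional covariates and a continuous outcome.

    ``frame`` is indexed by sample id and must carry a ``group`` column.
    Numeric columns other than the outcome (e.g. age in years, weight in kg,
    height in cm) are treated as covariates.
    """

    frame: pd.DataFrame
    outcome: str | None = None

    GROUP_COL = "group"

    def __post_init__(self) -> None:
        f = self.frame
        _check_unique(f.index, "sample")
        if self.GROUP_COL not in f.columns:
            raise TableFormatError("annotation table needs a 'group' column")
        f = f.copy()
        f[self.GROUP_COL] = f[self.GROUP_COL].astype(str)
        if self.outcome is not None and self.outcome not in f.columns:
            raise TableFormatError(f"outcome column {self.outcome!r} not in annotation")
        self.frame = f

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.frame[self.GROUP_COL]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def covariate_columns(self) -> list[str]:
        cols = []
        for c in self.frame.columns:
            if c == self.GROUP_COL or c == self.outcome:
                continue
            if pd.api.types.is_numeric_dtype(self.frame[c]):
                cols.append(c)
        return cols

    def group_of(self, samples: Sequence[str]) -> pd.Series:
        missing = [s for s in samples if s not in self.frame.index]
        if missing:
            raise TableFormatError(f"samples without annotation: {missing}")
        return self.frame.loc[list(samples), self.GROUP_COL]

    def samples_in(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame[self.GROUP_COL] == group])

    def subset(self, samples: Sequence[str]) -> "SampleAnnotation":
        self.group_of(samples)  # validates presence
        return SampleAnnotation(self.frame.loc[list(samples)], self.outcome)

    def require_groups(self, min_groups: int = 2, min_per_group: int = 2) -> None:
        sizes = self.frame[self.GROUP_COL].value_counts()
        if len(sizes) < min_groups:
            raise ValueError(f"need at least {min_groups} groups, found {len(sizes)}")
        small = sizes[sizes < min_per_group]
        if len(small):
            raise ValueError(
                f"groups with fewer than {min_per_group} samples: {dict(small)}"
            )


# ---------------------------------------------------------------------------
# readers / writers

def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_cq_cell(text: object, gene: object, sample: object) -> float:
    t = str(text).strip()
    if t.lower() in MISSING_TOKENS:
        return math.nan
    try:
        return float(t)
    except ValueError:
        raise TableFormatError(
            f"non-numeric Cq {text!r} for gene {gene!r}, sample {sample!r}"
        ) from None


def read_cq_table(path: str | Path, layout: str = "wide",
                  missing_policy: str = "drop", max_cycles: float = 40.0) -> CqMatrix:
    """Read a Cq table.

    Parameters
    ----------
    layout
        ``"wide"``: genes x samples with a header row, gene ids in the first
        column. ``"long"``: columns (gene, sample, cq).
    missing_policy
        ``"drop"`` leaves "Undetermined" wells as NaN so the gene-sample pair
        is dropped from analyses requiring complete profiles; ``"max_cycle"``
        imputes ``max_cycles``.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    if missing_policy not in ("drop", "max_cycle"):
        raise ValueError(f"missing_policy must be 'drop' or 'max_cycle', got {missing_policy!r}")
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.empty or raw.shape[1] < 2:
        raise TableFormatError(f"empty or degenerate Cq table: {path}")

    if layout == "wide":
        genes = raw.iloc[:, 0].astype(str).str.strip()
        if genes.duplicated().any():
            raise TableFormatError(
                f"duplicate gene id(s) in {path}: {genes[genes.duplicated()].unique().tolist()}"
            )
        samples = [str(c).strip() for c in raw.columns[1:]]
        data = np.empty((len(genes), len(samples)))
        for i, g in enumerate(genes):
            for j, s in enumerate(samples):
                data[i, j] = _parse_cq_cell(raw.iat[i, j + 1], g, s)
        values = pd.DataFrame(data, index=list(genes), columns=samples)
    else:
        cols = {str(c).strip().lower(): c for c in raw.columns}
        needed = ("gene", "sample", "cq")
        if not all(k in cols for k in needed):
            raise TableFormatError(
                f"long layout needs columns (gene, sample, cq); found {list(raw.columns)}"
            )
        tab = raw[[cols["gene"], cols["sample"], cols["cq"]]].copy()
        tab.columns = ["gene", "sample", "cq"]
        tab["gene"] = tab["gene"].astype(str).str.strip()
        tab["sample"] = tab["sample"].astype(str).str.strip()
        dup = tab.duplicated(["gene", "sample"], keep=False)
        if dup.any():
            first = tab[dup].iloc[0]
            raise TableFormatError(
                f"duplicate (gene, sample) pair ({first['gene']!r}, {first['sample']!r}) in {path}"
            )
        tab["cq"] = [
            _parse_cq_cell(c, g, s)
            for g, s, c in zip(tab["gene"], tab["sample"], tab["cq"])
        ]
        gene_order = list(dict.fromkeys(tab["gene"]))
        sample_order = list(dict.fromkeys(tab["sample"]))
        values = tab.pivot(index="gene", columns="sample", values="cq")
        values = values.reindex(index=gene_order, columns=sample_order)
        values.index.name = None
        values.columns.name = None

    if missing_policy == "max_cycle":
        values = values.fillna(max_cycles)
    return CqMatrix(values, max_cycles=max_cycles)


def write_cq_table(cq: CqMatrix, path: str | Path, layout: str = "wide") -> None:
    sep = _sep_for(path)
    if layout == "wide":
        out = cq.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep=sep, na_rep="Undetermined")
    elif layout == "long":
        long = cq.values.stack(future_stack=True).reset_index()
        long.columns = ["gene", "sample", "cq"]
        long.to_csv(path, sep=sep, index=False, na_rep="Undetermined")
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def read_intensity_table(path: str | Path) -> IntensityMatrix:
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if raw.empty:
        raise TableFormatError(f"empty intensity table: {path}")
    raw.index = raw.index.astype(str)
    return IntensityMatrix(raw)


def read_annotation(path: str | Path, outcome: str | None = None) -> SampleAnnotation:
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    if outcome is None and "bmd" in raw.columns:
        outcome = "bmd"
    return SampleAnnotation(raw, outcome=outcome)


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    out = ann.frame.copy()
    out.index.name = "sample"
    out.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# result reports

def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_sig(float(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round_floats(obj):
    if isinstance(obj, float):
        return _round_sig(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(result, path: str | Path, format: str | None = None) -> None:
    """Write any result object to TSV (flat table) or JSON (nested).

    ``result`` must expose ``to_frame()`` (for tabular output) and/or
    ``to_dict()`` (for JSON). Column order is deterministic; floats are
    serialized at 6 significant digits.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "tsv":
        if hasattr(result, "to_frame"):
            frame = result.to_frame()
        elif isinstance(result, pd.DataFrame):
            frame = result
        else:
            raise TypeError(f"{type(result).__name__} cannot be written as TSV")
        frame.to_csv(path, sep=_sep_for(path) if path.suffix else "\t",
                     index=False, float_format="%.6g")
    elif format == "json":
        if hasattr(result, "to_dict"):
            obj = result.to_dict()
        elif isinstance(result, pd.DataFrame):
            obj = result.to_dict(orient="records")
        elif isinstance(result, (dict, list)):
            obj = result
        else:
            raise TypeError(f"{type(result).__name__} cannot be written as JSON")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_round_floats(json.loads(json.dumps(obj, default=_json_default))),
                      fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
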