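"""Tabular input/output for every artifact the pipeline touches.

All tables are UTF-8 TSV with a mandatory header row; ``NA`` or an empty cell
means missing.  Gene identity is the symbol string, matched case-sensitively.
Staining/expression categories use the four-level ordinal vocabulary
``Not detected < Low < Medium < High``; patient fractions are stored as
percentages (0-100).

Expression matrices (genes x samples) are a single TSV whose first column is
``gene``; an optional leading ``# unit: <FPKM|TPM|...>`` comment records the
abundance unit, and the first data row, with gene id ``__cohort__``, carries
the per-sample cohort labels.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "LEVEL_LABELS",
    "SchemaError",
    "RowError",
    "ConfigError",
    "ExpressionMatrix",
    "StageRecord",
    "CascadeTrace",
    "NCI60_PANELS",
    "SCHEMAS",
    "read_table",
    "write_table",
    "write_outputs",
]


class SchemaError(ValueError):
    """A table is missing a mandatory column or violates a table-level rule."""


class RowError(ValueError):
    """A single row fails validation; carries the 1-based file row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class ConfigError(ValueError):
    """A configuration value is outside its documented domain."""


LEVEL_LABELS = ("Not detected", "Low", "Medium", "High")


class Level(enum.IntEnum):
    """Ordinal staining/expression category: not detected < low < medium < high."""

    NOT_DETECTED = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @classmethod
    def parse(cls, text: str) -> "Level":
        key = str(text).strip().lower().replace("_", " ")
        try:
            return _LEVEL_BY_NAME[key]
        except KeyError:
            accepted = ", ".join(LEVEL_LABELS)
            raise ValueError(
                f"unknown expression category {text!r}; accepted values: {accepted}"
            ) from None

    @property
    def label(self) -> str:
        return LEVEL_LABELS[int(self)]


_LEVEL_BY_NAME = {
    "not detected": Level.NOT_DETECTED,
    "notdetected": Level.NOT_DETECTED,
    "nd": Level.NOT_DETECTED,
    "low": Level.LOW,
    "medium": Level.MEDIUM,
    "high": Level.HIGH,
}

#: The nine NCI-60 indication panels (configurable everywhere they are used).
NCI60_PANELS = (
    "Leukemia",
    "Non-Small Cell Lung Cancer",
    "Colon Cancer",
    "CNS Cancer",
    "Melanoma",
    "Ovarian Cancer",
    "Renal Cancer",
    "Prostate Cancer",
    "Breast Cancer",
)

EVIDENCE_CRITERIA = ("literature", "antibody", "protein_family", "preclinical", "clinical")

GI50_STATUSES = ("none", "clinical", "fda_approved")

SCHEMAS = (
    "normal_tissue",
    "pathology",
    "gene_annotation",
    "evidence",
    "expression_matrix",
    "mutation",
    "gi50",
)

_MISSING = {"", "NA", "na", "NaN", "nan"}


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with per-sample cohort labels.

    ``values`` is a float DataFrame indexed by gene symbol with sample-id
    columns; ``cohort_of`` maps every sample to its cohort (tumor-type code or
    tissue name); ``unit`` records the abundance unit (FPKM/TPM/AU).
    """

    values: pd.DataFrame
    cohort_of: pd.Series
    unit: str = "TPM"

    def __post_init__(self) -> None:
        self.cohort_of = pd.Series(self.cohort_of)
        missing = [s for s in self.values.columns if s not in self.cohort_of.index]
        if missing:
            raise SchemaError(f"samples without a cohort label: {missing[:5]}")
        self.cohort_of = self.cohort_of.loc[list(self.values.columns)]
        arr = self.values.to_numpy(float)
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise SchemaError("expression values must be non-negative and finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def cohorts(self) -> list[str]:
        return list(dict.fromkeys(self.cohort_of))

    def cohort_samples(self, cohort: str) -> list[str]:
        return list(self.cohort_of.index[self.cohort_of == cohort])

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"# unit: {self.unit}\n")
            fh.write("gene\t" + "\t".join(map(str, self.values.columns)) + "\n")
            fh.write("__cohort__\t" + "\t".join(map(str, self.cohort_of)) + "\n")
            body = self.values.to_csv(
                sep="\t", header=False, float_format="%.6f", lineterminator="\n"
            )
            fh.write(body)

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionMatrix":
        path = Path(path)
        unit = "TPM"
        with path.open("r", encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#"):
                if "unit:" in first:
                    unit = first.split("unit:", 1)[1].strip()
                header_line = fh.readline()
            else:
                header_line = first
            header = header_line.rstrip("\n").split("\t")
            if not header or header[0] != "gene":
                raise SchemaError("expression matrix must start with a 'gene' column")
            cohort_line = fh.readline().rstrip("\n").split("\t")
            if not cohort_line or cohort_line[0] != "__cohort__":
                raise SchemaError("expression matrix is missing the '__cohort__' row")
            if len(cohort_line) != len(header):
                raise SchemaError("cohort row length does not match header")
            df = pd.read_csv(fh, sep="\t", header=None, names=header, index_col=0)
        cohort_of = pd.Series(cohort_line[1:], index=header[1:])
        return cls(values=df.astype(float), cohort_of=cohort_of, unit=unit)


@dataclass
class StageRecord:
    name: str
    n_surviving: int
    dropped: dict[str, str] = field(default_factory=dict)


@dataclass
class CascadeTrace:
    """Ordered per-stage record of surviving item counts and drop reasons.

    Counts are validated to be non-increasing, and every dropped item carries
    exactly one reason, recorded at the stage where it was dropped.
    """

    n_initial: int = 0
    stages: list[StageRecord] = field(default_factory=list)

    def add_stage(self, name: str, survivors, dropped: dict[str, str]) -> list:
        survivors = list(survivors)
        prev = self.stages[-1].n_surviving if self.stages else self.n_initial
        if len(survivors) + len(dropped) != prev:
            raise ValueError(
                f"stage {name!r}: {len(survivors)} survivors + {len(dropped)} dropped "
                f"!= {prev} entering items"
            )
        if len(survivors) > prev:
            raise ValueError(f"stage {name!r}: count increased ({len(survivors)} > {prev})")
        self.stages.append(StageRecord(name, len(survivors), dict(dropped)))
        return survivors

    @property
    def counts(self) -> list[tuple[str, int]]:
        return [(s.name, s.n_surviving) for s in self.stages]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.name for s in self.stages],
                "n_surviving": [s.n_surviving for s in self.stages],
                "n_dropped": [len(s.dropped) for s in self.stages],
            }
        )

    def drop_reasons(self) -> pd.DataFrame:
        rows = [
            {"item": item, "stage": s.name, "reason": reason}
            for s in self.stages
            for item, reason in sorted(s.dropped.items())
        ]
        return pd.DataFrame(rows, columns=["item", "stage", "reason"])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _raw(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return df


def _require(df: pd.DataFrame, columns, schema: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"schema {schema!r}: missing mandatory column {col!r}")


def _cell(value: str) -> str | None:
    value = value.strip()
    return None if value in _MISSING else value


def _parse_float(value: str, row: int, col: str) -> float:
    try:
        x = float(value)
    except ValueError:
        raise RowError(row, f"unparseable numeric value {value!r} in column {col!r}") from None
    if not np.isfinite(x):
        raise RowError(row, f"non-finite value {value!r} in column {col!r}")
    return x


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _parse_bool(value: str | None, row: int, col: str, default: bool | None = None) -> bool:
    if value is None:
        if default is not None:
            return default
        raise RowError(row, f"missing boolean value in column {col!r}")
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise RowError(row, f"unparseable boolean {value!r} in column {col!r}")


def _read_normal_tissue(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, ("gene", "tissue", "cell_type", "level"), "normal_tissue")
    levels = []
    for i, value in enumerate(df["level"]):
        try:
            levels.append(Level.parse(value).label)
        except ValueError as exc:
            raise RowError(i + 2, str(exc)) from None
    out = pd.DataFrame(
        {
            "gene": df["gene"].str.strip(),
            "tissue": df["tissue"].str.strip(),
            "cell_type": df["cell_type"].str.strip(),
            "level": pd.Categorical(levels, categories=LEVEL_LABELS, ordered=True),
        }
    )
    dup = out.duplicated(subset=["gene", "tissue", "cell_type"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise RowError(row, "duplicate (gene, tissue, cell_type) record")
    return out


def _read_pathology(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, ("gene", "cancer_type", "frac_low", "frac_medium", "frac_high"), "pathology")
    has_nd = "frac_not_detected" in df.columns
    rows = []
    for i, rec in df.iterrows():
        row = i + 2
        low = _parse_float(rec["frac_low"], row, "frac_low")
        med = _parse_float(rec["frac_medium"], row, "frac_medium")
        high = _parse_float(rec["frac_high"], row, "frac_high")
        if min(low, med, high) < 0:
            raise RowError(row, "patient fractions must be non-negative")
        if has_nd and _cell(rec["frac_not_detected"]) is not None:
            # counts-per-level dialect: normalize by the total, not-detected included
            nd = _parse_float(rec["frac_not_detected"], row, "frac_not_detected")
            total = nd + low + med + high
            if total <= 0:
                raise RowError(row, "zero patients across all staining levels")
            if abs(total - 100.0) > 1e-6:
                low, med, high = (100.0 * v / total for v in (low, med, high))
        elif low + med + high > 100.0 + 1e-9:
            raise RowError(
                row,
                f"frac_low+frac_medium+frac_high = {low + med + high:g} exceeds 100",
            )
        rows.append(
            {
                "gene": rec["gene"].strip(),
                "cancer_type": rec["cancer_type"].strip(),
                "frac_low": low,
                "frac_medium": med,
                "frac_high": high,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "cancer_type", "frac_low", "frac_medium", "frac_high"])


def _read_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, ("gene", "is_membrane", "has_protein_evidence", "is_surfaceome"), "gene_annotation")
    rows = []
    for i, rec in df.iterrows():
        row = i + 2
        gene = rec["gene"].strip()
        if not gene:
            raise RowError(row, "empty gene symbol")
        entry = {"gene": gene}
        for col in ("is_membrane", "has_protein_evidence", "is_surfaceome"):
            entry[col] = _parse_bool(_cell(rec[col]), row, col)
        for col in EVIDENCE_CRITERIA:
            raw = _cell(rec[col]) if col in df.columns else None
            entry[col] = _parse_bool(raw, row, col, default=False)
        rows.append(entry)
    out = pd.DataFrame(rows)
    dup = out["gene"].duplicated()
    if dup.any():
        raise RowError(int(dup.idxmax()) + 2, f"duplicate gene symbol {out['gene'][dup.idxmax()]!r}")
    return out


def _read_evidence(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, ("gene",) + EVIDENCE_CRITERIA, "evidence")
    rows = []
    for i, rec in df.iterrows():
        row = i + 2
        entry = {"gene": rec["gene"].strip()}
        for col in EVIDENCE_CRITERIA:
            entry[col] = _parse_bool(_cell(rec[col]), row, col)
        rows.append(entry)
    return pd.DataFrame(rows)


def _read_mutation(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, ("sample", "gene"), "mutation")
    out = pd.DataFrame({"sample": df["sample"].str.strip(), "gene": df["gene"].str.strip()})
    return out.drop_duplicates(ignore_index=True)


def _read_gi50(df: pd.DataFrame, panels) -> pd.DataFrame:
    _require(
        df,
        ("nsc_id", "name", "cell_line", "panel", "log_gi50", "failed_screen", "status"),
        "gi50",
    )
    panel_set = set(panels)
    rows = []
    for i, rec in df.iterrows():
        row = i + 2
        try:
            nsc = int(rec["nsc_id"])
        except ValueError:
            raise RowError(row, f"unparseable NSC id {rec['nsc_id']!r}") from None
        panel = rec["panel"].strip()
        if panel not in panel_set:
            raise RowError(
                row,
                f"unknown panel {panel!r}; accepted panels: {', '.join(panels)}",
            )
        status_raw = _cell(rec["status"])
        status = (status_raw or "none").strip().lower()
        if status not in GI50_STATUSES:
            raise RowError(
                row, f"unknown status {status_raw!r}; accepted: {', '.join(GI50_STATUSES)}"
            )
        rows.append(
            {
                "nsc_id": nsc,
                "name": _cell(rec["name"]) or "",
                "cell_line": rec["cell_line"].strip(),
                "panel": panel,
                "log_gi50": _parse_float(rec["log_gi50"], row, "log_gi50"),
                "failed_screen": _parse_bool(_cell(rec["failed_screen"]), row, "failed_screen"),
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["nsc_id", "name", "cell_line", "panel", "log_gi50", "failed_screen", "status"],
    )


def read_table(path: str | Path, schema: str, *, panels=NCI60_PANELS):
    """Read and validate one table; returns a typed DataFrame (or ExpressionMatrix).

    ``schema`` must be one of :data:`SCHEMAS`.  Category strings are
    normalized onto the four-level vocabulary; validation failures raise
    :class:`SchemaError` (table level) or :class:`RowError` (with the 1-based
    file row number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    if schema == "expression_matrix":
        return ExpressionMatrix.read(path)
    df = _raw(path)
    if schema == "normal_tissue":
        return _read_normal_tissue(df)
    if schema == "pathology":
        return _read_pathology(df)
    if schema == "gene_annotation":
        return _read_gene_annotation(df)
    if schema == "evidence":
        return _read_evidence(df)
    if schema == "mutation":
        return _read_mutation(df)
    return _read_gi50(df, panels)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_table(records, path: str | Path, schema: str | None = None) -> Path:
    """Write a record collection as TSV so that ``read_table`` round-trips it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, ExpressionMatrix):
        records.write(path)
        return path
    df = records.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = np.where(df[col], "true", "false")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_outputs(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame] | None = None,
    matrices: dict[str, ExpressionMatrix] | None = None,
    traces: dict[str, CascadeTrace] | None = None,
    manifest_extra: dict | None = None,
) -> dict:
    """Write result tables plus a JSON run manifest; returns the manifest dict.

    Empty collections are written as header-only tables.  The manifest lists
    every file written, row counts, and ordered per-stage trace counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "stage_counts": {}}
    for name, df in (tables or {}).items():
        p = write_table(df, out_dir / f"{name}.tsv")
        manifest["files"][name] = {"path": p.name, "n_rows": int(len(df))}
    for name, mat in (matrices or {}).items():
        p = out_dir / f"{name}.tsv"
        mat.write(p)
        manifest["files"][name] = {
            "path": p.name,
            "n_genes": len(mat.genes),
            "n_samples": len(mat.samples),
        }
    for name, trace in (traces or {}).items():
        manifest["stage_counts"][name] = [
            {"stage": s, "n_surviving": n} for s, n in trace.counts
        ]
        p = write_table(trace.to_frame(), out_dir / f"trace_{name}.tsv")
        manifest["files"][f"trace_{name}"] = {"path": p.name, "n_rows": len(trace.stages)}
        reasons = trace.drop_reasons()
        p = write_table(reasons, out_dir / f"drop_reasons_{name}.tsv")
        manifest["files"][f"drop_reasons_{name}"] = {"path": p.name, "n_rows": int(len(reasons))}
    if manifest_extra:
        manifest.update(manifest_extra)
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
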