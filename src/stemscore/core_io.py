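"""Typed containers and readers/writers for the pipeline's tabular inputs.

All containers wrap pandas objects and enforce their invariants at
construction time, so downstream code can assume clean data:

* :class:`ExpressionMatrix` — genes × samples, finite numeric values,
  unique identifiers.  Only the rank order of values matters downstream
  (the enrichment statistic is rank-based), so no scale interpretation or
  log-transform is applied on read and missing values are rejected.
* :class:`GeneSet` / :class:`GeneSetCollection` — GMT semantics.
* :class:`PhenotypeLabels` — binary phenotype per sample, positive class
  being the stem / tumor group.
* :class:`SurvivalTable` — time (>0), event (0/1), optional numeric
  covariates.
* :class:`ClinicalTable` — categorical clinicopathological columns; any
  column handed to the 2×2 association machinery must have two levels.

Gene and sample identifiers are matched case-sensitively after whitespace
stripping; alias/ortholog mapping is dataset policy, not method, and is
deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "PhenotypeLabels",
    "SurvivalTable",
    "ClinicalTable",
    "TableReadReport",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_table",
    "read_phenotype_labels",
    "write_phenotype_labels",
    "write_survival_table",
    "write_clinical_table",
]


class ParseError(ValueError):
    """A malformed input file that cannot be interpreted."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples numeric matrix (any monotone expression scale)."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "gene")
        _check_unique(list(df.columns), "sample")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free, nonempty collection of gene identifiers."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        _check_unique(self.members, f"member (set {self.name!r})")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene-set")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        wanted = list(names)
        missing = [n for n in wanted if n not in set(self.names)]
        if missing:
            raise KeyError(f"unknown gene sets: {missing}")
        return GeneSetCollection(tuple(s for s in self.sets if s.name in set(wanted)))


@dataclass(frozen=True)
class PhenotypeLabels:
    """Binary phenotype per sample; 1 = positive class (stem / tumor)."""

    labels: pd.Series  # index = sample ids, values in {0, 1}
    positive_name: str = "stem"
    negative_name: str = "somatic"

    def __post_init__(self) -> None:
        _check_unique(list(self.labels.index), "sample")
        vals = set(pd.unique(self.labels))
        if not vals <= {0, 1}:
            raise ValidationError(f"labels must be 0/1, got {sorted(vals)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def values_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels.index]
        if missing:
            raise ValidationError(f"samples without labels: {missing[:5]}")
        return self.labels.loc[list(sample_ids)].to_numpy(dtype=int)


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample follow-up time (>0), event flag (1=event, 0=censored)."""

    data: pd.DataFrame  # index = sample ids; columns: time, event, covariates…

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), "sample")
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValidationError(f"survival table missing {col!r} column")
        if not (df["time"].to_numpy() > 0).all():
            raise ValidationError("survival times must be strictly positive")
        if not set(pd.unique(df["event"])) <= {0, 1}:
            raise ValidationError("event flags must be 0 or 1")
        cov = df.drop(columns=["time", "event"])
        if len(cov.columns) and not np.all(np.isfinite(cov.to_numpy(dtype=float))):
            raise ValidationError("covariate columns must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]


@dataclass(frozen=True)
class ClinicalTable:
    """Categorical clinicopathological parameters per sample."""

    data: pd.DataFrame  # index = sample ids; columns categorical

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def binary_column(self, name: str) -> pd.Series:
        """Return a column, checking it has exactly two observed levels."""
        col = self.data[name].dropna()
        levels = sorted(map(str, pd.unique(col)))
        if len(levels) != 2:
            raise ValidationError(
                f"column {name!r} must have exactly two levels, got {levels}"
            )
        return col.astype(str)


@dataclass
class TableReadReport:
    """Accounting of rows dropped while reading a typed table."""

    n_read: int = 0
    n_rejected: int = 0
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, ``name<TAB>description<TAB>genes…``.

    Duplicate member symbols within a line are removed (first occurrence
    kept) with a logged warning; duplicate set names are an error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            members: list[str] = []
            seen: set[str] = set()
            dupes = 0
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dupes += 1
                    continue
                seen.add(g)
                members.append(g)
            if dupes:
                logger.warning(
                    "%s: line %d: set %r had %d duplicate member(s), deduplicated",
                    path, lineno, name, dupes,
                )
            if not members:
                raise ParseError(f"{path}: line {lineno}: set {name!r} has no members")
            sets.append(GeneSet(name=name, description=desc, members=tuple(members)))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices (plain TSV and GCT 1.2)
# ---------------------------------------------------------------------------

def _frame_from_records(
    path: str | Path, header: list[str], rows: list[list[str]], n_meta: int
) -> pd.DataFrame:
    sample_ids = [h.strip() for h in header[n_meta:]]
    gene_ids, data = [], []
    for i, fields in enumerate(rows, start=1):
        if len(fields) != n_meta + len(sample_ids):
            raise ParseError(
                f"{path}: data row {i}: expected {n_meta + len(sample_ids)} "
                f"fields, got {len(fields)}"
            )
        gene_ids.append(fields[0].strip())
        vals = []
        for j, cell in enumerate(fields[n_meta:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at gene "
                    f"{fields[0].strip()!r}, sample {sample_ids[j]!r}"
                ) from None
        data.append(vals)
    return pd.DataFrame(data, index=gene_ids, columns=sample_ids, dtype=float)


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix; ``dialect`` is ``"tsv"`` or ``"gct"`` (1.2).

    TSV: header row of sample ids, first column gene ids.  GCT: the two-line
    ``#1.2`` preamble with declared dimensions, then ``Name``/``Description``
    meta columns; declared and parsed dimensions must agree.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if dialect == "tsv":
        if not lines:
            raise ParseError(f"{path}: empty expression file")
        header = lines[0].split("\t")
        df = _frame_from_records(path, header, [ln.split("\t") for ln in lines[1:]], 1)
    elif dialect == "gct":
        if len(lines) < 3:
            raise ParseError(f"{path}: GCT file needs >=3 lines")
        if not lines[0].startswith("#1.2"):
            raise ParseError(f"{path}: missing '#1.2' GCT version line")
        try:
            n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
        except ValueError:
            raise ParseError(f"{path}: malformed GCT dimension line") from None
        header = lines[2].split("\t")
        df = _frame_from_records(path, header, [ln.split("\t") for ln in lines[3:]], 2)
        if df.shape != (n_genes, n_samples):
            raise ParseError(
                f"{path}: GCT declares {n_genes}x{n_samples} but body is "
                f"{df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ExpressionMatrix(df)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    df = matrix.data
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(["gene_id", *df.columns]) + "\n")
        elif dialect == "gct":
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            fh.write("\t".join(["Name", "Description", *df.columns]) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        for gene, row in df.iterrows():
            cells = [repr(float(v)) for v in row.to_numpy()]
            if dialect == "gct":
                fh.write("\t".join([gene, "na", *cells]) + "\n")
            else:
                fh.write("\t".join([gene, *cells]) + "\n")


# ---------------------------------------------------------------------------
# Survival / clinical / phenotype tables (TSV with header)
# ---------------------------------------------------------------------------

def read_table(
    path: str | Path, schema: str, strict: bool = False
) -> tuple[SurvivalTable | ClinicalTable, TableReadReport]:
    """Read a typed TSV table (``schema`` = ``"survival"`` or ``"clinical"``).

    Rows violating the schema (missing mandatory fields, time <= 0, event
    outside {0,1}) are dropped and counted in the returned report; with
    ``strict=True`` the first violation raises :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    report = TableReadReport(n_read=len(df))

    def reject(idx, reason: str) -> None:
        if strict:
            raise ValidationError(f"{path}: row {idx + 2}: {reason}")
        report.n_rejected += 1
        report.reasons.append(f"row {idx + 2}: {reason}")

    if schema == "survival":
        for col in ("time", "event"):
            if col not in df.columns:
                raise ParseError(f"{path}: survival table missing {col!r} column")
        keep_rows = []
        for idx, row in df.iterrows():
            if row.isna().any():
                reject(idx, "missing mandatory field")
                continue
            try:
                t = float(row["time"])
                e = float(row["event"])
            except ValueError:
                reject(idx, "non-numeric time/event")
                continue
            if t <= 0:
                reject(idx, f"time {t} <= 0")
                continue
            if e not in (0.0, 1.0):
                reject(idx, f"event {e} not in {{0,1}}")
                continue
            keep_rows.append(idx)
        kept = df.loc[keep_rows].set_index("sample_id")
        out = kept.astype(float)
        out["event"] = out["event"].astype(int)
        table: SurvivalTable | ClinicalTable = SurvivalTable(out)
    elif schema == "clinical":
        keep_rows = []
        for idx, row in df.iterrows():
            if row.isna().any():
                reject(idx, "missing field")
                continue
            keep_rows.append(idx)
        table = ClinicalTable(df.loc[keep_rows].set_index("sample_id"))
    else:
        raise ValueError(f"unknown schema {schema!r}")
    if report.n_rejected:
        logger.warning("%s: rejected %d row(s)", path, report.n_rejected)
    return table, report


def read_phenotype_labels(
    path: str | Path, positive_name: str = "stem", negative_name: str = "somatic"
) -> PhenotypeLabels:
    """Read sample_id/label TSV; labels may be 0/1 or the class names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ParseError(f"{path}: expected columns sample_id, label")
    mapping = {"0": 0, "1": 1, negative_name: 0, positive_name: 1}
    try:
        values = [mapping[v.strip()] for v in df["label"]]
    except KeyError as exc:
        raise ParseError(f"{path}: unknown label {exc.args[0]!r}") from None
    series = pd.Series(values, index=[s.strip() for s in df["sample_id"]], dtype=int)
    return PhenotypeLabels(series, positive_name=positive_name,
                           negative_name=negative_name)


def write_phenotype_labels(labels: PhenotypeLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, v in labels.labels.items():
            fh.write(f"{sid}\t{int(v)}\n")


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    df = table.data.reset_index(names="sample_id")
    df.to_csv(path, sep="\t", index=False)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    df = table.data.reset_index(names="sample_id")
    df.to_csv(path, sep="\t", index=False)
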