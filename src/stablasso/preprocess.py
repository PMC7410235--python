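"""Cohort preprocessing: limit-of-detection policy, complete cases, design matrix.

A raw cohort table holds one row per subject (here: one mouse pup) and one
column per variable — parental covariates, pup phenotypes, and serum cytokine
concentrations measured by a multiplex immunoassay.  Cytokine measurements are
left-censored at an analyte-specific lower limit of detection (LLOD).  This
module turns such a table into the standardized numeric design matrix used by
the penalized regression:

1. analytes censored in more than a configurable fraction of samples are
   excluded outright; remaining below-LLOD cells are imputed at LLOD/2;
2. subjects with any missing value are dropped (complete-case analysis);
3. numeric variables are mean-centered and scaled to unit variance, binary
   variables are encoded 0/1, and the binary outcome is coded 1 for the
   exposed (MIA) class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel written to TSV for a below-LLOD cell
LLOD_SENTINEL = "<LLOD"

ROLES = ("parental", "pup", "cytokine", "outcome")
KINDS = ("numeric", "binary")

#: label → 0/1 encodings for binary variables
BINARY_CODING = {"No": 0, "Yes": 1, "Control": 0, "MIA": 1}


class MetadataError(ValueError):
    """A variable's metadata is inconsistent with its role."""


class EmptyDataError(ValueError):
    """No subjects survive a filtering step."""


class DegenerateColumnError(ValueError):
    """A predictor is constant and cannot be standardized."""


class ClassError(ValueError):
    """The outcome does not contain both classes."""


@dataclass
class VariableSpec:
    """Metadata for one cohort variable.

    ``llod`` is the assay's lower limit of detection and must be present
    (positive) exactly when ``role == "cytokine"``.
    """

    name: str
    role: str
    stage: str = ""
    kind: str = "numeric"
    units: str = ""
    llod: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise MetadataError(f"unknown role {self.role!r} for {self.name}")
        if self.kind not in KINDS:
            raise MetadataError(f"unknown kind {self.kind!r} for {self.name}")
        if self.role == "cytokine":
            if self.llod is None or not self.llod > 0:
                raise MetadataError(
                    f"cytokine {self.name!r} requires a positive LLOD, got {self.llod}"
                )
        elif self.llod is not None:
            raise MetadataError(f"non-cytokine {self.name!r} must not carry an LLOD")


@dataclass
class CohortTable:
    """Raw subjects × variables table with censoring mask and metadata.

    ``data`` is indexed by subject id; predictor columns are float (NaN =
    missing), the single outcome column holds class labels (e.g.
    "Control"/"MIA").  ``censored`` is a same-shaped boolean frame; True marks
    a below-LLOD cell (whose ``data`` value is NaN until imputation).
    """

    data: pd.DataFrame
    censored: pd.DataFrame
    meta: dict[str, VariableSpec]
    outcome: str

    def __post_init__(self) -> None:
        outcomes = [n for n, s in self.meta.items() if s.role == "outcome"]
        if len(outcomes) != 1 or outcomes[0] != self.outcome:
            raise MetadataError(f"exactly one outcome variable required, got {outcomes}")
        if self.data.index.has_duplicates:
            raise MetadataError("subject ids must be unique")
        missing_meta = set(self.data.columns) - set(self.meta)
        if missing_meta:
            raise MetadataError(f"variables without metadata: {sorted(missing_meta)}")

    @property
    def cytokines(self) -> list[str]:
        return [n for n in self.data.columns if self.meta[n].role == "cytokine"]

    @property
    def predictors(self) -> list[str]:
        return [n for n in self.data.columns if n != self.outcome]

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.data.copy(), self.censored.copy(), dict(self.meta), self.outcome
        )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, data_path: str | Path, meta_path: str | Path) -> None:
        """Write the table and its metadata sidecar as TSV."""
        out = self.data.astype(object).copy()
        for col in self.data.columns:
            mask = self.censored[col]
            if mask.any():
                out.loc[mask, col] = LLOD_SENTINEL
        out.to_csv(data_path, sep="\t", index_label="subject_id", na_rep="")
        rows = [
            {
                "name": s.name,
                "role": s.role,
                "stage": s.stage,
                "kind": s.kind,
                "units": s.units,
                "llod": "" if s.llod is None else s.llod,
            }
            for s in self.meta.values()
        ]
        pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, data_path: str | Path, meta_path: str | Path) -> "CohortTable":
        meta_df = pd.read_csv(meta_path, sep="\t", dtype={"stage": str, "units": str})
        meta: dict[str, VariableSpec] = {}
        outcome = None
        for _, r in meta_df.iterrows():
            llod = r.get("llod")
            llod = None if pd.isna(llod) or llod == "" else float(llod)
            spec = VariableSpec(
                name=str(r["name"]),
                role=str(r["role"]),
                stage="" if pd.isna(r.get("stage")) else str(r.get("stage")),
                kind=str(r.get("kind", "numeric")),
                units="" if pd.isna(r.get("units")) else str(r.get("units")),
                llod=llod,
            )
            meta[spec.name] = spec
            if spec.role == "outcome":
                outcome = spec.name
        raw = pd.read_csv(
            data_path, sep="\t", index_col="subject_id", dtype=str, keep_default_na=False
        )
        data = pd.DataFrame(index=raw.index)
        censored = pd.DataFrame(False, index=raw.index, columns=raw.columns)
        for col in raw.columns:
            s = raw[col]
            cmask = s == LLOD_SENTINEL
            censored[col] = cmask
            if col == outcome:
                data[col] = s.replace("", np.nan)
            else:
                vals = s.where(~cmask, other="").replace("", np.nan)
                if meta.get(col) is not None and meta[col].kind == "binary":
                    # may hold labels like Yes/No; leave as-is if non-numeric
                    try:
                        data[col] = pd.to_numeric(vals)
                    except (ValueError, TypeError):
                        data[col] = vals
                else:
                    data[col] = pd.to_numeric(vals)
        return cls(data, censored, meta, outcome)


@dataclass
class DesignMatrix:
    """Standardized predictor matrix and 0/1 outcome, ready for the solver.

    ``scaling`` keeps each column's (mean, scale); binary columns have scaling
    (0, 1) so un-standardization is the identity for them.
    """

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    scaling: dict[str, tuple[float, float]]
    binary_columns: list[str] = field(default_factory=list)
    outcome_name: str = "outcome"
    outcome_coding: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def unstandardize(self) -> np.ndarray:
        """Map X back to the post-imputation value scale."""
        out = self.X.copy()
        for j, name in enumerate(self.column_names):
            m, s = self.scaling[name]
            out[:, j] = out[:, j] * s + m
        return out

    def to_tsv(self, x_path: str | Path, scaling_path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df[self.outcome_name] = self.y
        df.to_csv(x_path, sep="\t", index=False)
        rows = [
            {"name": n, "mean": self.scaling[n][0], "scale": self.scaling[n][1],
             "binary": n in self.binary_columns}
            for n in self.column_names
        ]
        pd.DataFrame(rows).to_csv(scaling_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations


def apply_llod_policy(
    table: CohortTable, exclusion_fraction: float = 0.20
) -> tuple[CohortTable, list[str]]:
    """Exclude heavily censored analytes; impute the rest at half the LLOD.

    The censored fraction is computed per analyte over all assayed samples
    (censored cells count as assayed, truly missing cells do not) *before*
    any complete-case filtering.  Analytes whose fraction strictly exceeds
    ``exclusion_fraction`` are dropped; for retained analytes every
    below-LLOD cell is set to LLOD/2 and unmasked.
    """
    table = table.copy()
    excluded: list[str] = []
    for name in table.cytokines:
        spec = table.meta[name]
        if spec.llod is None:  # defensive; VariableSpec enforces this
            raise MetadataError(f"cytokine {name!r} has no LLOD")
        cmask = table.censored[name]
        assayed = cmask | table.data[name].notna()
        n_assayed = int(assayed.sum())
        frac = cmask.sum() / n_assayed if n_assayed else 0.0
        if frac > exclusion_fraction:
            excluded.append(name)
        elif cmask.any():
            table.data.loc[cmask, name] = spec.llod / 2.0
            table.censored[name] = False
    if excluded:
        logger.info("LLOD policy excluded %d analyte(s): %s", len(excluded), excluded)
        table.data = table.data.drop(columns=excluded)
        table.censored = table.censored.drop(columns=excluded)
        for name in excluded:
            del table.meta[name]
    return table, excluded


def complete_cases(table: CohortTable) -> CohortTable:
    """Keep exactly the subjects with no missing value in any retained variable."""
    predictors = table.predictors
    keep = table.data[predictors].notna().all(axis=1) & table.data[table.outcome].notna()
    dropped = table.data.index[~keep].tolist()
    if dropped:
        logger.info("complete-case filter dropped %d subject(s): %s", len(dropped), dropped)
    if not keep.any():
        raise EmptyDataError("no subject has complete data")
    return CohortTable(
        table.data.loc[keep].copy(),
        table.censored.loc[keep].copy(),
        dict(table.meta),
        table.outcome,
    )


def build_design(
    table: CohortTable, ddof: int = 0, standardize: bool = True
) -> DesignMatrix:
    """Standardize numeric predictors and encode binaries, producing X and y.

    ``ddof=0`` (population variance, divisor n) matches the convention of the
    usual penalized-regression software; set ``ddof=1`` for the sample-variance
    convention.  Binary predictors are encoded 0/1 and never standardized.
    """
    predictors = table.predictors
    if table.data[predictors].isna().any().any():
        raise EmptyDataError("design requires complete cases; run complete_cases first")

    y_raw = table.data[table.outcome]
    coding = _encode_binary(y_raw, table.outcome)
    y = y_raw.map(coding).to_numpy(dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ClassError(f"outcome {table.outcome!r} has a single class")

    cols: list[np.ndarray] = []
    scaling: dict[str, tuple[float, float]] = {}
    binary_columns: list[str] = []
    for name in predictors:
        v = table.data[name]
        if table.meta[name].kind == "binary":
            enc = _encode_binary(v, name)
            x = v.map(enc).to_numpy(dtype=np.float64) if v.dtype == object else v.to_numpy(np.float64)
            if not np.isin(x, (0.0, 1.0)).all():
                raise MetadataError(f"binary variable {name!r} has non-0/1 values")
            scaling[name] = (0.0, 1.0)
            binary_columns.append(name)
        else:
            x = v.to_numpy(dtype=np.float64)
            m = float(x.mean())
            s = float(x.std(ddof=ddof))
            if s == 0.0:
                raise DegenerateColumnError(f"column {name!r} is constant")
            if standardize:
                x = (x - m) / s
                scaling[name] = (m, s)
            else:
                scaling[name] = (0.0, 1.0)
        cols.append(x)
    X = np.column_stack(cols) if cols else np.empty((len(y), 0))
    return DesignMatrix(
        X=X,
        y=y.astype(np.float64),
        column_names=list(predictors),
        scaling=scaling,
        binary_columns=binary_columns,
        outcome_name=table.outcome,
        outcome_coding=coding,
    )


def subset_variables(table: CohortTable, names: Iterable[str]) -> CohortTable:
    """Restrict a cohort table to the given predictors (outcome always kept)."""
    keep = [n for n in names if n != table.outcome] + [table.outcome]
    unknown = set(keep) - set(table.data.columns)
    if unknown:
        raise KeyError(f"unknown variables: {sorted(unknown)}")
    return CohortTable(
        table.data[keep].copy(),
        table.censored[keep].copy(),
        {n: table.meta[n] for n in keep},
        table.outcome,
    )


def _encode_binary(values: pd.Series, name: str) -> dict:
    """Return label → {0,1} mapping for a binary column (MIA→1, Yes→1)."""
    if values.dtype != object:
        return {0: 0, 1: 1}
    levels = sorted(values.dropna().unique().tolist())
    known = {lv: BINARY_CODING[lv] for lv in levels if lv in BINARY_CODING}
    if len(known) == len(levels) and len(set(known.values())) == len(levels):
        return known
    if len(levels) > 2:
        raise MetadataError(f"binary variable {name!r} has {len(levels)} levels: {levels}")
    # fall back to lexicographic: first level → 0
    return {lv: i for i, lv in enumerate(levels)}


def read_subject_spreadsheet(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    outcome: str = "Group",
    llods: dict[str, float] | None = None,
    cytokine_columns: Iterable[str] | None = None,
) -> CohortTable:
    """Import a cohort from a spreadsheet laid out like a supplementary table.

    The sheet is expected to carry one row per subject, a group/outcome column,
    and numeric variable columns; ``column_map`` renames spreadsheet headers to
    canonical names, ``llods`` supplies per-cytokine detection limits (required
    for columns listed in ``cytokine_columns``).  Cells equal to the sentinel
    ``"<LLOD"`` are read as below-LLOD.
    """
    raw = pd.read_excel(path, dtype=object)
    if column_map:
        raw = raw.rename(columns=column_map)
    if outcome not in raw.columns:
        raise MetadataError(f"outcome column {outcome!r} not found in spreadsheet")
    raw.index = pd.Index([f"s{i+1:03d}" for i in range(len(raw))], name="subject_id")
    cytokine_columns = set(cytokine_columns or [])
    llods = llods or {}
    meta: dict[str, VariableSpec] = {}
    data = pd.DataFrame(index=raw.index)
    censored = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        s = raw[col]
        if col == outcome:
            meta[col] = VariableSpec(col, "outcome", kind="binary")
            data[col] = s.astype(str)
            continue
        cmask = s.astype(str) == LLOD_SENTINEL
        censored[col] = cmask
        vals = pd.to_numeric(s.where(~cmask), errors="coerce")
        data[col] = vals
        if col in cytokine_columns:
            if col not in llods:
                raise MetadataError(f"cytokine column {col!r} needs an LLOD")
            meta[col] = VariableSpec(col, "cytokine", units="pg/ml", llod=llods[col])
        else:
            kind = "binary" if set(vals.dropna().unique()) <= {0.0, 1.0} else "numeric"
            meta[col] = VariableSpec(col, "pup", kind=kind)
    return CohortTable(data, censored, meta, outcome)
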