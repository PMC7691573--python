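"""Per-patient trial tables: the single input currency of every analysis stage.

A trial table holds one row per patient with a binary outcome ``Y`` (1 =
success, e.g. sinus rhythm at one year), a binary mediator ``M`` (1 =
co-intervention received, e.g. left atrial appendage removed), a binary
treatment arm ``T``, a surgeon/cluster label, and baseline covariates.
Tables are complete-case by contract: rows with missing values are rejected
at read time rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

RESERVED = ("Y", "M", "T", "cluster")


class SchemaError(ValueError):
    """A column required by the schema is missing or mis-declared."""


class TrialValidationError(ValueError):
    """Row-level contract violation (non-binary code, missing value, ...)."""


class PatientRecord(NamedTuple):
    Y: int
    M: int
    T: int
    covariates: dict
    cluster: str


@dataclass(frozen=True)
class TrialTable:
    """Validated per-patient records.

    ``df`` holds columns Y, M, T, cluster plus one column per (dummy-expanded)
    covariate; ``covariates`` maps covariate name to ``"continuous"`` or
    ``"binary"``. Cluster labels are opaque strings, never assumed numeric.
    """

    df: pd.DataFrame
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate(self.df, self.covariates)

    # -- convenience views ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def arm_sizes(self) -> dict:
        t = self.df["T"].to_numpy()
        return {0: int((t == 0).sum()), 1: int((t == 1).sum())}

    @property
    def clusters(self) -> list:
        return sorted(self.df["cluster"].unique())

    @property
    def cluster_index(self) -> dict:
        """Cluster label -> integer row positions (original order kept)."""
        groups = self.df.groupby("cluster", sort=True).indices
        return {str(k): np.asarray(v) for k, v in groups.items()}

    def records(self) -> Iterator[PatientRecord]:
        cov_names = list(self.covariates)
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield PatientRecord(
                Y=int(d["Y"]),
                M=int(d["M"]),
                T=int(d["T"]),
                covariates={c: d[c] for c in cov_names},
                cluster=str(d["cluster"]),
            )

    def __eq__(self, other: object) -> bool:  # field-by-field, used in round-trips
        if not isinstance(other, TrialTable):
            return NotImplemented
        if self.covariates != other.covariates:
            return False
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if c == "cluster":
                if not (a[c].astype(str).to_numpy() == b[c].astype(str).to_numpy()).all():
                    return False
            elif not np.allclose(a[c].to_numpy(float), b[c].to_numpy(float), atol=0, rtol=0):
                return False
        return True


def _validate(df: pd.DataFrame, covariates: dict) -> None:
    for col in RESERVED:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing")
    for name, kind in covariates.items():
        if name in RESERVED:
            raise SchemaError(f"covariate name {name!r} collides with a reserved column")
        if name not in df.columns:
            raise SchemaError(f"covariate column {name!r} missing")
        if kind not in ("continuous", "binary"):
            raise SchemaError(f"covariate {name!r}: unknown type {kind!r}")
    if len(set(covariates)) != len(covariates):
        raise SchemaError("covariate names must be unique")

    check_cols = list(RESERVED) + list(covariates)
    na = df[check_cols].isna()
    if na.to_numpy().any():
        col = na.any()[na.any()].index[0]
        row = int(na[col][na[col]].index[0])
        raise TrialValidationError(
            f"missing value in column {col!r} at row {row}: complete cases required"
        )
    for col in ("Y", "M", "T"):
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise TrialValidationError(
                f"column {col!r} must be coded 0/1; found {vals[bad][0]!r} at row {row}"
            )
    for name, kind in covariates.items():
        if kind == "binary":
            vals = df[name].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise TrialValidationError(f"binary covariate {name!r} not coded 0/1")
    labels = df["cluster"].astype(str)
    if (labels.str.len() == 0).any():
        raise TrialValidationError("empty cluster label")
    if labels.nunique() < 2:
        raise TrialValidationError("at least 2 clusters required")
    t = df["T"].to_numpy()
    if (t == 0).sum() == 0 or (t == 1).sum() == 0:
        raise TrialValidationError("both trial arms must be non-empty")


def expand_categorical(df: pd.DataFrame, name: str, reference=None) -> tuple[pd.DataFrame, list]:
    """Dummy-code a categorical column, dropping the reference level.

    Dummies are named ``<name>_<level>``; the reference level defaults to the
    first level in sorted order so the coding is deterministic.
    """
    levels = sorted(df[name].astype(str).unique())
    if reference is None:
        reference = levels[0]
    elif str(reference) not in levels:
        raise SchemaError(f"reference level {reference!r} not found in {name!r}")
    out = df.copy()
    new_cols = []
    for lev in levels:
        if lev == str(reference):
            continue
        col = f"{name}_{lev}"
        out[col] = (df[name].astype(str) == lev).astype(int)
        new_cols.append(col)
    out = out.drop(columns=[name])
    return out, new_cols


def read_trial_table(path, schema: dict | None = None) -> TrialTable:
    """Read a comma-delimited trial table with header Y,M,T,cluster,<covariates>.

    ``schema`` maps covariate names to ``"continuous"``, ``"binary"`` or
    ``("categorical", reference_level)`` / ``"categorical"``; categorical
    covariates are expanded to reference-coded dummies. Covariate columns in
    the file but absent from the schema are an error, as are schema entries
    absent from the file.
    """
    df = pd.read_csv(path, dtype={"cluster": str}, float_precision="round_trip")
    for col in RESERVED:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    file_covs = [c for c in df.columns if c not in RESERVED]
    if schema is None:
        schema = {c: "continuous" for c in file_covs}
        for c in file_covs:
            if np.isin(df[c].dropna().unique(), (0, 1)).all():
                schema[c] = "binary"
    if set(schema) != set(file_covs):
        raise SchemaError(
            f"schema covariates {sorted(schema)} do not match file covariates {sorted(file_covs)}"
        )
    covariates: dict = {}
    for name in file_covs:
        kind = schema[name]
        reference = None
        if isinstance(kind, tuple):
            kind, reference = kind
        if kind == "categorical":
            df, new_cols = expand_categorical(df, name, reference)
            covariates.update({c: "binary" for c in new_cols})
        else:
            covariates[name] = kind
    ordered = list(RESERVED) + [c for c in df.columns if c not in RESERVED]
    df = df[ordered].reset_index(drop=True)
    for col in ("Y", "M", "T"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return TrialTable(df=df, covariates=covariates)


def write_trial_table(table: TrialTable, path) -> None:
    """Write a table as UTF-8 CSV re-readable by :func:`read_trial_table`."""
    df = table.df.copy()
    for col in ("Y", "M", "T"):
        df[col] = df[col].astype(int)
    for name, kind in table.covariates.items():
        if kind == "binary":
            df[name] = df[name].astype(int)
    # repr round-trips doubles exactly; default formatting can drop an ulp
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def summarize_arms(table: TrialTable) -> dict:
    """Counts and proportions of success and mediator uptake per arm and cluster.

    Proportions are exact count ratios; rounding happens only at display.
    """
    df = table.df
    arms = {}
    for t in (0, 1):
        sub = df[df["T"] == t]
        n = len(sub)
        y1 = int(sub["Y"].sum())
        m1 = int(sub["M"].sum())
        arms[t] = {
            "n": n,
            "y_count": y1,
            "y_prop": y1 / n,
            "m_count": m1,
            "m_prop": m1 / n,
        }
    clusters = {}
    for lab, idx in table.cluster_index.items():
        sub = df.iloc[idx]
        clusters[lab] = {"n": len(sub), "m_prop": float(sub["M"].mean())}
    return {"arms": arms, "clusters": clusters}


def format_summary(summary: dict) -> str:
    lines = ["arm   n    Y=1 (prop)    M=1 (prop)"]
    for t in (0, 1):
        a = summary["arms"][t]
        lines.append(
            f"{t:>3} {a['n']:>4}  {a['y_count']:>4} ({a['y_prop']:.3f})  "
            f"{a['m_count']:>4} ({a['m_prop']:.3f})"
        )
    lines.append("cluster   n   M-uptake")
    for lab, c in summary["clusters"].items():
        lines.append(f"{lab:>7} {c['n']:>4}   {c['m_prop']:.3f}")
    return "\n".join(lines)
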