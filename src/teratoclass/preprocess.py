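"""Expression-matrix I/O and batch-wise control centering.

The screen design is a set of hybridization batches, each carrying its own
vehicle-control samples.  Batch effects are removed by subtracting, per probe
set, the mean of the control samples of the batch (optionally restricted to
controls with a matching vehicle, e.g. a 0.5% DMSO control group for
compounds dosed in 0.5% DMSO).  Downstream analyses operate either on the
raw matrix (per-condition differential expression against matched controls)
or on the centered matrix of treated samples (variance-based classifier).

In-memory containers are plain pandas objects:

* expression matrix — ``DataFrame`` of log2 intensities, probe sets as the
  index, sample ids as columns;
* sample sheet — ``DataFrame`` with one row per sample, columns
  ``sample_id, compound_id, tier, batch, role, vehicle, replicate, excluded``.

Missing values are not supported anywhere: upstream summarization produces a
complete matrix, and any NaN is treated as a parse/validation error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_SHEET_COLUMNS",
    "NoExpressionDataError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
    "center_by_batch_controls",
    "split_condition",
]

#: sample-sheet columns that must be present (``vehicle`` and ``excluded``
#: are optional and default to a single vehicle / no exclusions)
REQUIRED_SHEET_COLUMNS = ("sample_id", "compound_id", "tier", "batch", "role")

CONTROL_ROLE = "control"
TREATED_ROLE = "treated"


class NoExpressionDataError(ValueError):
    """Raised when a condition carries no expression data (e.g. cytotoxic)."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe-set × sample matrix from TSV/CSV.

    The first column holds probe-set identifiers; the header row holds sample
    identifiers.  Duplicate identifiers, non-numeric cells and missing values
    are rejected with an error naming the offending row or column.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id in {path!s}: {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id in {path!s}: {dup!r}")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[bad.isna().to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric value in {path!s} at probe {row!r}, sample {col!r}"
                ) from None
        raise
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError(f"non-finite values in {path!s}")
    values.index.name = "probe_id"
    return values


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=_sniff_sep(path))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "batch": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Normalize a sample sheet and check its invariants.

    Adds defaulted ``vehicle``/``excluded``/``replicate`` columns when absent
    and verifies that every batch containing treated samples also contains at
    least one (vehicle-matched) control.
    """
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    if "vehicle" not in sheet.columns:
        sheet["vehicle"] = "vehicle"
    if "replicate" not in sheet.columns:
        sheet["replicate"] = 0
    if "excluded" not in sheet.columns:
        sheet["excluded"] = False
    sheet["excluded"] = sheet["excluded"].astype(bool)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in sheet: {dup!r}")
    bad_roles = set(sheet["role"]) - {CONTROL_ROLE, TREATED_ROLE}
    if bad_roles:
        raise ValueError(f"unknown roles in sample sheet: {sorted(bad_roles)}")
    active = sheet[~sheet["excluded"]]
    for (batch, vehicle), grp in active.groupby(["batch", "vehicle"]):
        if (grp["role"] == TREATED_ROLE).any() and not (grp["role"] == CONTROL_ROLE).any():
            raise ValueError(
                f"batch {batch!r} has treated samples with vehicle {vehicle!r} "
                "but no matching control samples"
            )
    return sheet


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def _active(sheet: pd.DataFrame) -> pd.DataFrame:
    return sheet[~sheet["excluded"]]


def center_by_batch_controls(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Subtract the batch-wise (vehicle-matched) control mean per probe set.

    Returns the centered matrix restricted to treated samples; control
    columns are dropped.  Excluded samples are ignored entirely.
    """
    sheet = validate_sample_sheet(sheet)
    active = _active(sheet)
    known = set(matrix.columns)
    missing = [s for s in active["sample_id"] if s not in known]
    if missing:
        raise ValueError(f"sheet samples absent from matrix: {missing[:5]}")

    out: dict[str, pd.Series] = {}
    for (batch, vehicle), grp in active.groupby(["batch", "vehicle"]):
        treated_ids = grp.loc[grp["role"] == TREATED_ROLE, "sample_id"].tolist()
        if not treated_ids:
            continue
        control_ids = grp.loc[grp["role"] == CONTROL_ROLE, "sample_id"].tolist()
        if not control_ids:
            raise ValueError(
                f"batch {batch!r} (vehicle {vehicle!r}) has no control samples"
            )
        ctrl_mean = matrix[control_ids].mean(axis=1)
        for sid in treated_ids:
            out[sid] = matrix[sid] - ctrl_mean
    # preserve the matrix column order
    ordered = [s for s in matrix.columns if s in out]
    centered = pd.DataFrame({s: out[s] for s in ordered}, index=matrix.index)
    centered.index.name = "probe_id"
    return centered


def split_condition(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    compound: str,
    tier: str,
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (treated columns, matched control columns) for one condition.

    Controls are pooled from every batch that contains treated replicates of
    the condition, restricted to the vehicle the condition was dosed in.
    A cytotoxic or absent condition raises :class:`NoExpressionDataError`
    (cytotoxic exposures yield no usable RNA, hence no samples).
    """
    sheet = validate_sample_sheet(sheet)
    active = _active(sheet)
    mask = (
        (active["compound_id"] == compound)
        & (active["tier"] == tier)
        & (active["role"] == TREATED_ROLE)
    )
    treated = active[mask]
    if treated.empty:
        detail = "absent from the sample sheet"
        if annotations is not None:
            hit = annotations[
                (annotations["compound_id"] == compound) & (annotations["tier"] == tier)
            ]
            if not hit.empty and bool(hit["cytotoxic"].iloc[0]):
                detail = "cytotoxic (no usable RNA was obtained)"
        raise NoExpressionDataError(
            f"no expression data for condition {compound!r} @ {tier!r}: {detail}"
        )
    control_ids: list[str] = []
    for (batch, vehicle), grp in treated.groupby(["batch", "vehicle"]):
        ctrl = active[
            (active["batch"] == batch)
            & (active["vehicle"] == vehicle)
            & (active["role"] == CONTROL_ROLE)
        ]
        control_ids.extend(ctrl["sample_id"].tolist())
    control_ids = list(dict.fromkeys(control_ids))  # dedupe, keep order
    if not control_ids:
        raise ValueError(
            f"no matched controls for condition {compound!r} @ {tier!r}"
        )
    return matrix[treated["sample_id"].tolist()], matrix[control_ids]
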