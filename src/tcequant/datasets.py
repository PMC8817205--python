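"""Data model and I/O for T-cell engager assay time courses.

The canonical in-memory container is :class:`TimeCourseDataset`, a thin
wrapper around a tidy long-format :class:`pandas.DataFrame` with one row
per (readout, concentration, time, replicate) observation.  Concentrations
are held internally in pM, times in hours; readout units are free-form
strings attached per readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "Compound",
    "TimeCourseDataset",
    "DoseResponseTable",
    "SchemaError",
    "IntegrityError",
    "read_timecourse",
    "write_timecourse",
    "read_timecourse_wide",
    "write_parameter_table",
]

#: required columns of the tidy long format
COLUMNS = ("readout", "concentration_pm", "time_h", "replicate", "value")

# Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema."""


class IntegrityError(ValueError):
    """Raised on duplicate observation keys or broken invariants."""


@dataclass(frozen=True)
class Compound:
    """A CD3-bispecific antibody and its binding characteristics.

    Parameters
    ----------
    name : str
        Compound identifier.
    molecular_weight : float
        Molecular weight in g/mol (a typical IgG-based T-cell bispecific
        is ~194 kDa, i.e. 194_000 g/mol).
    kd_ta : float
        Avidity/affinity to the tumor antigen, in nM.
    kd_cd3 : float
        Affinity of the CD3 arm, in nM.
    """

    name: str
    molecular_weight: float
    kd_ta: float = np.nan
    kd_cd3: float = np.nan

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValueError("molecular_weight must be > 0")
        for label, kd in (("kd_ta", self.kd_ta), ("kd_cd3", self.kd_cd3)):
            if not (np.isnan(kd) or kd > 0):
                raise ValueError(f"{label} must be > 0")


@dataclass
class TimeCourseDataset:
    """Tidy long-format assay time-course data.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``readout`` (str), ``concentration_pm`` (float, pM),
        ``time_h`` (float, h), ``replicate`` (str), ``value`` (float).
    readout_units : dict
        Map readout name -> unit string (e.g. ``"cells"``, ``"pg/mL"``).
    lloq : dict
        Map readout name -> lower limit of quantification in the
        readout's own units.  Optional per readout.
    """

    data: pd.DataFrame
    readout_units: dict[str, str] = field(default_factory=dict)
    lloq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.loc[:, list(COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        if (df["concentration_pm"] < 0).any():
            raise SchemaError("negative concentration encountered")
        if (df["time_h"] < 0).any():
            raise SchemaError("negative time encountered")
        keys = df[["readout", "concentration_pm", "time_h", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise IntegrityError(f"duplicate observation key: {dup}")

    # -- convenience accessors -------------------------------------------------
    @property
    def readouts(self) -> list[str]:
        return sorted(self.data["readout"].unique())

    def select(self, readout: str) -> pd.DataFrame:
        """Rows of a single readout, copy."""
        sub = self.data[self.data["readout"] == readout]
        if sub.empty:
            raise KeyError(f"readout {readout!r} not in dataset")
        return sub.copy()

    def concentrations(self, readout: str) -> np.ndarray:
        return np.sort(self.select(readout)["concentration_pm"].unique())

    def times(self, readout: str) -> np.ndarray:
        return np.sort(self.select(readout)["time_h"].unique())

    def with_data(self, data: pd.DataFrame) -> "TimeCourseDataset":
        """New dataset sharing units/LLOQ metadata but different rows."""
        return TimeCourseDataset(
            data=data.reset_index(drop=True),
            readout_units=dict(self.readout_units),
            lloq=dict(self.lloq),
        )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DoseResponseTable:
    """Per-concentration summary metric ready for dose-response fitting.

    ``metric_name`` is typically ``"AUCE"``, ``"Rmax"`` or ``"static@<t>"``.
    Concentrations must be strictly increasing (a zero-dose control point
    is allowed and handled by the fitted model's zero-concentration limit).
    """

    metric_name: str
    concentrations: np.ndarray
    values: np.ndarray
    metric_units: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.concentrations.shape != self.values.shape:
            raise SchemaError("concentrations and values must align")
        if np.any(np.diff(self.concentrations) <= 0):
            raise SchemaError("concentrations must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise SchemaError("negative concentration")

    def __len__(self) -> int:
        return len(self.concentrations)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_COLMAP = {
    "readout": "readout",
    "concentration": "concentration_pm",
    "concentration_pm": "concentration_pm",
    "time": "time_h",
    "time_h": "time_h",
    "replicate": "replicate",
    "value": "value",
}

_CONC_FACTORS_TO_PM = {"pm": 1.0, "nm": 1e3, "um": 1e6}


def _convert_concentration(
    values: pd.Series, unit: str, compound: Compound | None
) -> pd.Series:
    unit = unit.strip().lower()
    if unit in _CONC_FACTORS_TO_PM:
        return values * _CONC_FACTORS_TO_PM[unit]
    if unit in ("ug/ml", "µg/ml", "ng/ml"):
        if compound is None:
            raise SchemaError(
                f"mass concentration unit {unit!r} needs a Compound "
                "with molecular_weight for conversion to pM"
            )
        grams_per_l = values * (1e-3 if unit == "ng/ml" else 1.0) * 1e-3
        return grams_per_l / compound.molecular_weight * 1e12
    raise SchemaError(f"unsupported concentration unit {unit!r}")


def read_timecourse(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    readout_units: Mapping[str, str] | None = None,
    lloq: Mapping[str, float] | None = None,
    concentration_unit: str = "pM",
    compound: Compound | None = None,
) -> TimeCourseDataset:
    """Read a tidy long-format CSV time course.

    Parameters
    ----------
    path : path
        CSV file (RFC-4180, UTF-8, header row mandatory).
    column_map : mapping, optional
        Map from file column names to the canonical names
        ``readout, concentration_pm, time_h, replicate, value``.
    concentration_unit : str
        Unit of the concentration column (``pM``, ``nM``, ``uM`` or a mass
        unit, the latter requiring ``compound`` for molar conversion).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    rename = dict(_DEFAULT_COLMAP)
    if column_map:
        rename.update({src: dst for src, dst in column_map.items()})
    df = df.rename(columns={c: rename[c] for c in df.columns if c in rename})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    for col in ("concentration_pm", "time_h", "value"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()
            raise SchemaError(f"malformed numeric cell(s) in {col!r} at rows {rows}")
        df[col] = parsed
    df["readout"] = df["readout"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    if concentration_unit.strip().lower() != "pm":
        df["concentration_pm"] = _convert_concentration(
            df["concentration_pm"], concentration_unit, compound
        )
    return TimeCourseDataset(
        data=df[list(COLUMNS)],
        readout_units=dict(readout_units or {}),
        lloq=dict(lloq or {}),
    )


def write_timecourse(ds: TimeCourseDataset, path: str | Path) -> None:
    """Write a dataset back to tidy CSV (lossless for finite values)."""
    ds.data.to_csv(path, index=False)


def read_timecourse_wide(
    path: str | Path,
    time_columns: Mapping[str, float] | None = None,
    readout: str = "value",
    concentration_column: str = "concentration",
    replicate_column: str | None = "replicate",
    **kwargs,
) -> TimeCourseDataset:
    """Convenience importer for wide tables (one column per time point).

    ``time_columns`` maps column name -> time in hours; when omitted, every
    column other than the concentration/replicate columns is parsed as a
    number of hours.  The result is melted into the canonical long format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    id_cols = [concentration_column]
    if replicate_column and replicate_column in df.columns:
        id_cols.append(replicate_column)
    if time_columns is None:
        candidates = [c for c in df.columns if c not in id_cols]
        time_columns = {}
        for c in candidates:
            try:
                time_columns[c] = float(str(c).lower().rstrip("h").strip())
            except ValueError as exc:
                raise SchemaError(
                    f"cannot interpret column {c!r} as a time point; "
                    "pass time_columns explicitly"
                ) from exc
    long = df.melt(
        id_vars=id_cols, value_vars=list(time_columns), var_name="_tcol",
        value_name="value",
    )
    long["time_h"] = long["_tcol"].map(dict(time_columns))
    long["readout"] = readout
    long["concentration_pm"] = pd.to_numeric(long[concentration_column])
    if replicate_column and replicate_column in long.columns:
        long["replicate"] = long[replicate_column].astype(str)
    else:
        long["replicate"] = "1"
    long["value"] = pd.to_numeric(long["value"], errors="coerce")
    long = long.dropna(subset=["value"])
    return TimeCourseDataset(data=long[list(COLUMNS)], **kwargs)


def write_parameter_table(fits: Sequence, path: str | Path) -> pd.DataFrame:
    """Write fitted dose-response parameters as a delimited table.

    Each fit object must expose ``readout``, ``model_name`` and
    ``parameter_rows()`` yielding (parameter, estimate, se, rse_percent).
    Column layout mirrors the conventional potency-report format
    (estimate with %RSE per parameter).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to write")
    rows = []
    for fit in fits:
        for name, est, se, rse in fit.parameter_rows():
            rows.append(
                {
                    "readout": fit.readout,
                    "model": fit.model_name,
                    "parameter": name,
                    "estimate": est,
                    "se": se,
                    "rse_percent": rse,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
    return table
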