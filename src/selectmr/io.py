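"""Dataset readers/writers, fit serialization and metrics tables.

Individual-level data travel as delimited text (comma by default, tab
accepted) with a header row; missing cells are empty or ``NA``.  A role
map assigns columns to model roles.  Fits serialize to JSON; simulation
metrics to delimited tables with the column order Method, Mean, Emp SD,
StdErr, Cover, Power.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MRDataset, SelectionDataset

__all__ = ["read_table", "read_individual_data", "write_individual_data",
           "write_fit_json", "write_metrics_table"]

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_table(path, delimiter=None) -> pd.DataFrame:
    """Delimited text with header; delimiter sniffed from the extension
    (.tsv -> tab) unless given."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=delimiter, na_values=_NA_VALUES,
                       keep_default_na=True, float_precision="round_trip")


def read_individual_data(path, role_map, delimiter=None):
    """Parse a delimited file into a :class:`SelectionDataset` or
    :class:`MRDataset` according to the role map.

    Regression roles: ``outcome``, ``covariates`` (list),
    ``selection_instruments`` (list), optional ``selected``.
    MR roles: ``instruments`` (list), ``exposure``, ``outcome``,
    ``selection_instrument``, optional ``selected``.  A missing selection
    indicator is derived from outcome/exposure missingness.  Missing
    values in any instrument-for-selection column are a hard error.
    """
    df = read_table(path, delimiter=delimiter)
    roles = dict(role_map)
    needed = [c for key in ("outcome", "exposure", "selected",
                            "selection_instrument") if (c := roles.get(key))]
    for key in ("covariates", "selection_instruments", "instruments"):
        needed.extend(roles.get(key, []))
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise KeyError(f"role column(s) absent from file: {missing_cols}")
    for col in needed:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in numeric role column {col!r}")

    if "instruments" in roles:
        data = MRDataset.from_dataframe(
            df, instruments=roles["instruments"], exposure=roles["exposure"],
            outcome=roles["outcome"],
            selection_instrument=roles["selection_instrument"],
            selected=roles.get("selected"))
        n_missing = int((~data.selected).sum())
    else:
        data = SelectionDataset.from_dataframe(
            df, outcome=roles["outcome"],
            covariates=roles.get("covariates", []),
            selection_instruments=roles["selection_instruments"],
            selected=roles.get("selected"))
        n_missing = data.nobs - data.n_selected
    import logging
    logging.getLogger(__name__).info(
        "read %d rows from %s; missing fraction %.3f",
        data.nobs, path, n_missing / data.nobs)
    return data


def write_individual_data(df: pd.DataFrame, path, delimiter=","):
    """Write a tidy data frame losslessly (17 significant digits)."""
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g",
              na_rep="NA")


def write_fit_json(fit, path):
    """Serialize any fit object exposing ``to_dict`` to JSON."""
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_metrics_table(metrics: pd.DataFrame, path, delimiter=","):
    """Metrics table in the canonical column order."""
    out = metrics.rename(columns={
        "method": "Method", "mean": "Mean", "emp_sd": "Emp SD",
        "mean_se": "StdErr", "coverage": "Cover", "power": "Power",
        "n_failed": "Failed"})
    out.to_csv(path, sep=delimiter, index=False, float_format="%.6g")
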