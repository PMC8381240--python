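"""Closed-form assay statistics: qPCR ΔCT relative expression and flow iMFI.

Relative expression from qPCR threshold cycles (CT), normalized to a
housekeeping gene (Gapdh in the motivating experiments):

    value = 2 ** (CT_housekeeping - CT_target) * 1e4

Group-level fold increase is the ratio of (unpaired) group means of those
values.  The flow-cytometry integrated MFI is

    iMFI = frequency * MFI

with frequency on the percent-of-parent-gate scale (0-100); the scale choice
is a documented convention of this package.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import read_tsv

__all__ = [
    "relative_expression",
    "fold_increase",
    "imfi",
    "read_ct_table",
    "relative_expression_table",
    "fold_increase_summary",
    "read_flow_table",
    "imfi_table",
]

DCT_SCALE = 1e4

_CT_COLUMNS = ("sample", "group", "target", "ct_target", "ct_housekeeping")
_FLOW_COLUMNS = ("population", "frequency_percent", "mfi")


def relative_expression(ct_target, ct_housekeeping):
    """ΔCT relative expression: ``2 ** (ct_housekeeping - ct_target) * 1e4``.

    Accepts scalars or arrays; equal CTs give exactly 1e4.  Non-finite CTs
    raise.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_h = np.asarray(ct_housekeeping, dtype=float)
    if not (np.isfinite(ct_t).all() and np.isfinite(ct_h).all()):
        raise ValueError("CT values must be finite")
    value = np.power(2.0, ct_h - ct_t) * DCT_SCALE
    if value.ndim == 0:
        return float(value)
    return value


def fold_increase(values_case: Sequence[float], values_control: Sequence[float]) -> float:
    """Ratio of group arithmetic means (case over control, unpaired)."""
    case = np.asarray(values_case, dtype=float)
    control = np.asarray(values_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    control_mean = control.mean()
    if not control_mean > 0:
        raise ValueError("control mean must be positive")
    return float(case.mean() / control_mean)


def imfi(frequency_percent, mfi):
    """Integrated MFI: population frequency (percent, 0-100) times MFI."""
    freq = np.asarray(frequency_percent, dtype=float)
    m = np.asarray(mfi, dtype=float)
    if ((freq < 0) | (freq > 100)).any():
        raise ValueError("frequency must lie in [0, 100] percent")
    if (m < 0).any():
        raise ValueError("MFI must be non-negative")
    value = freq * m
    if value.ndim == 0:
        return float(value)
    return value


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns: {missing}")


def read_ct_table(source: str | Path) -> pd.DataFrame:
    """Read a CT table (columns sample, group, target, ct_target, ct_housekeeping)."""
    df = read_tsv(source)
    _require_columns(df, _CT_COLUMNS, "CT")
    return df


def relative_expression_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Append the per-row ΔCT relative-expression value."""
    _require_columns(ct, _CT_COLUMNS, "CT")
    out = ct.copy()
    out["relative_expression"] = relative_expression(
        out["ct_target"].to_numpy(), out["ct_housekeeping"].to_numpy()
    )
    return out


def fold_increase_summary(
    ct: pd.DataFrame, case_group: str, control_group: str
) -> pd.DataFrame:
    """Per-target fold increase of case over control group mean expression."""
    values = relative_expression_table(ct)
    rows = []
    for target, sub in values.groupby("target", sort=False):
        case = sub.loc[sub["group"] == case_group, "relative_expression"]
        control = sub.loc[sub["group"] == control_group, "relative_expression"]
        rows.append(
            {
                "target": target,
                "n_case": len(case),
                "n_control": len(control),
                "fold_increase": fold_increase(case, control),
            }
        )
    return pd.DataFrame(rows)


def read_flow_table(source: str | Path) -> pd.DataFrame:
    """Read a flow table (columns population, frequency_percent, mfi)."""
    df = read_tsv(source)
    _require_columns(df, _FLOW_COLUMNS, "flow")
    return df


def imfi_table(flow: pd.DataFrame) -> pd.DataFrame:
    """Append the iMFI column to a flow frequency/MFI table."""
    _require_columns(flow, _FLOW_COLUMNS, "flow")
    out = flow.copy()
    out["imfi"] = imfi(out["frequency_percent"].to_numpy(), out["mfi"].to_numpy())
    return out
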