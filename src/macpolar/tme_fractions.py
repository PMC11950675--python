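"""Post-deconvolution tumor-microenvironment analysis.

Consumes the outputs of an immune-deconvolution tool (per-sample
infiltration scores for each immune cell type, with treatment-group
labels) plus the upstream TPM expression matrix, and computes the
quantities of interest: low-expression gene filtering (TPM < 1), per-sample
M1/M2 macrophage ratios, and treatment-vs-control shifts of each cell
type's infiltration (fold change of group medians, exact Mann-Whitney p).

Group sizes of n = 3 per arm are typical for such in vivo designs; note the
exact two-sided Mann-Whitney p-value can then never go below 0.1
(C(6,3) = 20 assignments), which the result objects make visible via the
``exact`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .inference import TestResult, mann_whitney

#: Cell-type name variants from common deconvolution exports.
DEFAULT_CELLTYPE_ALIASES: Mapping[str, str] = {
    "m1 macrophage": "Macrophage.M1",
    "macrophage m1": "Macrophage.M1",
    "m1": "Macrophage.M1",
    "m2 macrophage": "Macrophage.M2",
    "macrophage m2": "Macrophage.M2",
    "m2": "Macrophage.M2",
}


@dataclass
class FractionTable:
    """Samples x cell types infiltration scores plus per-sample group label."""

    fractions: pd.DataFrame  # index: sample, columns: cell types, values >= 0
    groups: pd.Series        # index: sample, values: group label

    def __post_init__(self) -> None:
        if (self.fractions.to_numpy(dtype=float) < 0).any():
            raise ValidationError("infiltration scores must be >= 0")
        if not self.groups.index.equals(self.fractions.index):
            self.groups = self.groups.reindex(self.fractions.index)
        if self.groups.isna().any():
            missing = self.fractions.index[self.groups.isna()].tolist()
            raise ValidationError(f"samples without a group label: {missing}")

    def resolve_celltype(self, name: str,
                         aliases: Mapping[str, str] | None = None) -> str:
        table = {k.lower(): v for k, v in DEFAULT_CELLTYPE_ALIASES.items()}
        if aliases:
            table.update({k.lower(): v for k, v in aliases.items()})
        cols = {str(c).lower(): str(c) for c in self.fractions.columns}
        key = name.strip().lower()
        key = table.get(key, key).lower()
        for cand in (name, table.get(name.strip().lower(), name)):
            if str(cand) in map(str, self.fractions.columns):
                return str(cand)
        if key in cols:
            return cols[key]
        raise ValidationError(
            f"cell type {name!r} not found; available: "
            f"{[str(c) for c in self.fractions.columns]}"
        )


def read_fraction_table(path, sep: str = "\t",
                        group_column: str = "group") -> FractionTable:
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    cols = {c.lower(): c for c in df.columns}
    if group_column.lower() not in cols:
        raise ValidationError(
            f"fraction table needs a {group_column!r} column; has {list(df.columns)}"
        )
    gcol = cols[group_column.lower()]
    groups = df[gcol].astype(str)
    fractions = df.drop(columns=[gcol]).astype(float)
    return FractionTable(fractions, groups)


def write_fraction_table(table: FractionTable, path, sep: str = "\t") -> None:
    df = table.fractions.copy()
    df.insert(0, "group", table.groups)
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------


def filter_low_tpm(expr: pd.DataFrame, threshold: float = 1.0,
                   rule: str = "any") -> tuple[pd.DataFrame, dict]:
    """Drop low-expression genes from a genes x samples TPM matrix.

    ``rule`` sets the aggregation across samples: keep a gene if its TPM is
    >= threshold in at least one sample ("any", the least destructive and
    the default), in every sample ("all"), or on average ("mean").
    Returns the filtered matrix and a {retained, dropped} count report.
    """
    if expr.index.has_duplicates:
        raise ValidationError("duplicate gene ids")
    if (expr.to_numpy(dtype=float) < 0).any():
        raise ValidationError("TPM values must be >= 0")
    if rule == "any":
        keep = (expr >= threshold).any(axis=1)
    elif rule == "all":
        keep = (expr >= threshold).all(axis=1)
    elif rule == "mean":
        keep = expr.mean(axis=1) >= threshold
    else:
        raise ValidationError(f"unknown rule {rule!r}; use any/all/mean")
    out = expr.loc[keep]
    report = {"retained": int(keep.sum()), "dropped": int((~keep).sum())}
    return out, report


def m1m2_ratio(fractions: FractionTable, m1_label: str = "Macrophage.M1",
               m2_label: str = "Macrophage.M2") -> pd.DataFrame:
    """Per-sample M1/M2 infiltration ratio.

    A zero M2 score makes the ratio undefined; such samples are flagged
    (ratio NaN) rather than reported as infinite.
    """
    m1c = fractions.resolve_celltype(m1_label)
    m2c = fractions.resolve_celltype(m2_label)
    m1 = fractions.fractions[m1c].astype(float)
    m2 = fractions.fractions[m2c].astype(float)
    undefined = m2 == 0
    ratio = np.where(undefined, np.nan, m1 / m2.replace(0, np.nan))
    return pd.DataFrame({"m1": m1, "m2": m2, "ratio": ratio,
                         "undefined": undefined,
                         "group": fractions.groups})


@dataclass(frozen=True)
class GroupShift:
    group: str
    cell_type: str
    median_treatment: float
    median_control: float
    fold_change: float | None  # None when control median is 0
    test: TestResult

    @property
    def undefined(self) -> bool:
        return self.fold_change is None


def group_shift(fractions: FractionTable, cell_type: str, control_group: str,
                *, statistic: str = "median") -> list[GroupShift]:
    """Fold change of each treatment group vs control for one cell type.

    Fold change = statistic(treatment) / statistic(control) (median by
    default, mean optional); the two-sided Mann-Whitney test compares the
    raw per-sample scores of each group against the control's.
    """
    if statistic not in ("median", "mean"):
        raise ValidationError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    col = fractions.resolve_celltype(cell_type)
    groups = fractions.groups
    if control_group not in set(groups):
        raise ValidationError(
            f"control group {control_group!r} not present; groups: "
            f"{sorted(set(groups))}"
        )
    agg = np.median if statistic == "median" else np.mean
    ctrl_vals = fractions.fractions.loc[groups == control_group, col].to_numpy()
    ctrl_stat = float(agg(ctrl_vals))
    out = []
    for g in [g for g in pd.unique(groups) if g != control_group]:
        vals = fractions.fractions.loc[groups == g, col].to_numpy()
        g_stat = float(agg(vals))
        fc = None if ctrl_stat == 0 else g_stat / ctrl_stat
        test = mann_whitney(vals, ctrl_vals)
        out.append(GroupShift(str(g), col, g_stat, ctrl_stat, fc, test))
    return out


def shift_table(shifts: list[GroupShift]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": s.group, "cell_type": s.cell_type,
          "median_treatment": s.median_treatment,
          "median_control": s.median_control,
          "fold_change": np.nan if s.fold_change is None else s.fold_change,
          "undefined": s.undefined, "U": s.test.statistic, "p": s.test.p,
          "exact": s.test.exact} for s in shifts]
    ).set_index("group")
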