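"""The two normalizations used throughout: modified z-score and log2 FC.

Modified z-score
----------------
For one feature (marker or analyte) measured across samples,

    z_n = 0.6745 * (x_n - median(x)) / MAD(x),
    MAD(x) = median(|x - median(x)|).

The constant 0.6745 is the MAD of the standard normal distribution, so on
Gaussian data the modified z-score is numerically comparable to a classical
z-score while the median/MAD pair keeps single outliers from inflating the
scale.  By default the output is truncated to [-3.5, 3.5], the conventional
outlier band for this statistic; truncation can be disabled.

A feature constant across samples has MAD = 0 and carries no contrast; its
z column is set to all zeros and recorded as a warning (``mad_policy="zero"``,
the default) or raises (``mad_policy="error"``).

Log2 fold change
----------------
log2(treated / control) of a marker's MFI, comparing treatment conditions
within one cell line; replicate-wise values are summarised per condition by
their median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .panel_io import MFIMatrix

#: MAD of the standard normal distribution: Phi^-1(0.75).
MODIFIED_Z_CONSTANT = 0.6745

#: Conventional modified z-score outlier band.
DEFAULT_CLIP_BOUND = 3.5


@dataclass
class ZMatrix:
    """Samples x features modified z-scores.

    ``mad_zero_features`` lists features whose z column was forced to zero
    because the feature was constant across samples.
    """

    z_values: pd.DataFrame
    clipped: bool = True
    clip_bound: float = DEFAULT_CLIP_BOUND
    mad_zero_features: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.z_values.index]

    @property
    def features(self) -> list[str]:
        return [str(c) for c in self.z_values.columns]


def modified_zscore_column(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Raw (unclipped) modified z-scores of one feature across samples.

    Returns ``(z, mad_is_zero)``; when MAD = 0 the column is all zeros.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x), True
    return MODIFIED_Z_CONSTANT * (x - med) / mad, False


def modified_zscore(matrix: MFIMatrix | pd.DataFrame, *, clip: bool = True,
                    clip_bound: float = DEFAULT_CLIP_BOUND,
                    mad_policy: str = "zero") -> ZMatrix:
    """Modified z-score of every feature column, across samples.

    The transform is always across samples within one feature; the input
    orientation is fixed (rows = samples, columns = features) so the axis
    is never inferred.
    """
    values = matrix.values if isinstance(matrix, MFIMatrix) else matrix
    if values.shape[0] < 2:
        raise DegenerateDataError(
            f"modified z-score needs >= 2 samples, got {values.shape[0]}"
        )
    if mad_policy not in ("zero", "error"):
        raise ValidationError(f"mad_policy must be 'zero' or 'error', got {mad_policy!r}")
    if clip_bound <= 0:
        raise ValidationError(f"clip_bound must be > 0, got {clip_bound}")
    out = {}
    mad_zero = []
    for col in values.columns:
        z, degenerate = modified_zscore_column(values[col].to_numpy(dtype=float))
        if degenerate:
            if mad_policy == "error":
                raise DegenerateDataError(f"feature {col!r} has MAD = 0")
            mad_zero.append(str(col))
        out[col] = z
    z_df = pd.DataFrame(out, index=values.index)
    if clip:
        z_df = z_df.clip(-clip_bound, clip_bound)
    return ZMatrix(z_df, clipped=clip, clip_bound=clip_bound,
                   mad_zero_features=mad_zero)


def log2_fold_change(treated: float, control: float) -> float:
    """log2(treated / control); both MFIs must be positive."""
    if treated <= 0 or control <= 0:
        raise ValidationError(
            f"log2 fold change needs positive MFIs, got treated={treated}, "
            f"control={control}"
        )
    return float(np.log2(treated / control))


@dataclass
class Log2FCTable:
    """Per-sample log2 fold changes vs the matched control, with a
    per-condition median summary (replicates collapse by median)."""

    per_sample: pd.DataFrame      # index: sample_id, columns: features
    per_condition: pd.DataFrame   # index: condition, columns: features
    control_condition: str


def log2_fc_table(matrix: MFIMatrix, control_condition: str) -> Log2FCTable:
    """Element-wise log2 FC of each sample vs its replicate-matched control.

    Every replicate block must contain exactly one sample of the control
    condition; treated samples are divided by the control of their own
    replicate before taking log2.
    """
    conditions = {m.sample_id: m.condition for m in matrix.meta}
    replicates = {m.sample_id: m.replicate for m in matrix.meta}
    controls: dict[int, str] = {}
    for sid, cond in conditions.items():
        if cond == control_condition:
            rep = replicates[sid]
            if rep in controls:
                raise ValidationError(
                    f"replicate {rep} has multiple control samples: "
                    f"{controls[rep]!r}, {sid!r}"
                )
            controls[rep] = sid
    if not controls:
        raise ValidationError(
            f"no sample with control condition {control_condition!r}; "
            f"conditions present: {sorted(set(conditions.values()))}"
        )
    uncovered = [sid for sid, rep in replicates.items() if rep not in controls]
    if uncovered:
        raise ValidationError(
            f"no control of condition {control_condition!r} for replicate "
            f"block(s) of samples: {uncovered}"
        )
    rows = {}
    for sid in matrix.samples:
        ctrl = matrix.values.loc[controls[replicates[sid]]]
        rows[sid] = np.log2(matrix.values.loc[sid] / ctrl)
    per_sample = pd.DataFrame(rows).T.loc[matrix.samples]
    per_sample.index.name = "sample_id"
    cond_series = pd.Series({sid: conditions[sid] for sid in matrix.samples})
    per_condition = per_sample.groupby(cond_series).median()
    per_condition.index.name = "condition"
    return Log2FCTable(per_sample, per_condition, control_condition)


def write_long_format(df: pd.DataFrame, path, value_name: str = "value",
                      sep: str = "\t") -> None:
    """Write a wide samples x features table as long (sample, feature, value)."""
    long = df.stack().rename(value_name).reset_index()
    long.columns = ["sample", "feature", value_name]
    long.to_csv(path, sep=sep, index=False)
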