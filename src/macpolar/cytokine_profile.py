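"""Semi-quantitative antibody-array processing and association screening.

A membrane array carries each analyte as duplicate spots plus positive /
negative / blank control spots.  Spots are aggregated per analyte (mean of
duplicates, optional negative-control background subtraction floored at
zero), assembled into a samples x analytes matrix, normalized with the
modified z-score across samples, and screened for associations between
analyte signal intensity and macrophage-marker MFI.

Associations are Pearson correlations on the raw values (not z-scores):
two-sided p from the t statistic with n-2 df, 95% CI by the Fisher
z-transform, and Benjamini-Hochberg adjustment across all analyte x marker
pairs of one call at alpha = 0.10.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .panel_io import MFIMatrix
from .robust_transform import DEFAULT_CLIP_BOUND, ZMatrix, modified_zscore

CONTROL_ROLES = ("positive", "negative", "blank")


@dataclass(frozen=True)
class Spot:
    row: int
    column: int
    analyte: str  # analyte name, or a control role
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0 or not np.isfinite(self.intensity):
            raise ValidationError(
                f"spot ({self.row},{self.column}) {self.analyte!r}: "
                f"bad intensity {self.intensity}"
            )

    @property
    def is_control(self) -> bool:
        return self.analyte in CONTROL_ROLES


@dataclass
class SpotGrid:
    """All spots of one membrane (one sample)."""

    membrane_id: str
    spots: list[Spot]

    def __post_init__(self) -> None:
        coords = [(s.row, s.column) for s in self.spots]
        if len(set(coords)) != len(coords):
            raise ValidationError(f"{self.membrane_id}: duplicate spot coordinates")
        counts = {}
        for s in self.spots:
            if not s.is_control:
                counts[s.analyte] = counts.get(s.analyte, 0) + 1
        if counts and len(set(counts.values())) > 1:
            raise ValidationError(
                f"{self.membrane_id}: unequal duplicate counts per analyte: {counts}"
            )

    def analytes(self) -> list[str]:
        seen = []
        for s in self.spots:
            if not s.is_control and s.analyte not in seen:
                seen.append(s.analyte)
        return seen


def aggregate_spots(grid: SpotGrid, background: str = "none") -> pd.Series:
    """One cytokine-matrix row: per-analyte mean of duplicate spots.

    ``background="negative_control"`` subtracts the mean negative-control
    intensity and floors at zero.
    """
    if background not in ("none", "negative_control"):
        raise ValidationError(f"unknown background mode {background!r}")
    analytes = grid.analytes()
    if not analytes:
        raise ValidationError(f"{grid.membrane_id}: no analyte spots")
    bg = 0.0
    if background == "negative_control":
        neg = [s.intensity for s in grid.spots if s.analyte == "negative"]
        if not neg:
            raise ValidationError(
                f"{grid.membrane_id}: background subtraction requested but no "
                "negative-control spots present"
            )
        bg = float(np.mean(neg))
    out = {}
    for a in analytes:
        vals = [s.intensity for s in grid.spots if s.analyte == a]
        out[a] = max(float(np.mean(vals)) - bg, 0.0)
    return pd.Series(out, name=grid.membrane_id)


def assemble_cytokine_matrix(grids: list[SpotGrid],
                             background: str = "none") -> pd.DataFrame:
    """Stack per-membrane rows into a samples x analytes matrix."""
    rows = [aggregate_spots(g, background) for g in grids]
    df = pd.DataFrame(rows)
    if df.isna().any().any():
        raise ValidationError("membranes disagree on the analyte set")
    return df


def normalize_cytokines(matrix: pd.DataFrame, *, clip: bool = True,
                        clip_bound: float = DEFAULT_CLIP_BOUND) -> ZMatrix:
    """Modified z-score of each analyte across samples (cell lines)."""
    if (matrix.to_numpy(dtype=float) < 0).any():
        raise ValidationError("cytokine matrix has negative intensities")
    return modified_zscore(matrix, clip=clip, clip_bound=clip_bound)


def top_expressed(z: ZMatrix, sample: str, cutoff: float = 1.0) -> list[str]:
    """Analytes with z >= cutoff in ``sample``, sorted by decreasing z."""
    if sample not in z.z_values.index:
        raise ValidationError(f"sample {sample!r} not in z-matrix")
    row = z.z_values.loc[sample]
    hits = row[row >= cutoff].sort_values(ascending=False)
    return [str(a) for a in hits.index]


def read_spot_grid(path, membrane_id: str | None = None, sep: str = "\t") -> SpotGrid:
    """Read a spot map: columns row, col, analyte, intensity."""
    df = pd.read_csv(path, sep=sep)
    need = {"row", "col", "analyte", "intensity"}
    if not need.issubset({c.lower() for c in df.columns}):
        raise ValidationError(f"spot map needs columns {sorted(need)}")
    cols = {c.lower(): c for c in df.columns}
    spots = [Spot(int(r[cols["row"]]), int(r[cols["col"]]),
                  str(r[cols["analyte"]]), float(r[cols["intensity"]]))
             for _, r in df.iterrows()]
    mid = membrane_id or str(getattr(path, "stem", path))
    return SpotGrid(mid, spots)


# ---------------------------------------------------------------------------
# association screening


def _pearson_with_ci(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """r, two-sided p (t with n-2 df) and Fisher-z 95% CI.

    At |r| = 1 the Fisher transform diverges; the CI degenerates to [r, r].
    """
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if abs(r) >= 1.0 - 1e-12:
        return r, p, r, r
    ci = res.confidence_interval(confidence_level=0.95)
    return r, p, float(ci.low), float(ci.high)


def cytokine_marker_association(cyt: pd.DataFrame, mfi: MFIMatrix | pd.DataFrame,
                                *, alpha: float = 0.10) -> pd.DataFrame:
    """Screen every analyte x marker pair for Pearson association.

    Both tables must cover the same samples (matched by id, order-free).
    Pairs where either series has zero variance are reported with
    ``undefined=True`` and excluded from the BH family rather than given a
    fabricated r of zero.

    Returns a table with columns analyte, marker, n, r, ci_low, ci_high,
    p, q, significant_raw (p < 0.05), significant_fdr (q <= alpha),
    undefined.
    """
    from statsmodels.stats.multitest import multipletests

    mfi_df = mfi.values if isinstance(mfi, MFIMatrix) else mfi
    common = [s for s in cyt.index if s in mfi_df.index]
    if set(cyt.index) != set(mfi_df.index):
        raise ValidationError(
            "cytokine and MFI tables cover different samples: "
            f"{sorted(set(cyt.index) ^ set(mfi_df.index))}"
        )
    n = len(common)
    if n < 3:
        raise DegenerateDataError(f"association screen needs n >= 3 samples, got {n}")
    cyt = cyt.loc[common]
    mfi_df = mfi_df.loc[common]
    rows = []
    for analyte, marker in itertools.product(cyt.columns, mfi_df.columns):
        x = cyt[analyte].to_numpy(dtype=float)
        y = mfi_df[marker].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"analyte": analyte, "marker": marker, "n": n,
                         "r": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "undefined": True})
            continue
        r, p, lo, hi = _pearson_with_ci(x, y)
        rows.append({"analyte": analyte, "marker": marker, "n": n,
                     "r": r, "ci_low": lo, "ci_high": hi, "p": p,
                     "undefined": False})
    out = pd.DataFrame(rows)
    defined = ~out["undefined"]
    out["q"] = np.nan
    out["significant_raw"] = False
    out["significant_fdr"] = False
    if defined.any():
        pvals = out.loc[defined, "p"].to_numpy()
        reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        out.loc[defined, "q"] = qvals
        out.loc[defined, "significant_raw"] = pvals < 0.05
        out.loc[defined, "significant_fdr"] = reject
    return out
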