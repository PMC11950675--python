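"""Composite M1/M2 macrophage polarization scoring and classification.

A macrophage sample co-cultured with a cancer cell line is scored by
averaging the modified z-scores of its M1 markers (CD86, CD80, MHC II,
CD274, CD11c) and, separately, its M2 markers (CD163, CD206), both computed
across the study's samples.  The (m1, m2) score pair is then classified:

==========  =============================================
type        condition (checked in order)
==========  =============================================
M1          m1 > 0.5 and m2 < 0
M2          m2 > 0.5 and m1 < 0
Unpolarized m1 < 0 and m2 < 0
Mixed       otherwise
==========  =============================================

Polarization strength uses the type-congruent score (m1 for M1, m2 for M2,
max(|m1|, |m2|) for Mixed; Unpolarized is always "none").  The score is
rounded to one decimal before binning — none below 0.5, moderate in
[0.5, 1], strong above 1 — so that a score of e.g. 0.48 reads as 0.5 and
bins as moderate, matching how such tables are reported at one-decimal
precision.  Rounding can be disabled with ``round_strength=False``.

Because the z-scores are relative to the sample set, adding or removing a
sample re-normalizes every column and may change classifications; that is a
property of the method, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel_io import MarkerPanel, MFIMatrix
from .robust_transform import DEFAULT_CLIP_BOUND, ZMatrix, modified_zscore

PTYPES = ("M1", "M2", "Mixed", "Unpolarized")
STRENGTHS = ("none", "moderate", "strong")


@dataclass(frozen=True)
class PolarizationResult:
    sample_id: str
    m1_score: float
    m2_score: float
    ptype: str
    strength: str


@dataclass(frozen=True)
class StemnessCategory:
    """Expression bin of a stemness marker's percent-positive value:
    low below 10%, high above 40%, moderate in between."""

    marker: str
    percent_positive: float
    category: str


def polarization_scores(z: ZMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Per-sample (m1_score, m2_score): unweighted means of role-marker z."""
    panel.require_polarization_markers()
    m1_cols = panel.resolve(z.features, "M1")
    m2_cols = panel.resolve(z.features, "M2")
    return pd.DataFrame({
        "m1_score": z.z_values[m1_cols].mean(axis=1),
        "m2_score": z.z_values[m2_cols].mean(axis=1),
    })


def classify_polarization(m1: float, m2: float, *,
                          round_strength: bool = True) -> tuple[str, str]:
    """Classify a score pair into (polarization type, strength)."""
    if not (math.isfinite(m1) and math.isfinite(m2)):
        raise ValidationError(f"non-finite polarization scores: ({m1}, {m2})")
    if m1 > 0.5 and m2 < 0:
        ptype, s = "M1", m1
    elif m2 > 0.5 and m1 < 0:
        ptype, s = "M2", m2
    elif m1 < 0 and m2 < 0:
        return "Unpolarized", "none"
    else:
        ptype, s = "Mixed", max(abs(m1), abs(m2))
    if round_strength:
        s = round(s, 1)
    if s < 0.5:
        strength = "none"
    elif s <= 1:
        strength = "moderate"
    else:
        strength = "strong"
    return ptype, strength


def stemness_category(marker: str, percent_positive: float) -> StemnessCategory:
    if not 0 <= percent_positive <= 100:
        raise ValidationError(
            f"percent positive must be in [0, 100], got {percent_positive}"
        )
    if percent_positive < 10:
        cat = "low"
    elif percent_positive > 40:
        cat = "high"
    else:
        cat = "moderate"
    return StemnessCategory(marker, float(percent_positive), cat)


def score_study(mfi: MFIMatrix, panel: MarkerPanel, *, clip: bool = True,
                clip_bound: float = DEFAULT_CLIP_BOUND,
                round_strength: bool = True,
                ) -> tuple[list[PolarizationResult], ZMatrix]:
    """End-to-end scoring of one study: MFI -> z -> scores -> labels.

    Returns one result per sample plus the intermediate z-matrix for audit.
    Needs at least two samples: the z-transform is a cross-sample contrast.
    """
    if len(mfi.samples) < 2:
        raise ValidationError("polarization scoring needs >= 2 samples")
    z = modified_zscore(mfi, clip=clip, clip_bound=clip_bound)
    scores = polarization_scores(z, panel)
    results = []
    for sid in mfi.samples:
        m1 = float(scores.loc[sid, "m1_score"])
        m2 = float(scores.loc[sid, "m2_score"])
        ptype, strength = classify_polarization(m1, m2, round_strength=round_strength)
        results.append(PolarizationResult(sid, m1, m2, ptype, strength))
    return results, z


def results_table(results: list[PolarizationResult]) -> pd.DataFrame:
    """Report-shaped table: sample, scores (2 decimals preserved as float),
    polarization type and strength."""
    return pd.DataFrame(
        [{"sample_id": r.sample_id, "m1_score": r.m1_score, "m2_score": r.m2_score,
          "polarization_type": r.ptype, "polarization_strength": r.strength}
         for r in results]
    ).set_index("sample_id")
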