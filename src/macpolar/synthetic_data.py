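"""Seeded generators for every input format the pipeline consumes.

Each generator is a pure function of a :class:`SyntheticConfig` (seed
included): calling it twice with the same config yields identical data.
The defaults emulate the study conditions the analytics were built for —
20,000 events per cytometry sample, an eight-line co-culture panel over
the seven-marker M1/M2 panel with lognormal MFI noise (CV 15%) and planted
inducer effects of +/-2 MAD, cytokine analytes with planted Pearson links
to marker MFIs across eight lines, four-parameter-logistic viability
curves on decade dose grids, and six-arm (n = 3) infiltration-fraction
tables with planted multiplicative group shifts.

Event fluorescence is a two-component lognormal mixture and MFI noise is
multiplicative lognormal: fluorescence intensities are positive and
right-skewed by nature, which lognormality reproduces while keeping every
generated value strictly positive for the downstream log/ratio transforms.

Planted cell-line effects are expressed in MAD units and mapped onto log-MFI
through a fixed profile scale; because the eight default profiles differ
from each other, the cross-line MAD of every marker is set by the profile
spread itself, so with noise switched off the scoring pipeline recovers the
planted polarization types exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gating import EventTable, GateSpec
from .inference import DoseResponseCurve, four_pl
from .panel_io import MFIMatrix, SampleMeta, default_panel
from .tme_fractions import FractionTable

#: Eight virtual cell lines: (M1-marker effect, M2-marker effect) in MAD
#: units.  Two strong inducers (+2 on own markers, -1 on the opposite set),
#: two moderate, two neutral, one unpolarized, one mixed — mirroring the
#: qualitative diversity of a real co-culture panel.
DEFAULT_LINE_PROFILES: Mapping[str, tuple[float, float]] = {
    "VL1-M1strong": (2.0, -1.0),
    "VL2-M2strong": (-1.0, 2.0),
    "VL3-M1mod": (1.0, -0.5),
    "VL4-M2mod": (-0.5, 1.0),
    "VL5-neutral": (0.0, 0.0),
    "VL6-neutral": (0.1, -0.1),
    "VL7-unpol": (-1.0, -1.0),
    "VL8-mixed": (0.8, 0.8),
}

#: Plausible baseline MFIs (a.u.) per panel marker.
DEFAULT_MARKER_BASELINES: Mapping[str, float] = {
    "CD86": 1500.0, "CD80": 800.0, "MHC II": 5000.0, "CD274": 600.0,
    "CD11c": 2000.0, "CD163": 1200.0, "CD206": 900.0,
}

DEFAULT_CYTOKINE_LINKS: tuple[tuple[str, str, float], ...] = (
    ("IL4", "CD206", 0.95),
    ("CXCL9", "CD86", 0.95),
    ("CCL8", "CD163", 0.95),
)

DEFAULT_DISTRACTOR_ANALYTES: tuple[str, ...] = (
    "IL7", "CCL3", "EGF", "ICAM1", "OSM", "IL15",
)

DEFAULT_FRACTION_BASELINES: Mapping[str, float] = {
    "Macrophage": 0.45, "Macrophage.M1": 0.08, "Macrophage.M2": 0.30,
    "DC": 0.05, "Monocyte": 0.08, "Neutrophil": 0.05,
}

#: Planted multiplicative shifts vs control, per arm and cell type.
DEFAULT_FRACTION_EFFECTS: Mapping[str, Mapping[str, float]] = {
    "SB": {"Macrophage.M2": 0.5, "Macrophage": 0.5},
    "COMBO": {"Macrophage.M2": 0.5, "Macrophage": 0.5},
}

DEFAULT_ARMS: tuple[str, ...] = ("CTRL", "SAL", "SB", "JIB", "NAPA", "COMBO")


@dataclass
class SyntheticConfig:
    """All knobs of the generators; defaults are the emulated study design."""

    seed: int = 0
    # flow events
    n_events: int = 20_000
    positive_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"CD44": 0.42, "CD133": 0.10})
    negative_median: float = 100.0
    positive_median: float = 1000.0
    event_log_sd: float = 0.35
    debris_fraction: float = 0.08
    # MFI panel study
    cell_line_profiles: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LINE_PROFILES))
    marker_baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_BASELINES))
    mfi_cv: float = 0.15
    profile_scale: float = 0.35  # log-MFI units per MAD-unit of effect
    # cytokine study
    cytokine_links: Sequence[tuple[str, str, float]] = DEFAULT_CYTOKINE_LINKS
    distractor_analytes: Sequence[str] = DEFAULT_DISTRACTOR_ANALYTES
    cytokine_log_sd: float = 0.30
    cytokine_baseline: float = 1000.0
    # dose-response
    true_ic50: float = 3.0
    hill: float = 1.0
    dose_noise_sd: float = 2.0  # % of control, additive
    doses: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0)
    dose_replicates: int = 3
    # fraction study
    fraction_arms: Sequence[str] = DEFAULT_ARMS
    n_per_arm: int = 3
    fraction_baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_BASELINES))
    fraction_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_FRACTION_EFFECTS.items()})
    fraction_cv: float = 0.10

    def __post_init__(self) -> None:
        for ch, f in self.positive_fractions.items():
            if not 0 <= f <= 1:
                raise ValidationError(f"positive fraction for {ch!r} not in [0,1]: {f}")
        for a, m, rho in self.cytokine_links:
            if not -1 < rho < 1:
                raise ValidationError(f"link ({a},{m}): rho must be in (-1,1), got {rho}")
        if self.true_ic50 <= 0:
            raise ValidationError("true_ic50 must be > 0")
        if not 0 <= self.debris_fraction < 1:
            raise ValidationError("debris_fraction must be in [0,1)")

    def rng(self, stream: str = "") -> np.random.Generator:
        # crc32 (not hash()) so streams are stable across interpreter runs
        if stream:
            return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(self.seed)

    @property
    def positivity_threshold(self) -> float:
        """Geometric midpoint of the two mixture medians — the planted
        per-channel positivity cutoff."""
        return float(np.sqrt(self.negative_median * self.positive_median))

    @property
    def scatter_gate(self) -> GateSpec:
        """Rectangular gate known to contain the live population."""
        return GateSpec(scatter_bounds={"FSC": (20_000.0, 260_000.0),
                                        "SSC": (5_000.0, 200_000.0)})


def simulate_flow_sample(cfg: SyntheticConfig, sample_id: str = "synthetic") -> EventTable:
    """One stained sample: scatter channels plus two-component lognormal
    fluorescence mixtures with the planted positive fractions.

    A fraction ``debris_fraction`` of events falls below the known scatter
    gate (:attr:`SyntheticConfig.scatter_gate`), so gating retains
    approximately ``1 - debris_fraction`` of events.
    """
    rng = cfg.rng()
    n = cfg.n_events
    debris = rng.random(n) < cfg.debris_fraction
    fsc = np.where(debris,
                   rng.uniform(1_000, 15_000, n),
                   rng.normal(100_000, 25_000, n).clip(25_000, 255_000))
    ssc = np.where(debris,
                   rng.uniform(500, 4_000, n),
                   rng.normal(60_000, 20_000, n).clip(6_000, 195_000))
    cols = {"FSC": fsc, "SSC": ssc}
    for ch, frac in cfg.positive_fractions.items():
        pos = rng.random(n) < frac
        med = np.where(pos, cfg.positive_median, cfg.negative_median)
        cols[ch] = med * np.exp(rng.normal(0.0, cfg.event_log_sd, n))
    return EventTable(sample_id, pd.DataFrame(cols))


def _panel_log_medians(cfg: SyntheticConfig) -> pd.DataFrame:
    panel = default_panel()
    rows = {}
    for line, (d_m1, d_m2) in cfg.cell_line_profiles.items():
        row = {}
        for marker in panel.markers():
            base = cfg.marker_baselines[marker]
            delta = d_m1 if marker in panel.m1_markers else d_m2
            row[marker] = np.log(base) + delta * cfg.profile_scale
        rows[line] = row
    return pd.DataFrame(rows).T


def simulate_panel_study(cfg: SyntheticConfig) -> MFIMatrix:
    """Eight virtual cell lines x seven-marker panel with multiplicative
    lognormal MFI noise (CV ``mfi_cv``) around the planted per-line medians."""
    log_med = _panel_log_medians(cfg)
    rng = cfg.rng("panel")
    sigma = float(np.sqrt(np.log1p(cfg.mfi_cv ** 2)))
    noise = rng.normal(0.0, sigma, size=log_med.shape) if sigma > 0 else 0.0
    values = np.exp(log_med + noise)
    meta = [SampleMeta(str(s), condition="co-culture") for s in values.index]
    return MFIMatrix(values, meta)


def planted_types(cfg: SyntheticConfig) -> dict[str, str]:
    """Polarization type of each virtual line under zero noise — the ground
    truth the noisy recovery tests compare against."""
    from .polarization import score_study

    noiseless = MFIMatrix(np.exp(_panel_log_medians(cfg)))
    results, _ = score_study(noiseless, default_panel())
    return {r.sample_id: r.ptype for r in results}


def simulate_cytokine_study(cfg: SyntheticConfig
                            ) -> tuple[pd.DataFrame, MFIMatrix]:
    """Cytokine-array matrix paired with a marker MFI matrix.

    Linked analytes are built on the log scale as
    ``rho * z(marker) + sqrt(1-rho^2) * noise`` against the standardized
    log-MFI of their marker, so the planted Pearson correlation holds
    across the virtual lines; distractor analytes are independent.
    """
    mfi = simulate_panel_study(cfg)
    rng = cfg.rng("cytokine")
    log_mfi = np.log(mfi.values)
    rows = {}
    for analyte, marker, rho in cfg.cytokine_links:
        zm = (log_mfi[marker] - log_mfi[marker].mean()) / log_mfi[marker].std(ddof=0)
        eps = rng.normal(0.0, 1.0, len(zm))
        za = rho * zm.to_numpy() + np.sqrt(1 - rho ** 2) * eps
        rows[analyte] = cfg.cytokine_baseline * np.exp(cfg.cytokine_log_sd * za)
    for analyte in cfg.distractor_analytes:
        rows[analyte] = cfg.cytokine_baseline * np.exp(
            cfg.cytokine_log_sd * rng.normal(0.0, 1.0, len(mfi.samples)))
    cyt = pd.DataFrame(rows, index=mfi.values.index)
    return cyt, mfi


def simulate_dose_response(cfg: SyntheticConfig) -> DoseResponseCurve:
    """4PL viability curve (% of control) with additive Gaussian noise."""
    rng = cfg.rng("dose")
    doses = np.asarray(cfg.doses, dtype=float)
    clean = four_pl(doses, cfg.true_ic50, cfg.hill)
    resp = clean[:, None] + rng.normal(0.0, cfg.dose_noise_sd,
                                       (doses.size, cfg.dose_replicates))
    return DoseResponseCurve(doses, resp)


def simulate_fraction_study(cfg: SyntheticConfig) -> FractionTable:
    """Six-arm infiltration-fraction table, n per arm as configured, with
    planted multiplicative shifts and lognormal noise (CV ``fraction_cv``)."""
    rng = cfg.rng("fractions")
    sigma = float(np.sqrt(np.log1p(cfg.fraction_cv ** 2)))
    records, groups = {}, {}
    for arm in cfg.fraction_arms:
        effects = cfg.fraction_effects.get(arm, {})
        for i in range(cfg.n_per_arm):
            sid = f"{arm}-{i + 1}"
            row = {}
            for ct, base in cfg.fraction_baselines.items():
                med = base * effects.get(ct, 1.0)
                row[ct] = med * np.exp(rng.normal(0.0, sigma))
            records[sid] = row
            groups[sid] = arm
    fractions = pd.DataFrame(records).T
    return FractionTable(fractions, pd.Series(groups))
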