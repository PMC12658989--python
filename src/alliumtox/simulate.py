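"""Synthetic Allium cepa assay data with known ground truth.

Three generators emulate the wet-lab stages so every downstream estimator can
be tested against parameters it should recover:

* root growth — group mean length is ``control_mean * (1 - min(1, slope*c))``
  (linear inhibition, so the OLS EC50 estimator is correctly specified, with
  true EC50 = 0.5/slope) plus Gaussian noise clamped at zero;
* cell counts — each slide is a multinomial over {non-dividing normal,
  dividing, six aberration categories}, with the dividing probability set by
  the true mitotic index and the aberrant mass split uniformly over the six
  categories (aberrant cells are tallied separately from dividing cells, so
  MF = CA/MI holds at the level of the truth);
* band matrices — each control band is lost with p = 1 - exp(-loss_rate*c*m)
  and each non-control pool locus gained with p = 1 - exp(-gain_rate*c*m),
  m = 1 for single and combined treatments and ``positive_control_multiplier``
  for the positive-control lane.

Determinism: one integer seed; the three generators draw from independent
streams ``default_rng([seed, k])`` with k = 0 (roots), 1 (cells), 2 (bands),
so each stage is reproducible independently of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .cytogenetics import ABERRATION_CATEGORIES, CellCounts
from .doseresponse import RootGrowthRecord
from .issr import BandMatrix

_STREAM_ROOTS, _STREAM_CELLS, _STREAM_BANDS = 0, 1, 2

# Defaults mirror the study conditions: test concentrations (0.5, 1, 1.5) x
# EC50 of 43 mg/mL, three exposures, 40 roots per group, 3 slides x 1000
# cells, control means and control MI/CA per exposure as observed, and band
# pool shaped like a typical single-primer gel (13 loci, 7 control bands,
# 193-3076 bp).


def _default_control_lengths() -> dict[float, float]:
    return {24.0: 40.43, 48.0: 49.33, 72.0: 60.5}


def _default_mi0() -> dict[float, float]:
    return {24.0: 20.93, 48.0: 25.20, 72.0: 31.00}


def _default_ca0() -> dict[float, float]:
    return {24.0: 0.20, 48.0: 0.53, 72.0: 1.03}


@dataclass
class SimulationConfig:
    seed: int = 0
    concentrations: tuple[float, ...] = (0.0, 21.5, 43.0, 64.5)
    exposures_h: tuple[float, ...] = (24.0, 48.0, 72.0)
    n_roots_per_group: int = 40
    n_slides: int = 3
    cells_per_slide: int = 1000
    control_mean_length_mm: dict[float, float] = field(default_factory=_default_control_lengths)
    inhibition_slope: float = 0.5 / 43.0  # fraction of control lost per mg/mL
    noise_sd_mm: float = 4.0
    mi0_percent: dict[float, float] = field(default_factory=_default_mi0)
    mi_decay: float = 0.074  # MI percentage points lost per mg/mL
    ca0_percent: dict[float, float] = field(default_factory=_default_ca0)
    ca_slope: float = 0.0764  # CA percentage points gained per mg/mL
    band_pool_size: int = 13
    control_band_count: int = 7
    loss_rate: float = 0.0052  # per mg/mL
    gain_rate: float = 0.0028  # per mg/mL
    positive_control_multiplier: float = 40.0
    positive_control_concentration: float = 4.0  # mg/mL (the reference mutagen)

    def validate(self) -> None:
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if min(self.n_roots_per_group, self.n_slides, self.cells_per_slide) < 1:
            raise ValueError("group sizes must be >= 1")
        for name in ("inhibition_slope", "noise_sd_mm", "mi_decay", "ca_slope",
                     "loss_rate", "gain_rate", "positive_control_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.control_band_count > self.band_pool_size:
            raise ValueError("control_band_count cannot exceed band_pool_size")
        for t in self.exposures_h:
            if t not in self.control_mean_length_mm:
                raise ValueError(f"no control mean length for exposure {t}")
            if t not in self.mi0_percent or t not in self.ca0_percent:
                raise ValueError(f"no control MI/CA for exposure {t}")


@dataclass
class GroundTruth:
    """True parameters stored alongside each simulated dataset."""

    true_ec50: float
    mean_length_mm: dict[tuple[float, float], float] = field(default_factory=dict)
    true_mi_percent: dict[tuple[float, float], float] = field(default_factory=dict)
    true_ca_percent: dict[tuple[float, float], float] = field(default_factory=dict)
    expected_lost_bands: dict[str, float] = field(default_factory=dict)
    expected_gained_bands: dict[str, float] = field(default_factory=dict)
    clamped: bool = False  # inhibition hit 100% within the tested range

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("mean_length_mm", "true_mi_percent", "true_ca_percent"):
            d[key] = {f"{c}|{t}": v for (c, t), v in d[key].items()}
        return d


def true_mean_length(config: SimulationConfig, concentration: float, exposure_h: float) -> float:
    frac = min(1.0, config.inhibition_slope * concentration)
    return config.control_mean_length_mm[exposure_h] * (1.0 - frac)


def true_mi(config: SimulationConfig, concentration: float, exposure_h: float) -> float:
    return max(0.0, config.mi0_percent[exposure_h] - config.mi_decay * concentration)


def true_ca(config: SimulationConfig, concentration: float, exposure_h: float) -> float:
    return min(100.0, config.ca0_percent[exposure_h] + config.ca_slope * concentration)


def simulate_root_growth(
    config: SimulationConfig,
) -> tuple[list[RootGrowthRecord], GroundTruth]:
    """Root-length records for every exposure x concentration group.

    Lengths are Gaussian around the linear-inhibition mean, clamped at 0 mm.
    If ``inhibition_slope * max(c) > 1`` the mean is clamped at full
    inhibition and the ground truth notes the clamp (not fatal).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_ROOTS])
    truth = GroundTruth(
        true_ec50=(0.5 / config.inhibition_slope) if config.inhibition_slope > 0 else math.inf,
        clamped=bool(
            config.concentrations
            and config.inhibition_slope * max(config.concentrations) > 1.0
        ),
    )
    records: list[RootGrowthRecord] = []
    for t in config.exposures_h:
        for c in config.concentrations:
            mu = true_mean_length(config, c, t)
            truth.mean_length_mm[(c, t)] = mu
            lengths = mu + rng.normal(0.0, config.noise_sd_mm, config.n_roots_per_group) \
                if config.noise_sd_mm > 0 else np.full(config.n_roots_per_group, mu)
            lengths = np.maximum(lengths, 0.0)
            label = "negative_control" if c == 0 else "single"
            for i, length in enumerate(lengths):
                records.append(
                    RootGrowthRecord(
                        treatment=label, concentration=c, exposure_h=t,
                        replicate=i, length_mm=float(length),
                    )
                )
    return records, truth


def _slide_counts(
    rng: np.random.Generator, n_cells: int, mi_pct: float, ca_pct: float
) -> tuple[int, dict[str, int]]:
    p_div = mi_pct / 100.0
    p_ab = ca_pct / 100.0
    p_div, p_ab = max(0.0, min(1.0, p_div)), max(0.0, min(1.0, p_ab))
    p_normal = 1.0 - p_div - p_ab
    if p_normal < 0:
        raise ValueError("MI + CA probabilities exceed 1")
    probs = [p_normal, p_div] + [p_ab / len(ABERRATION_CATEGORIES)] * len(ABERRATION_CATEGORIES)
    counts = rng.multinomial(n_cells, probs)
    aberrations = dict(zip(ABERRATION_CATEGORIES, (int(x) for x in counts[2:])))
    return int(counts[1]), aberrations


def simulate_cell_counts(
    config: SimulationConfig,
    include_positive_control: bool = False,
    positive_control_mi: float = 10.2,
    positive_control_ca: float = 9.9,
) -> tuple[list[CellCounts], GroundTruth]:
    """Per-slide multinomial cell tallies for every exposure x concentration.

    Optionally adds a positive-control (reference mutagen) group with its own
    MI/CA truth so mutagenicity inhibition can be exercised end to end.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_CELLS])
    truth = GroundTruth(
        true_ec50=(0.5 / config.inhibition_slope) if config.inhibition_slope > 0 else math.inf
    )
    slides: list[CellCounts] = []
    for t in config.exposures_h:
        groups: list[tuple[str, float, float, float]] = []
        for c in config.concentrations:
            label = "negative_control" if c == 0 else "single"
            groups.append((label, c, true_mi(config, c, t), true_ca(config, c, t)))
        if include_positive_control:
            groups.append(
                ("positive_control", config.positive_control_concentration,
                 positive_control_mi, positive_control_ca)
            )
        for label, c, mi_pct, ca_pct in groups:
            truth.true_mi_percent[(c, t)] = mi_pct
            truth.true_ca_percent[(c, t)] = ca_pct
            for k in range(config.n_slides):
                tcd, ab = _slide_counts(rng, config.cells_per_slide, mi_pct, ca_pct)
                slides.append(
                    CellCounts(
                        slide_id=f"{label}_{c}_{t}_s{k + 1}",
                        treatment=label, concentration=c, exposure_h=t,
                        total_cells=config.cells_per_slide,
                        dividing_cells=tcd, aberrations=ab,
                    )
                )
    return slides, truth


def simulate_band_matrix(config: SimulationConfig) -> tuple[BandMatrix, GroundTruth]:
    """One primer's loci x samples presence/absence matrix.

    Samples: negative control, single treatments at each nonzero
    concentration, positive control, combined treatments.  Molecular weights
    are log-uniform in [193, 3076] bp, sorted descending.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_BANDS])
    pool = config.band_pool_size
    weights = np.sort(np.exp(rng.uniform(np.log(193.0), np.log(3076.0), pool)))[::-1]
    control_loci = np.zeros(pool, dtype=np.uint8)
    control_loci[rng.choice(pool, config.control_band_count, replace=False)] = 1

    nonzero = [c for c in config.concentrations if c > 0]
    samples: list[tuple[str, float, float]] = []  # (id, concentration, multiplier)
    samples.append(("neg_control", 0.0, 1.0))
    samples += [(f"single_{c:g}", c, 1.0) for c in nonzero]
    samples.append(("pos_control", config.positive_control_concentration,
                    config.positive_control_multiplier))
    samples += [(f"combined_{c:g}", c, 1.0) for c in nonzero]

    truth = GroundTruth(
        true_ec50=(0.5 / config.inhibition_slope) if config.inhibition_slope > 0 else math.inf
    )
    cols = []
    for sid, c, m in samples:
        if sid == "neg_control":
            cols.append(control_loci.copy())
            truth.expected_lost_bands[sid] = 0.0
            truth.expected_gained_bands[sid] = 0.0
            continue
        p_loss = 1.0 - math.exp(-config.loss_rate * c * m)
        p_gain = 1.0 - math.exp(-config.gain_rate * c * m)
        col = control_loci.copy()
        for i in range(pool):
            if control_loci[i]:
                if rng.random() < p_loss:
                    col[i] = 0
            elif rng.random() < p_gain:
                col[i] = 1
        cols.append(col)
        truth.expected_lost_bands[sid] = config.control_band_count * p_loss
        truth.expected_gained_bands[sid] = (pool - config.control_band_count) * p_gain

    matrix = BandMatrix(
        primer="synthetic",
        weights_bp=weights,
        sample_ids=[s[0] for s in samples],
        presence=np.column_stack(cols),
    )
    return matrix, truth
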