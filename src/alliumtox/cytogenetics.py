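"""Cytogenetic endpoints of the Allium cepa assay.

Per slide, a fixed number of meristem cells is scored into non-dividing,
dividing, and aberrant categories.  Endpoints:

* mitotic index       MI  = 100 * dividing / total            (cytotoxicity)
* aberration percent  CA  = 100 * aberrant / total            (genotoxicity)
* mutation frequency  MF  = (100 * aberrant / total) / MI = CA / MI
  (damage normalised per unit of division activity)
* mutagenicity inhibition, for a co-treatment against a positive control:
  100 * (a - b) / (a - c) with a = positive-control CA, b = co-treatment CA,
  c = negative-control CA; classified insignificant (<25 %), moderate
  (25-40 %), strong (>40 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ABERRATION_CATEGORIES = (
    "micronucleus",
    "c_metaphase",
    "disturbance",
    "vagrant",
    "stickiness",
    "bridge",
)

INHIBITION_CLASSES = ("insignificant", "moderate", "strong")


@dataclass(frozen=True)
class CellCounts:
    """Per-slide cytogenetic tallies: total, dividing, aberrations by category."""

    slide_id: str
    treatment: str
    concentration: float
    exposure_h: float
    total_cells: int
    dividing_cells: int
    aberrations: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_cells < 0 or self.dividing_cells < 0:
            raise ValueError("counts must be non-negative")
        if self.dividing_cells > self.total_cells:
            raise ValueError("dividing cells exceed total cells")
        unknown = set(self.aberrations) - set(ABERRATION_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown aberration categories: {sorted(unknown)}")
        if any(v < 0 for v in self.aberrations.values()):
            raise ValueError("aberration counts must be non-negative")
        if self.total_aberrations > self.total_cells:
            raise ValueError("aberrant cells exceed total cells")

    @property
    def total_aberrations(self) -> int:
        return int(sum(self.aberrations.values()))

    def group_key(self) -> tuple[str, float, float]:
        return (self.treatment, self.concentration, self.exposure_h)


def mitotic_index(counts: CellCounts) -> float:
    """MI % = 100 * dividing / total."""
    if counts.total_cells == 0:
        raise ValueError("total cell count is zero")
    return 100.0 * counts.dividing_cells / counts.total_cells


def ca_percent(counts: CellCounts) -> float:
    """CA % = 100 * (sum of aberration counts) / total."""
    if counts.total_cells == 0:
        raise ValueError("total cell count is zero")
    return 100.0 * counts.total_aberrations / counts.total_cells


def mutation_frequency(counts: CellCounts) -> float:
    """MF = (100 * aberrant / total) / MI; algebraically CA% / MI.

    Undefined (raises) when no dividing cells were scored.
    """
    mi = mitotic_index(counts)
    if mi == 0:
        raise ValueError("mutation frequency undefined: mitotic index is zero")
    return (100.0 * counts.total_aberrations / counts.total_cells) / mi


def classify_inhibition(percent: float) -> str:
    # 25 and 40 are inclusive to "moderate".
    if percent < 25.0:
        return "insignificant"
    if percent <= 40.0:
        return "moderate"
    return "strong"


@dataclass(frozen=True)
class InhibitionResult:
    inhibition: float  # %
    classification: str


def mutagenicity_inhibition(ca_pos: float, ca_trt: float, ca_neg: float) -> InhibitionResult:
    """Antimutagenicity of a co-treatment: 100 * (a - b) / (a - c).

    a = positive-control CA%, b = co-treatment CA%, c = negative-control CA%.
    0 % means no improvement over the mutagen alone; 100 % means damage fully
    restored to the negative-control level.  Requires a > c (a mutagenic
    signal to inhibit).
    """
    if ca_pos <= ca_neg:
        raise ValueError(
            "inhibition undefined: positive-control CA must exceed negative-control CA"
        )
    pct = 100.0 * (ca_pos - ca_trt) / (ca_pos - ca_neg)
    return InhibitionResult(inhibition=pct, classification=classify_inhibition(pct))


def _pool(slides: list[CellCounts]) -> CellCounts:
    ab: dict[str, int] = {}
    for s in slides:
        for k, v in s.aberrations.items():
            ab[k] = ab.get(k, 0) + int(v)
    first = slides[0]
    return CellCounts(
        slide_id="pooled",
        treatment=first.treatment,
        concentration=first.concentration,
        exposure_h=first.exposure_h,
        total_cells=sum(s.total_cells for s in slides),
        dividing_cells=sum(s.dividing_cells for s in slides),
        aberrations=ab,
    )


def aggregate_endpoints(
    slides: Iterable[CellCounts], mode: str = "per_slide"
) -> pd.DataFrame:
    """Per-group endpoint table (MI, CA, MF with dispersion across slides).

    ``mode="per_slide"`` (default) computes each endpoint per slide and then
    the mean and sample SD across slides, mirroring how replicate slides are
    summarised in practice.  ``mode="pooled"`` sums counts over slides first
    and reports single pooled values (SD columns are NaN).  A group with one
    slide reports SD as missing.
    """
    if mode not in ("per_slide", "pooled"):
        raise ValueError("mode must be 'per_slide' or 'pooled'")
    groups: dict[tuple, list[CellCounts]] = {}
    for s in slides:
        groups.setdefault(s.group_key(), []).append(s)
    if not groups:
        raise ValueError("no slides provided")
    rows = []
    for (treatment, conc, exp), members in sorted(groups.items()):
        if mode == "pooled":
            pooled = _pool(members)
            mi, ca = mitotic_index(pooled), ca_percent(pooled)
            mf = mutation_frequency(pooled) if pooled.dividing_cells else np.nan
            rows.append(
                (treatment, conc, exp, len(members), pooled.total_cells,
                 pooled.dividing_cells, mi, np.nan, ca, np.nan, mf, np.nan)
            )
        else:
            mis = np.array([mitotic_index(s) for s in members])
            cas = np.array([ca_percent(s) for s in members])
            mfs = np.array(
                [mutation_frequency(s) if s.dividing_cells else np.nan for s in members]
            )
            sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else np.nan
            rows.append(
                (treatment, conc, exp, len(members),
                 sum(s.total_cells for s in members),
                 sum(s.dividing_cells for s in members),
                 float(mis.mean()), sd(mis), float(cas.mean()), sd(cas),
                 float(np.nanmean(mfs)), sd(mfs))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "treatment", "concentration", "exposure_h", "n_slides",
            "tcc", "tcd", "mi_percent", "mi_sd", "ca_percent", "ca_sd", "mf", "mf_sd",
        ],
    )
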