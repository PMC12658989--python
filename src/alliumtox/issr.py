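"""ISSR dominant-marker band-profile analysis.

An ISSR gel is scored as a binary loci x samples presence/absence matrix with
one negative-control lane.  Treatment-induced genomic instability shows up as
bands lost from, or gained relative to, the control profile.  The per-sample
polymorphism statistic used here is the Jaccard distance between control and
sample band sets expressed as a percentage:

    polymorphism % = 100 * (|lost| + |gained|) / |bands(control) u bands(sample)|

and the per-primer total polymorphism is the fraction of non-monomorphic loci.
Samples are clustered by UPGMA (average linkage) on pairwise band-set
distances, yielding an ultrametric tree in Newick form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

ROLES = ("negative_control", "single", "positive_control", "combined")

_SAMPLE_NAME_RE = re.compile(r"^(single|combined)_([0-9.]+)$")


def role_of(sample_id: str) -> tuple[str, float | None]:
    """Parse the role (and concentration, if any) from a sample column name.

    Convention: ``neg_control``, ``pos_control``, ``single_<c>``, ``combined_<c>``.
    """
    if sample_id == "neg_control":
        return "negative_control", None
    if sample_id == "pos_control":
        return "positive_control", None
    m = _SAMPLE_NAME_RE.match(sample_id)
    if m:
        return m.group(1), float(m.group(2))
    raise ValueError(f"cannot parse sample role from column name {sample_id!r}")


@dataclass
class BandMatrix:
    """Binary loci x samples ISSR profile with molecular weights and roles."""

    primer: str
    weights_bp: np.ndarray  # (n_loci,)
    sample_ids: list[str]
    presence: np.ndarray  # (n_loci, n_samples), values in {0, 1}
    locus_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights_bp = np.asarray(self.weights_bp, dtype=float)
        self.presence = np.asarray(self.presence)
        if not self.locus_ids:
            self.locus_ids = list(range(1, len(self.weights_bp) + 1))
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus indices")
        if self.presence.shape != (len(self.weights_bp), len(self.sample_ids)):
            raise ValueError("presence matrix shape does not match loci/samples")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0 or 1")
        if (self.weights_bp <= 0).any():
            raise ValueError("molecular weights must be > 0")
        roles = [role_of(s)[0] for s in self.sample_ids]
        if roles.count("negative_control") != 1:
            raise ValueError("exactly one negative-control sample is required")
        self.presence = self.presence.astype(np.uint8)

    @property
    def n_loci(self) -> int:
        return len(self.weights_bp)

    @property
    def control_id(self) -> str:
        return next(s for s in self.sample_ids if role_of(s)[0] == "negative_control")

    def column(self, sample_id: str) -> np.ndarray:
        return self.presence[:, self.sample_ids.index(sample_id)]

    def band_set(self, sample_id: str) -> frozenset[int]:
        col = self.column(sample_id)
        return frozenset(lid for lid, v in zip(self.locus_ids, col) if v)


def classify_bands(matrix: BandMatrix) -> list[str]:
    """Per-locus label: monomorphic (all samples), unique (exactly one),
    polymorphic (some but not all), absent (no sample — degenerate, flagged)."""
    if matrix.n_loci == 0:
        raise ValueError("empty band matrix")
    n = len(matrix.sample_ids)
    labels = []
    for row in matrix.presence:
        k = int(row.sum())
        if k == 0:
            labels.append("absent")
        elif k == n:
            labels.append("monomorphic")
        elif k == 1:
            labels.append("unique")
        else:
            labels.append("polymorphic")
    return labels


@dataclass(frozen=True)
class SampleDivergence:
    """Band changes of one sample relative to the negative control."""

    sample_id: str
    lost: tuple[tuple[int, float], ...]  # (locus, weight_bp) present in control only
    gained: tuple[tuple[int, float], ...]  # present in sample only
    percent: float  # 100 * Jaccard distance control vs sample


def polymorphism_vs_control(matrix: BandMatrix, sample_id: str) -> SampleDivergence:
    """Lost/gained bands and polymorphism % of a sample against the control."""
    control_id = matrix.control_id
    if sample_id == control_id:
        raise ValueError("sample must differ from the negative control")
    ctrl = matrix.band_set(control_id)
    samp = matrix.band_set(sample_id)
    union = ctrl | samp
    if not union:
        raise ValueError("polymorphism undefined: both band sets are empty")
    weights = dict(zip(matrix.locus_ids, matrix.weights_bp))
    lost = tuple((lid, weights[lid]) for lid in sorted(ctrl - samp))
    gained = tuple((lid, weights[lid]) for lid in sorted(samp - ctrl))
    pct = 100.0 * (len(lost) + len(gained)) / len(union)
    return SampleDivergence(sample_id=sample_id, lost=lost, gained=gained, percent=pct)


def total_polymorphism(matrix: BandMatrix) -> float:
    """Percent of loci that are not monomorphic across all samples."""
    labels = classify_bands(matrix)
    non_mono = sum(1 for lb in labels if lb != "monomorphic")
    return 100.0 * non_mono / matrix.n_loci


def polymorphism_report(matrix: BandMatrix) -> pd.DataFrame:
    """Per-sample polymorphism table (control row included at 0 %)."""
    rows = []
    for sid in matrix.sample_ids:
        if sid == matrix.control_id:
            rows.append((matrix.primer, sid, 0, 0, 0.0))
            continue
        div = polymorphism_vs_control(matrix, sid)
        rows.append((matrix.primer, sid, len(div.lost), len(div.gained), div.percent))
    return pd.DataFrame(
        rows, columns=["primer", "sample", "n_lost", "n_gained", "polymorphism_percent"]
    )


_METRICS = ("jaccard", "dice", "simple_matching")


def distance_matrix(matrix: BandMatrix, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise sample x sample distances on the binary band profiles.

    ``jaccard`` (default) is consistent with the polymorphism statistic:
    control-vs-sample jaccard distance * 100 equals that sample's
    polymorphism %.  ``simple_matching`` is the Hamming proportion.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least two samples")
    cols = matrix.presence.T.astype(bool)
    if metric == "jaccard" and (~cols.any(axis=1)).any():
        raise ValueError("jaccard distance undefined for an all-empty sample")
    scipy_metric = {"jaccard": "jaccard", "dice": "dice", "simple_matching": "hamming"}[metric]
    from scipy.spatial.distance import pdist

    d = squareform(pdist(cols, metric=scipy_metric))
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


@dataclass
class UpgmaTree:
    """UPGMA result: scipy linkage, leaf labels, and the Newick rendering."""

    linkage: np.ndarray
    labels: list[str]
    newick: str

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf (equal for an ultrametric tree)."""
        root = hierarchy.to_tree(self.linkage)
        depths: dict[str, float] = {}

        def walk(node, acc: float) -> None:
            h = 0.0 if node.is_leaf() else node.dist / 2.0
            if node.is_leaf():
                depths[self.labels[node.id]] = acc
                return
            for child in (node.left, node.right):
                ch = 0.0 if child.is_leaf() else child.dist / 2.0
                walk(child, acc + (h - ch))

        walk(root, 0.0)
        return depths


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    h = node.dist / 2.0
    parts = []
    for child in (node.left, node.right):
        ch = 0.0 if child.is_leaf() else child.dist / 2.0
        parts.append(f"{_newick(child, labels)}:{h - ch:.10g}")
    return "(" + ",".join(parts) + ")"


def upgma(distances: pd.DataFrame) -> UpgmaTree:
    """Average-linkage (UPGMA) agglomeration of a symmetric distance matrix.

    Branch lengths place every merge at half its cophenetic distance, so the
    tree is ultrametric.  Output is deterministic for a given input matrix.
    """
    d = np.asarray(distances, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = list(distances.index)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    newick = _newick(hierarchy.to_tree(link), labels) + ";"
    return UpgmaTree(linkage=link, labels=labels, newick=newick)


def read_band_matrix(path: str | Path, primer: str | None = None) -> BandMatrix:
    """Read a band-matrix CSV: ``locus``(optional), ``weight_bp``, one column
    per sample (role encoded in the column name), optional trailing
    annotation columns (ignored)."""
    df = pd.read_csv(path)
    if "weight_bp" not in df.columns:
        raise ValueError("band matrix CSV requires a 'weight_bp' column")
    locus_ids = (
        df["locus"].astype(int).tolist() if "locus" in df.columns else []
    )
    sample_cols = []
    for col in df.columns:
        if col in ("locus", "weight_bp"):
            continue
        try:
            role_of(col)
        except ValueError:
            continue  # annotation column (e.g. printed band type)
        sample_cols.append(col)
    if not sample_cols:
        raise ValueError("no sample columns found")
    vals = df[sample_cols].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("non-binary presence entries in band matrix")
    return BandMatrix(
        primer=primer or Path(path).stem,
        weights_bp=df["weight_bp"].to_numpy(float),
        sample_ids=sample_cols,
        presence=vals,
        locus_ids=locus_ids,
    )


def write_band_matrix(matrix: BandMatrix, path: str | Path) -> None:
    df = pd.DataFrame({"locus": matrix.locus_ids, "weight_bp": matrix.weights_bp})
    for j, sid in enumerate(matrix.sample_ids):
        df[sid] = matrix.presence[:, j]
    df.to_csv(path, index=False)
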