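"""End-to-end orchestration: simulate -> EC50 -> cytogenetics -> ISSR -> stats.

``run_pipeline`` executes the whole analysis on a simulated assay and writes
a report bundle (CSV/JSON/Newick plus a manifest with seed, config hash and
package version) so a run can be reproduced bit-identically from its
manifest.  ``reproduce_published`` replays the analysis layer on the bundled
printed tables instead and reports recomputed-vs-printed agreement.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cytogenetics as cyto
from . import published
from .doseresponse import (
    derive_test_concentrations,
    fit_ec50_from_records,
    records_to_frame,
    summarize_root_growth,
)
from .issr import distance_matrix, polymorphism_report, upgma, write_band_matrix
from .simulate import SimulationConfig, simulate_band_matrix, simulate_cell_counts, simulate_root_growth
from .stats import anova_with_interaction, assumption_checks, correlation_matrix

log = logging.getLogger("alliumtox")


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "alliumtox_run"
    alpha: float = 0.05
    distance_metric: str = "jaccard"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed

    def identity(self) -> dict:
        # The output path is not part of a run's scientific identity: two runs
        # with the same seed and parameters must produce identical bundles.
        d = {k: v for k, v in asdict(self).items() if k not in ("simulation", "output_dir")}
        d["simulation"] = asdict(self.simulation)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.identity(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on simulated data and write the report bundle.

    Returns the in-memory report dict; stage failures propagate with the
    failing stage named in the log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    report: dict = {}

    log.info("stage 1/4: root growth and EC50")
    records, root_truth = simulate_root_growth(sim)
    roots = records_to_frame(records)
    roots.to_csv(out / "root_growth.csv", index=False)
    summarize_root_growth(roots).to_csv(out / "root_growth_summary.csv", index=False)
    fit = fit_ec50_from_records(roots, exposure_h=sim.exposures_h[0])
    derived = derive_test_concentrations(fit.ec50) if fit.ec50 else None
    report["dose_response"] = {
        "slope": fit.slope, "intercept": fit.intercept, "r_squared": fit.r_squared,
        "ec50_mg_ml": fit.ec50, "true_ec50_mg_ml": root_truth.true_ec50,
        "derived_concentrations": asdict(derived) if derived else None,
    }
    _write_json(out / "dose_response.json", report["dose_response"])

    log.info("stage 2/4: cytogenetic endpoints and ANOVA")
    slides, cell_truth = simulate_cell_counts(sim, include_positive_control=True)
    endpoints = cyto.aggregate_endpoints(slides)
    endpoints.to_csv(out / "endpoints.csv", index=False)
    per_slide = pd.DataFrame(
        {
            "slide_id": [s.slide_id for s in slides],
            "treatment": [s.treatment for s in slides],
            "concentration": [s.concentration for s in slides],
            "exposure_h": [s.exposure_h for s in slides],
            "mi_percent": [cyto.mitotic_index(s) for s in slides],
            "ca_percent": [cyto.ca_percent(s) for s in slides],
        }
    )
    single = per_slide[per_slide["treatment"].isin(["negative_control", "single"])]
    anova = anova_with_interaction(single, "mi_percent", alpha=config.alpha)
    checks = assumption_checks(single, "mi_percent")
    anova.tukey.to_csv(out / "tukey_mi.csv", index=False)
    report["anova_mi"] = {
        "table": anova.anova_table.to_dict(),
        "letters": anova.letters,
        "levene_p": checks.levene_p,
        "shapiro_p": checks.shapiro_p,
    }
    # Mutagenicity inhibition of each combined concentration (here the
    # positive-control truth drives the simulated slides).
    pos = endpoints[endpoints["treatment"] == "positive_control"]
    neg = endpoints[endpoints["treatment"] == "negative_control"]
    report["endpoint_truth"] = {
        "true_mi_percent": {f"{c}|{t}": v for (c, t), v in cell_truth.true_mi_percent.items()},
        "n_pos_control_groups": int(len(pos)),
        "n_neg_control_groups": int(len(neg)),
    }

    log.info("stage 3/4: ISSR band matrix, polymorphism, UPGMA")
    matrix, band_truth = simulate_band_matrix(sim)
    write_band_matrix(matrix, out / "band_matrix.csv")
    poly = polymorphism_report(matrix)
    poly.to_csv(out / "polymorphism.csv", index=False)
    dist = distance_matrix(matrix, metric=config.distance_metric)
    dist.to_csv(out / "distances.csv")
    tree = upgma(dist)
    (out / "upgma.nwk").write_text(tree.newick + "\n")
    report["issr"] = {
        "polymorphism_percent": dict(zip(poly["sample"], poly["polymorphism_percent"])),
        "expected_lost": band_truth.expected_lost_bands,
        "expected_gained": band_truth.expected_gained_bands,
        "newick": tree.newick,
    }

    log.info("stage 4/4: correlations")
    e48 = sim.exposures_h[1] if len(sim.exposures_h) > 1 else sim.exposures_h[0]
    single_rows = endpoints[
        (endpoints["treatment"] == "single") & (endpoints["exposure_h"] == e48)
    ].sort_values("concentration")
    root_means = (
        roots[(roots["treatment"] == "single") & (roots["exposure_h"] == e48)]
        .groupby("concentration")["length_mm"].mean()
    )
    poly_single = poly[poly["sample"].str.startswith("single_")].copy()
    poly_single["concentration"] = [
        float(s.split("_", 1)[1]) for s in poly_single["sample"]
    ]
    endpoint_table = pd.DataFrame(
        {
            "root_length": single_rows["concentration"].map(root_means).to_numpy(),
            "mi": single_rows["mi_percent"].to_numpy(),
            "ca": single_rows["ca_percent"].to_numpy(),
            "mf": single_rows["mf"].to_numpy(),
            "polymorphism": single_rows["concentration"]
            .map(poly_single.set_index("concentration")["polymorphism_percent"])
            .to_numpy(),
        }
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # n=3 low-power warning is expected here
        corr = correlation_matrix(endpoint_table, alpha=config.alpha)
    corr.to_csv(out / "correlations.csv", index=False)
    report["correlations"] = corr.to_dict(orient="records")

    manifest = {
        "package": "alliumtox",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "run_config": config.identity(),
    }
    _write_json(out / "manifest.json", manifest)
    report["manifest"] = manifest
    _write_json(out / "report.json", report)
    return report


def reproduce_published(output_dir: str | Path | None = None) -> dict:
    """Replay the analysis layer on the bundled printed tables.

    Recomputes MI from printed counts, MF from printed CA/MI, the 48 h
    mutagenicity-inhibition column, and every per-primer polymorphism
    percentage; reports the worst absolute deviation from print for each,
    plus the known irreproducible entries.
    """
    report: dict = {"known_discrepancies": {
        f"{k[0]}:{k[1]}": v for k, v in published.KNOWN_DISCREPANCIES.items()
    }}

    single = published.load_cytogenetic_table("single")
    combined = published.load_cytogenetic_table("combined")
    for name, table in (("single", single), ("combined", combined)):
        mi_err = (published.recompute_mitotic_index(table) - table["mi_percent"]).abs()
        mf_err = (published.recompute_mutation_frequency(table) - table["mf"]).abs()
        report[f"cytogenetics_{name}"] = {
            "n_rows": int(len(table)),
            "mi_max_abs_error": float(mi_err.max()),
            "mf_max_abs_error": float(mf_err.max()),
        }

    inh = published.recompute_inhibition_column(exposure_h=48)
    report["inhibition_48h"] = {
        f"{row.concentration_mg_ml:g}": {
            "computed": round(float(row.inhibition), 4),
            "printed": float(row.printed),
            "classification": row.classification,
        }
        for row in inh.itertuples()
    }

    poly_err = []
    report["issr"] = {}
    for primer in published.PRIMERS:
        table = published.recompute_polymorphism(primer)
        per_sample = table[table["sample"] != "total"]
        err = (per_sample["polymorphism_percent"] - per_sample["printed"]).abs()
        poly_err.extend(err.tolist())
        total_row = table[table["sample"] == "total"].iloc[0]
        report["issr"][primer] = {
            "per_sample_max_abs_error": float(err.max()),
            "total_computed": float(total_row["polymorphism_percent"]),
            "total_printed": float(total_row["printed"]),
        }
    report["issr"]["per_sample_values_checked"] = len(poly_err)
    report["issr"]["max_abs_error_all_primers"] = float(max(poly_err))

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(out / "reproduce_report.json", report)
        for primer in published.PRIMERS:
            published.recompute_polymorphism(primer).to_csv(
                out / f"polymorphism_{primer.lower().replace('-', '')}.csv", index=False
            )
    return report
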