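"""End-to-end orchestration: simulate/load -> preprocess -> analyse -> export.

``run_pipeline`` executes the full analysis order on one study: pollution
variables, OTU preprocessing (contaminant + rare filtering, rarefaction),
diversity and Bray–Curtis dissimilarities, the gradient analysis per marker
and colonization status, chemistry summaries, the LC–HRMS filter cascade,
the harmonized variable table, and the association network.  Every artifact
is written with a provenance sidecar (package version, seed, thresholds,
config hash), so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import chem, io, network, ordination, otu, simulate

log = logging.getLogger("habitatlink")

__all__ = ["PipelineConfig", "run_pipeline", "harmonized_variable_table", "config_hash"]


@dataclass
class PipelineConfig:
    """Thresholds, depths and seeds of one pipeline run."""

    output_dir: str = "habitatlink_out"
    seed: int = 0
    # preprocessing
    contaminant_factor: float = 10.0
    rare_fraction: float = 0.00005  # 0.005 %
    rarefaction_depths: dict = field(
        default_factory=lambda: {"16S": 4103, "ITS": 6567, "18S": 7204}
    )
    # feature cascade
    cv_max: float = 30.0
    blank_ratio: float = 10.0
    alpha: float = 0.05
    # ordination
    n_perm: int = 999
    # network
    z_threshold: float = network.DEFAULT_Z_THRESHOLD
    zhang_min: float = 0.25
    # synthetic-study generation (used when no input files are given)
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim:
            cfg.simulation = simulate.SimulationConfig(**sim)
        return cfg

    def validate(self) -> None:
        if not 0 <= self.rare_fraction <= 1:
            raise ValueError("rare_fraction must be in [0, 1]")
        if self.contaminant_factor <= 0 or self.cv_max <= 0 or self.blank_ratio <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic stages")


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def harmonized_variable_table(
    samples: pd.DataFrame,
    otu_tables: dict,
    feature_matrix=None,
    retained_features=None,
    top_otus: int = 30,
) -> tuple[pd.DataFrame, pd.Series]:
    """One samples x variables table mixing chemistry, OTUs and features.

    Chemistry columns come straight from the per-sample table; the
    ``top_otus`` most abundant OTUs of each marker enter as relative
    abundances; retained LC–HRMS features enter as per-sample mean
    intensities.  Returns the table and a per-variable kind label
    (physicochemical / bacteria / fungi / eukaryote / organic molecule).
    """
    kind_of_marker = {"16S": "bacteria", "ITS": "fungi", "18S": "eukaryote"}
    sam = samples.set_index("sample_id")
    numeric = sam.select_dtypes("number")
    table = numeric.copy()
    kinds = {c: "physicochemical" for c in numeric.columns}
    for marker, t in otu_tables.items():
        rel = t.relative_abundance()
        top = rel.sum(axis=1).sort_values(ascending=False).index[:top_otus]
        block = rel.loc[top].T.reindex(table.index)
        for c in block.columns:
            kinds[c] = kind_of_marker.get(marker, "unknown")
        table = table.join(block)
    if feature_matrix is not None and retained_features:
        inj = feature_matrix.injections
        study = feature_matrix.intensities[
            [c for c in feature_matrix.intensities.columns if inj.loc[c, "role"] == "study"]
        ]
        per_sample = study.T.groupby(inj.loc[study.columns, "sample_id"]).mean().T
        block = per_sample.loc[list(retained_features)].T.reindex(table.index)
        for c in block.columns:
            kinds[c] = "organic molecule"
        table = table.join(block)
    return table, pd.Series(kinds)


def _write_with_provenance(df: pd.DataFrame, path: Path, meta: dict) -> None:
    df.to_csv(path)
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def run_pipeline(config: PipelineConfig, study: dict | None = None) -> dict:
    """Run the full chain on a (by default simulated) study; write artifacts.

    Returns a dict of in-memory results; artifacts land in
    ``config.output_dir``.  A stage failure raises with the stage name and
    leaves earlier artifacts in place.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "thresholds": {
            "contaminant_factor": config.contaminant_factor,
            "rare_fraction": config.rare_fraction,
            "cv_max": config.cv_max,
            "blank_ratio": config.blank_ratio,
            "alpha": config.alpha,
            "z_threshold": config.z_threshold,
            "zhang_min": config.zhang_min,
        },
    }
    results: dict = {"meta": meta}
    stage = "simulate"
    try:
        if study is None:
            study = simulate.simulate_study(config.simulation, seed=config.seed)
        gardens, samples = study["gardens"], study["samples"]

        stage = "pollution"
        from .pollution import pollution_variables

        pv = pollution_variables(gardens)
        results["pollution"] = pv
        _write_with_provenance(pv.set_index("garden_id"), outdir / "pollution_variables.csv", meta)

        stage = "otu_preprocessing"
        processed: dict = {}
        diversity_frames = []
        for marker, (table, truth) in study["otu_tables"].items():
            neg_ids = [s for s in table.sample_ids
                       if table.sample_meta is not None
                       and table.sample_meta.loc[s, "sample_type"] == "NEG"]
            t = otu.filter_contaminants(table, neg_ids) if neg_ids else table
            t = otu.filter_rare(t, config.rare_fraction)
            t = otu.rarefy(t, config.rarefaction_depths[marker], seed=config.seed)
            processed[marker] = t
            io.write_otu_tsv(t, outdir / f"otu_{marker}_processed.tsv")
            div = otu.alpha_diversity(t)
            div["marker"] = marker
            diversity_frames.append(div)
        results["otu_tables"] = processed
        diversity = pd.concat(diversity_frames)
        results["diversity"] = diversity
        _write_with_provenance(diversity, outdir / "alpha_diversity.csv", meta)

        stage = "gradient_analysis"
        abiotic_cols = ["temperature_c", "ph", "dissolved_o2_mg_l", "gas_o2_pct",
                        "n2o_ppmv", "ch4_ppmv", "co2_ppmv", "toc_mg_l"]
        grad_reports: dict = {}
        for marker, t in processed.items():
            dist = otu.bray_curtis(t)
            io.write_distance_tsv(dist, outdir / f"bray_curtis_{marker}.tsv")
            for status in ("NC", "C"):
                ids = [s for s in t.sample_ids if s.endswith(f"_{status}")]
                if len(ids) < 5:
                    continue
                sub = t.subset_samples(ids)
                ab = samples.set_index("sample_id").loc[ids, abiotic_cols]
                ab = ab.join(pv.set_index("garden_id")
                             .loc[[s.rsplit("_", 1)[0] for s in ids],
                                  ["var_atmo", "var_agri", "var_indus"]]
                             .set_index(pd.Index(ids)))
                rep = ordination.gradient_analysis(
                    otu.bray_curtis(sub), ab, sub.counts.T,
                    n_perm=config.n_perm, seed=config.seed,
                )
                grad_reports[f"{marker}_{status}"] = rep
        results["gradient"] = grad_reports
        summary = {
            key: {ax: {"R2": rep["permanova"].r2(ax), "p": rep["permanova"].p(ax)}
                  for ax in rep["axes"]}
            for key, rep in grad_reports.items()
        }
        (outdir / "gradient_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

        stage = "chemistry"
        chem_summary = chem.summarize(
            samples, ["n2o_ppmv", "ch4_ppmv", "temperature_c", "ph"], group="status"
        )
        results["chem_summary"] = chem_summary
        _write_with_provenance(chem_summary, outdir / "chem_summary.csv", meta)

        stage = "feature_cascade"
        cascade = chem.filter_cascade(
            study["features"], istd_feature="ISTD",
            cv_max=config.cv_max, blank_ratio=config.blank_ratio, alpha=config.alpha,
        )
        results["cascade"] = cascade
        (outdir / "feature_cascade_audit.json").write_text(
            json.dumps({"audit": cascade.audit,
                        "dropped_at": cascade.dropped_at.to_dict(),
                        **meta}, indent=2, sort_keys=True)
        )

        stage = "association_network"
        var_table, kinds = harmonized_variable_table(
            samples, processed, study["features"], cascade.retained
        )
        binary, audit = network.exceptionality_matrix(var_table, threshold=config.z_threshold)
        status_indicator = (samples.set_index("sample_id")["status"] == "C").astype(float)
        binary["status_C"] = status_indicator.reindex(binary.index)
        kinds["status_C"] = "physicochemical"
        graph = network.build_network(binary, kinds=kinds,
                                      zhang_min=config.zhang_min, alpha=config.alpha)
        results["network"] = graph
        io.export_graphml(graph, outdir / "association_network.graphml")
        network.edge_table(graph).to_csv(outdir / "association_edges.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    log.info("pipeline complete: %s", outdir)
    return results
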