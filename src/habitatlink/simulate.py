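"""Synthetic paired colonized/noncolonized study datasets with known truth.

Generates the complete input universe of the pipeline — garden pollution
geometry, paired NC/C water chemistry, per-marker OTU count tables with a
planted pollution gradient and seeded contaminants, LC–HRMS feature matrices
with triplicate injections, pooled QCs and blanks, and harmonized variable
tables with planted associations — so every stage can be tested end to end
with ground truth and no external downloads.

Default shapes mirror the field survey: 23 gardens, one noncolonized and one
colonized container each, three markers rarefied at 4103 (16S), 6567 (ITS)
and 7204 (18S) reads, triplicate injections per water sample.  N2O and CH4
are generated with noncolonized-over-colonized mean ratios of 2 and 6; all
other chemistry is colonization-neutral.  Concentrations are lognormal
(positive, right-skewed, as observed in container water).

Every generator is a pure function of (config, seed): reruns are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable
from .chem import FeatureMatrix
from .pollution import quartile_scores, pollution_variables

__all__ = [
    "SimulationConfig",
    "MarkerConfig",
    "simulate_gardens",
    "simulate_chemistry",
    "simulate_otu_table",
    "simulate_features",
    "plant_associations",
    "simulate_study",
]


@dataclass(frozen=True)
class MarkerConfig:
    """Per-marker richness, rarefaction depth and overdispersion.

    ``depth`` is the downstream rarefaction target; raw per-sample sequencing
    depths are drawn uniformly from ``depth_factor_range`` times ``depth`` so
    preprocessing losses never push samples below the target.
    """

    depth: int
    richness: int
    dirichlet_concentration: float = 500.0  # total; lower = more overdispersed
    depth_factor_range: tuple = (1.5, 2.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the field survey."""

    n_gardens: int = 23
    # chemistry status effects: NC mean over C mean
    n2o_nc_over_c: float = 2.0
    ch4_nc_over_c: float = 6.0
    chem_sigma: float = 0.8  # lognormal shape of concentrations
    # pollution gradient planted in the OTU tables
    planted_otu_fraction: float = 0.3
    gradient_slope: float = 1.0
    gradient_variable: str = "var_indus"
    markers: dict = field(
        default_factory=lambda: {
            "16S": MarkerConfig(depth=4103, richness=400),
            "ITS": MarkerConfig(depth=6567, richness=300),
            "18S": MarkerConfig(depth=7204, richness=300),
        }
    )
    n_contaminant_otus: int = 5
    # LC-HRMS features
    n_real_features: int = 20
    n_artifact_features: int = 80
    n_qc_injections: int = 5
    n_blank_injections: int = 3
    qc_cv_real: float = 0.05
    qc_cv_artifact: float = 0.6
    real_feature_fold: float = 4.0  # NC vs C intensity fold of real features
    # association planting
    n_association_variables: int = 60
    n_planted_pairs: int = 10
    joint_exceedance: float = 0.15
    # garden geometry bounds (m)
    distance_range: tuple = (10.0, 1.0e4)

    def validate(self) -> None:
        if self.n_gardens < 4:
            raise ValueError("n_gardens must be >= 4")
        for name in ("n2o_nc_over_c", "ch4_nc_over_c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("planted_otu_fraction", "joint_exceedance"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.distance_range
        if not 0 < lo < hi:
            raise ValueError("distance_range must satisfy 0 < lo < hi")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _loguniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_gardens(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Garden table: distances, emission-derived quartile scores, variables.

    Distances are log-uniform over ``config.distance_range``; emission levels
    for NO2/PM2.5/PM10 are lognormal and converted to quartile scores across
    the garden set; pollution groups are assigned from the largest normalized
    variable.  Returns one row per garden including raw and normalized
    pollution variables.
    """
    config.validate()
    rng = _rng(seed)
    n = config.n_gardens
    lo, hi = config.distance_range
    ids = [f"G{i + 1:02d}" for i in range(n)]
    g = pd.DataFrame(
        {
            "garden_id": ids,
            "d_highway": _loguniform(rng, lo, hi, n),
            "d_agri": _loguniform(rng, lo, hi, n),
            "d_indus": _loguniform(rng, lo, hi, n),
            "agri_surface": _loguniform(rng, 10.0, 2000.0, n),
        }
    )
    for pollutant in ("no2", "pm25", "pm10"):
        emissions = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        g[f"q_{pollutant}"] = quartile_scores(emissions)
    pv = pollution_variables(g)
    g = g.merge(pv, on="garden_id")
    norm = g[["var_agri_norm", "var_indus_norm", "var_atmo_norm"]].to_numpy()
    g["pollution_group"] = np.array(["AGRI", "INDUS", "ATMO"])[norm.argmax(axis=1)]
    return g


def simulate_chemistry(config: SimulationConfig, gardens: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Paired NC/C water samples with planted N2O and CH4 status effects.

    Concentrations are lognormal; for N2O and CH4 the noncolonized medians
    are multiplied by the configured NC:C ratios so the group means differ by
    those factors in expectation.  All other fields are status-neutral.
    """
    config.validate()
    rng = _rng(seed)
    # field -> (median at C, lognormal sigma, NC-over-C ratio)
    field_params = {
        "temperature_c": (21.0, 0.12, 1.0),
        "ph": (7.4, 0.05, 1.0),
        "dissolved_o2_mg_l": (6.0, 0.4, 1.0),
        "redox_mv": (200.0, 0.3, 1.0),
        "gas_o2_pct": (2.1, 0.3, 1.0),
        "gas_n2_pct": (5.0, 0.2, 1.0),
        "co2_ppmv": (2500.0, config.chem_sigma, 1.0),
        "toc_mg_l": (10.0, config.chem_sigma, 1.0),
        "n2o_ppmv": (0.5, config.chem_sigma, config.n2o_nc_over_c),
        "ch4_ppmv": (0.3, config.chem_sigma, config.ch4_nc_over_c),
    }
    containers = ["rainwater collector", "bucket", "watering can"]
    rows = []
    for _, garden in gardens.iterrows():
        for status in ("NC", "C"):
            row = {
                "sample_id": f"{garden['garden_id']}_{status}",
                "garden_id": garden["garden_id"],
                "status": status,
                "container_type": containers[rng.choice(3, p=[0.87, 0.09, 0.04])],
            }
            for fieldname, (median_c, sigma, ratio) in field_params.items():
                scale = ratio if status == "NC" else 1.0
                row[fieldname] = float(
                    scale * median_c * np.exp(rng.normal(0.0, sigma))
                )
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_otu_table(
    config: SimulationConfig,
    gardens: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    marker: str = "16S",
    seed=None,
) -> tuple[OtuTable, dict]:
    """Dirichlet-multinomial OTU counts with a planted pollution gradient.

    A ``planted_otu_fraction`` of OTUs has its log-abundance shifted linearly
    by the garden's standardized raw pollution variable
    (``config.gradient_variable``) scaled by ``gradient_slope``.  One
    negative extraction control (``NEG1``) carries the configured contaminant
    OTUs.  Returns the table and a truth dict (planted OTU ids, contaminant
    ids, per-sample gradient values).
    """
    config.validate()
    rng = _rng(seed)
    mc: MarkerConfig = config.markers[marker]
    if samples is None:
        samples = pd.DataFrame(
            {
                "sample_id": [
                    f"{gid}_{status}"
                    for gid in gardens["garden_id"]
                    for status in ("NC", "C")
                ],
                "garden_id": np.repeat(gardens["garden_id"].to_numpy(), 2),
                "status": ["NC", "C"] * len(gardens),
            }
        )
    grad = gardens.set_index("garden_id")[config.gradient_variable]
    grad_z = (grad - grad.mean()) / (grad.std(ddof=0) if grad.std(ddof=0) > 0 else 1.0)

    n_otus = mc.richness
    otu_ids = [f"{marker}_OTU{i + 1}" for i in range(n_otus)]
    base_log = rng.normal(0.0, 1.5, size=n_otus)
    n_planted = int(round(config.planted_otu_fraction * n_otus))
    planted = list(rng.choice(n_otus, size=n_planted, replace=False))

    lo_f, hi_f = mc.depth_factor_range
    depths = {}
    cols = {}
    for _, s in samples.iterrows():
        z = grad_z.loc[s["garden_id"]]
        log_ab = base_log.copy()
        log_ab[planted] += config.gradient_slope * z
        weights = np.exp(log_ab)
        p = rng.dirichlet(weights / weights.sum() * mc.dirichlet_concentration)
        depth = int(rng.integers(int(lo_f * mc.depth), int(hi_f * mc.depth) + 1))
        depths[s["sample_id"]] = depth
        cols[s["sample_id"]] = rng.multinomial(depth, p)

    # negative extraction control: a few contaminant OTUs at high abundance
    contaminants = [f"{marker}_CONT{i + 1}" for i in range(config.n_contaminant_otus)]
    neg = np.zeros(n_otus + len(contaminants), dtype=int)
    neg_counts = rng.multinomial(max(mc.depth // 4, 100), np.full(len(contaminants), 1.0 / len(contaminants)))
    neg[n_otus:] = neg_counts
    counts = pd.DataFrame(cols, index=otu_ids)
    # contaminants also leak weakly into study samples
    leak = rng.poisson(2.0, size=(len(contaminants), counts.shape[1]))
    counts = pd.concat([counts, pd.DataFrame(leak, index=contaminants, columns=counts.columns)])
    counts["NEG1"] = neg

    meta = samples.set_index("sample_id")[["garden_id", "status"]].rename(
        columns={"status": "sample_type"}
    )
    meta["marker"] = marker
    meta.loc["NEG1"] = {"garden_id": "none", "sample_type": "NEG", "marker": marker}
    truth = {
        "planted_otus": [otu_ids[i] for i in planted],
        "contaminants": contaminants,
        "depths": depths,
        "gradient": {s: float(grad_z.loc[g]) for s, g in zip(samples["sample_id"], samples["garden_id"])},
    }
    return OtuTable(counts, sample_meta=meta), truth


def simulate_features(
    config: SimulationConfig, samples: pd.DataFrame, seed=None
) -> tuple[FeatureMatrix, dict]:
    """LC–HRMS feature matrix with planted real features and rule-specific artifacts.

    Every water sample gets triplicate study injections; pooled QC and blank
    injections are appended.  ``n_real_features`` planted signals differ
    between NC and C by ``real_feature_fold`` and pass every filter stage.
    Artifacts violate exactly one cascade rule each, in equal shares:

    - ``qc_cv``: QC coefficient of variation far above the cutoff;
    - ``detection``: absent from one sample of every pollution group;
    - ``blank``: blank intensity at half the study mean (ratio <= 10);
    - ``ttest``: flat (identical in every study injection), hence no NC/C
      difference.

    Returns the matrix (including the internal-standard row ``ISTD``) and a
    truth dict mapping each feature to its class.
    """
    config.validate()
    rng = _rng(seed)
    sample_ids = list(samples["sample_id"])
    status = dict(zip(samples["sample_id"], samples["status"]))
    group = dict(zip(samples["sample_id"], samples.get("pollution_group", pd.Series(["AGRI"] * len(samples), index=samples.index))))

    inj_rows = []
    for sid in sample_ids:
        for r in (1, 2, 3):
            inj_rows.append(
                {
                    "injection_id": f"{sid}_r{r}",
                    "sample_id": sid,
                    "role": "study",
                    "replicate": r,
                    "status": status[sid],
                    "group": group[sid],
                }
            )
    for q in range(config.n_qc_injections):
        inj_rows.append(
            {"injection_id": f"QC{q + 1}", "sample_id": "QC", "role": "QC",
             "replicate": q + 1, "status": "none", "group": "none"}
        )
    for b in range(config.n_blank_injections):
        inj_rows.append(
            {"injection_id": f"BLANK{b + 1}", "sample_id": "BLANK", "role": "blank",
             "replicate": b + 1, "status": "none", "group": "none"}
        )
    injections = pd.DataFrame(inj_rows).set_index("injection_id")
    study_cols = injections.index[injections["role"] == "study"]
    qc_cols = injections.index[injections["role"] == "QC"]
    blank_cols = injections.index[injections["role"] == "blank"]

    classes = ["real"] * config.n_real_features
    artifact_kinds = ["qc_cv", "detection", "blank", "ttest"]
    for i in range(config.n_artifact_features):
        classes.append(artifact_kinds[i % 4])
    feature_ids = [f"M{100 + i}T{30 + 7 * i}" for i in range(len(classes))]
    truth = dict(zip(feature_ids, classes))

    groups_present = sorted({group[s] for s in sample_ids})
    drop_per_group = {g: rng.choice([s for s in sample_ids if group[s] == g]) for g in groups_present}

    # internal standard: per-injection spike level (injection effect); all
    # signals ride on it multiplicatively so normalization is meaningful
    istd_level = 5e4
    istd = pd.Series(
        np.exp(rng.normal(np.log(istd_level), 0.1, size=len(injections))),
        index=injections.index,
    )
    inj_effect = istd / istd_level

    # deterministic +/- pattern keeps the planted QC CV exact regardless of
    # how few QC injections are configured
    cv_pattern = np.where(np.arange(len(qc_cols)) % 2 == 0, 1.0, -1.0)
    if len(qc_cols) % 2 == 1:
        cv_pattern[-1] = 0.0
    cv_pattern = cv_pattern - cv_pattern.mean()
    cv_pattern /= np.std(cv_pattern, ddof=1)

    intensities = pd.DataFrame(index=feature_ids, columns=injections.index, dtype=float)
    for fid, cls in truth.items():
        base = float(np.exp(rng.normal(np.log(1e5), 0.5)))
        fold = config.real_feature_fold if cls != "ttest" else 1.0
        per_sample = {}
        for sid in sample_ids:
            mu = base * (fold if status[sid] == "NC" else 1.0)
            per_sample[sid] = mu * np.exp(rng.normal(0.0, 0.15))
        if cls == "ttest":
            # exactly proportional to the spike: flat after normalization
            vals = {c: base * inj_effect[c] for c in study_cols}
        else:
            vals = {
                c: per_sample[injections.loc[c, "sample_id"]]
                * np.exp(rng.normal(0.0, 0.05)) * inj_effect[c]
                for c in study_cols
            }
        if cls == "detection":
            for sid in drop_per_group.values():
                for c in study_cols:
                    if injections.loc[c, "sample_id"] == sid:
                        vals[c] = 0.0
        intensities.loc[fid, list(vals)] = pd.Series(vals)
        qc_mean = base * (1 + fold) / 2
        if cls == "qc_cv":
            qc_vals = qc_mean * (1.0 + config.qc_cv_artifact * cv_pattern)
        elif cls == "ttest":
            qc_vals = np.full(len(qc_cols), qc_mean)
        else:
            qc_vals = qc_mean * np.exp(rng.normal(0.0, config.qc_cv_real, size=len(qc_cols)))
        intensities.loc[fid, qc_cols] = qc_vals * inj_effect[qc_cols].to_numpy()
        blank_level = (base * (1 + fold) / 4) if cls == "blank" else 0.0
        intensities.loc[fid, blank_cols] = blank_level * inj_effect[blank_cols].to_numpy()

    # a couple of real features exercise replicate imputation
    real_ids = [f for f, c in truth.items() if c == "real"]
    for fid in real_ids[:2]:
        col = f"{sample_ids[0]}_r2"
        intensities.loc[fid, col] = np.nan

    intensities.loc["ISTD"] = istd
    return FeatureMatrix(intensities, injections), truth


def plant_associations(
    config: SimulationConfig, variable_table: pd.DataFrame | None = None, seed=None
) -> tuple[pd.DataFrame, list]:
    """Harmonized variable table with planted co-exceptional pairs.

    Starts from ``variable_table`` (samples x variables; standard-normal
    noise variables are generated when omitted) and, for each planted pair,
    injects exceptionally high values into the same randomly chosen
    ``joint_exceedance`` fraction of samples of both members.  Pairs are
    disjoint; overlapping specifications raise.  Returns the table and the
    truth list of planted pairs.
    """
    config.validate()
    rng = _rng(seed)
    if variable_table is None:
        n_samples = 100
        cols = [f"V{i + 1}" for i in range(config.n_association_variables)]
        variable_table = pd.DataFrame(
            rng.normal(0.0, 1.0, size=(n_samples, len(cols))),
            index=[f"S{i + 1}" for i in range(n_samples)],
            columns=cols,
        )
    table = variable_table.copy()
    n = len(table)
    n_pairs = config.n_planted_pairs
    if 2 * n_pairs > table.shape[1]:
        raise ValueError("not enough variables for disjoint planted pairs")
    chosen = rng.choice(table.shape[1], size=2 * n_pairs, replace=False)
    pairs = [(table.columns[chosen[2 * i]], table.columns[chosen[2 * i + 1]]) for i in range(n_pairs)]
    seen: set = set()
    for pair in pairs:
        if seen & set(pair):
            raise ValueError(f"overlapping pair specification: {pair}")
        seen |= set(pair)
    k = int(round(config.joint_exceedance * n))
    for va, vb in pairs:
        hit = rng.choice(n, size=k, replace=False)
        for v in (va, vb):
            x = table[v].to_numpy(dtype=float)
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            scale = mad if mad > 0 else (np.std(x) or 1.0)
            x[hit] = med + 10.0 * scale * (1.0 + 0.1 * rng.random(k))
            table[v] = x
    return table, pairs


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> dict:
    """One full synthetic study: gardens, chemistry, OTU tables, features.

    Seeds for the component generators are derived from ``seed`` via
    ``numpy.random.SeedSequence.spawn`` so the pieces are independent but
    jointly reproducible.  Returns a dict with gardens, samples, per-marker
    (OtuTable, truth) pairs, the feature matrix and its truth.
    """
    config = config or SimulationConfig()
    config.validate()
    streams = np.random.SeedSequence(seed).spawn(4 + len(config.markers))
    gardens = simulate_gardens(config, np.random.default_rng(streams[0]))
    samples = simulate_chemistry(config, gardens, np.random.default_rng(streams[1]))
    samples = samples.merge(gardens[["garden_id", "pollution_group"]], on="garden_id")
    otu_tables = {}
    for i, marker in enumerate(config.markers):
        otu_tables[marker] = simulate_otu_table(
            config, gardens, samples[["sample_id", "garden_id", "status"]], marker,
            np.random.default_rng(streams[2 + i]),
        )
    features, feature_truth = simulate_features(
        config, samples, np.random.default_rng(streams[2 + len(config.markers)])
    )
    return {
        "config": config,
        "seed": seed,
        "gardens": gardens,
        "samples": samples,
        "otu_tables": otu_tables,
        "features": features,
        "feature_truth": feature_truth,
    }
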