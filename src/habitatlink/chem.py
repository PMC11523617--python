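"""Water chemistry summaries and the untargeted LC–HRMS feature filter.

Two halves.  The first summarizes per-sample physicochemistry (temperature,
pH, dissolved oxygen, gases, ions, total organic carbon) by colonization
status as mean ± standard error, mirroring the survey's per-container
summary columns.

The second implements the untargeted feature-filter cascade applied to the
LC–HRMS feature matrix (features x injections, with study / pooled-QC /
blank injection roles and triplicate injections per water sample):

1. normalization of every intensity to the injection's internal standard
   (deuterated diuron spike);
2. removal of features whose coefficient of variation across the QC
   injections exceeds 30 %;
3. imputation of a missing replicate by the mean of its two siblings (0 if
   none are available);
4. removal of features not detected in 100 % of the samples of at least one
   pollution group;
5. removal of features whose study/blank mean-intensity ratio is not
   above 10;
6. removal of features with no significant colonized-vs-noncolonized
   difference (two-sided Welch t-test on per-sample intensities).

Every stage can only shrink the retained set; an audit of survivors per
stage and each dropped feature's first failing stage is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

ROLES = ("study", "QC", "blank")
CASCADE_STAGES = (
    "input",
    "istd_normalized",
    "qc_cv",
    "imputed",
    "detection_rate",
    "blank_ratio",
    "status_ttest",
)

__all__ = [
    "FeatureMatrix",
    "summarize",
    "container_tally",
    "toc",
    "normalize_to_istd",
    "filter_cascade",
    "CascadeResult",
]


# ---------------------------------------------------------------------------
# physicochemistry summaries


def summarize(samples: pd.DataFrame, fields, group: str = "status") -> pd.DataFrame:
    """Mean ± SE of one or more numeric fields per group.

    ``samples`` is a per-sample table with a grouping column (default the
    NC/C colonization status).  SE is sd(ddof=1)/sqrt(n).  Returns a tidy
    DataFrame indexed by (field, group) with columns mean, se, n.
    """
    if isinstance(fields, str):
        fields = [fields]
    missing = [f for f in fields if f not in samples.columns]
    if missing:
        raise KeyError(f"unknown field(s): {missing}")
    if group not in samples.columns:
        raise KeyError(f"unknown grouping column: {group}")
    rows = []
    for f in fields:
        for g, sub in samples.groupby(group, sort=False):
            v = sub[f].astype(float).dropna()
            if len(v) < 2:
                raise ValueError(f"need >=2 samples per group for {f}/{g}")
            rows.append(
                {
                    "field": f,
                    "group": g,
                    "mean": v.mean(),
                    "se": v.std(ddof=1) / np.sqrt(len(v)),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows).set_index(["field", "group"])


def container_tally(samples: pd.DataFrame, column: str = "container_type") -> pd.Series:
    """Percentage of samples per container type (sums to 100 up to rounding)."""
    if len(samples) == 0:
        raise ValueError("empty sample list")
    counts = samples[column].value_counts()
    return counts / counts.sum() * 100.0


def toc(tc, ic):
    """Total organic carbon (mg/l) as total minus inorganic carbon."""
    tc = np.asarray(tc, dtype=float)
    ic = np.asarray(ic, dtype=float)
    if np.any(ic < 0) or np.any(tc < 0):
        raise ValueError("carbon concentrations must be nonnegative")
    if np.any(ic > tc):
        raise ValueError("inorganic carbon exceeds total carbon")
    return tc - ic


# ---------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """LC–HRMS feature intensities with injection roles and replicates.

    intensities: DataFrame, features x injections (NaN = missing).
    injections: DataFrame indexed by injection id with columns ``sample_id``,
    ``role`` (study/QC/blank), ``replicate`` (1–3 for study injections),
    ``status`` (NC/C/none) and ``group`` (pollution group or none).
    """

    intensities: pd.DataFrame
    injections: pd.DataFrame

    def __post_init__(self) -> None:
        inj = self.injections
        if not set(inj["role"]).issubset(ROLES):
            raise ValueError(f"roles must be within {ROLES}")
        missing = set(self.intensities.columns) - set(inj.index)
        if missing:
            raise ValueError(f"injections without metadata: {sorted(missing)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be nonnegative or missing")
        reps = inj[inj["role"] == "study"].groupby("sample_id").size()
        if (reps > 3).any():
            raise ValueError("every study sample has at most 3 replicates")

    def columns_for(self, role: str) -> list[str]:
        idx = self.injections.index[self.injections["role"] == role]
        return [c for c in self.intensities.columns if c in set(idx)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)


def normalize_to_istd(matrix: FeatureMatrix, istd_feature: str) -> FeatureMatrix:
    """Divide every intensity by its injection's internal-standard intensity.

    Injections whose internal standard is missing or nonpositive are flagged
    and excluded (with a warning); the internal-standard row itself is kept
    (all ones) for auditability.
    """
    if istd_feature not in matrix.intensities.index:
        raise KeyError(f"internal standard {istd_feature!r} not in matrix")
    istd = matrix.intensities.loc[istd_feature]
    bad = istd.index[~(istd > 0)].tolist()
    if bad:
        warnings.warn(f"excluding {len(bad)} injection(s) with missing internal standard: {bad}",
                      stacklevel=2)
    good = [c for c in matrix.intensities.columns if c not in set(bad)]
    normalized = matrix.intensities[good] / istd[good]
    return FeatureMatrix(normalized, matrix.injections.loc[good])


# ---------------------------------------------------------------------------
# filter cascade


@dataclass
class CascadeResult:
    """Outcome of the feature-filter cascade."""

    retained: list[str]
    audit: dict  # stage -> surviving feature count
    dropped_at: pd.Series  # feature -> stage name of first failure
    matrix: FeatureMatrix  # normalized + imputed intensities, study injections
    ttest_p: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _qc_cv(values: pd.DataFrame) -> pd.Series:
    """Coefficient of variation (%) per feature over QC injections."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    cv = sd / mean * 100.0
    cv[mean <= 0] = np.inf  # absent from QCs: unreliable
    return cv


def _impute_replicates(study: pd.DataFrame, injections: pd.DataFrame) -> pd.DataFrame:
    """Replace a missing replicate by the mean of its siblings, else 0."""
    out = study.copy()
    for _, grp in injections.groupby("sample_id"):
        cols = [c for c in grp.index if c in out.columns]
        block = out[cols]
        sib_mean = block.mean(axis=1)  # NaN-aware
        for c in cols:
            mask = block[c].isna()
            out.loc[mask, c] = sib_mean[mask]
    return out.fillna(0.0)


def filter_cascade(
    matrix: FeatureMatrix,
    istd_feature: str | None = None,
    cv_max: float = 30.0,
    blank_ratio: float = 10.0,
    alpha: float = 0.05,
    detection_rule: str = "any_group",
) -> CascadeResult:
    """Run the six-stage untargeted feature filter; see the module docstring.

    ``detection_rule`` — ``"any_group"`` (default) keeps a feature detected
    in 100 % of the samples of at least one pollution group; ``"all_groups"``
    requires 100 % everywhere.
    """
    if detection_rule not in ("any_group", "all_groups"):
        raise ValueError("detection_rule must be 'any_group' or 'all_groups'")
    audit: dict = {}
    dropped_at: dict = {}

    m = matrix
    audit["input"] = len(m.feature_ids)
    if istd_feature is not None:
        m = normalize_to_istd(m, istd_feature)
        m = FeatureMatrix(m.intensities.drop(index=istd_feature), m.injections)
    audit["istd_normalized"] = len(m.feature_ids)

    inj = m.injections.loc[list(m.intensities.columns)]
    qc_cols = [c for c in m.intensities.columns if inj.loc[c, "role"] == "QC"]
    blank_cols = [c for c in m.intensities.columns if inj.loc[c, "role"] == "blank"]
    study_cols = [c for c in m.intensities.columns if inj.loc[c, "role"] == "study"]
    if not study_cols:
        raise ValueError("matrix has no study injections")

    # stage 2: QC repeatability
    keep = pd.Series(True, index=m.intensities.index)
    if qc_cols:
        cv = _qc_cv(m.intensities[qc_cols])
        fail = cv > cv_max
        for fid in m.intensities.index[keep & fail]:
            dropped_at[fid] = "qc_cv"
        keep &= ~fail
    else:
        warnings.warn("no QC injections: skipping the QC CV stage", stacklevel=2)
    audit["qc_cv"] = int(keep.sum())

    # stage 3: replicate imputation (never changes a present value)
    study_inj = inj.loc[study_cols]
    study = _impute_replicates(m.intensities.loc[keep, study_cols], study_inj)
    audit["imputed"] = int(keep.sum())

    # stage 4: detection rate per pollution group (detection = intensity > 0)
    per_sample = study.T.groupby(study_inj["sample_id"]).mean().T  # features x samples
    sample_group = study_inj.drop_duplicates("sample_id").set_index("sample_id")["group"]
    detected = per_sample > 0
    rates = detected.T.groupby(sample_group.loc[per_sample.columns]).mean().T
    full = rates == 1.0
    ok = full.any(axis=1) if detection_rule == "any_group" else full.all(axis=1)
    fail = keep & ~ok.reindex(keep.index, fill_value=False)
    for fid in m.intensities.index[fail]:
        dropped_at[fid] = "detection_rate"
    keep &= ~fail
    audit["detection_rate"] = int(keep.sum())

    # stage 5: study-over-blank intensity ratio
    if blank_cols:
        study_mean = study.mean(axis=1).reindex(keep.index)
        blank_mean = m.intensities[blank_cols].fillna(0.0).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = study_mean / blank_mean
        passes = (ratio > blank_ratio) | ((blank_mean == 0) & (study_mean > 0))
        fail = keep & ~passes.fillna(False)
        for fid in m.intensities.index[fail]:
            dropped_at[fid] = "blank_ratio"
        keep &= ~fail
    else:
        warnings.warn("no blank injections: skipping the blank-ratio stage", stacklevel=2)
    audit["blank_ratio"] = int(keep.sum())

    # stage 6: NC vs C difference (two-sided Welch on per-sample values)
    sample_status = study_inj.drop_duplicates("sample_id").set_index("sample_id")["status"]
    nc_cols = sample_status.index[sample_status == "NC"]
    c_cols = sample_status.index[sample_status == "C"]
    pvals = pd.Series(np.nan, index=m.intensities.index)
    if len(nc_cols) >= 2 and len(c_cols) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance features yield NaN t
            res = ttest_ind(
                per_sample[nc_cols], per_sample[c_cols], axis=1, equal_var=False
            )
        pvals.loc[per_sample.index] = res.pvalue
        # features whose total variation is at floating-point noise level are
        # effectively constant: no evidence of a status difference
        scale = per_sample.abs().mean(axis=1)
        degenerate = per_sample.std(axis=1, ddof=1) <= 1e-9 * scale
        pvals.loc[per_sample.index[degenerate]] = np.nan
        p_eff = pvals.fillna(1.0)  # degenerate (constant) features: no evidence
        fail = keep & ~(p_eff < alpha)
        for fid in m.intensities.index[fail]:
            dropped_at[fid] = "status_ttest"
        keep &= ~fail
    else:
        warnings.warn("fewer than 2 samples per status: skipping the t-test stage", stacklevel=2)
    audit["status_ttest"] = int(keep.sum())

    retained = list(m.intensities.index[keep])
    return CascadeResult(
        retained=retained,
        audit=audit,
        dropped_at=pd.Series(dropped_at, dtype=object),
        matrix=FeatureMatrix(pd.concat([study], axis=1), study_inj),
        ttest_p=pvals,
    )
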