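"""Gradient ordination chain: PCA, PERMANOVA, dbRDA, OTU screen, Procrustes.

The analysis asks how much of the between-sample microbial community
variation (Bray–Curtis dissimilarities) is explained by the dominant axes of
the abiotic environment.  Abiotic variables (physicochemistry + pollution
variables, or organic-molecule occurrence) are summarized by PCA; the leading
components enter a sequential PERMANOVA of the community dissimilarities and
a distance-based redundancy analysis (dbRDA) whose site scores support a
Spearman screen for the OTUs that track each axis.  A Monte Carlo Procrustes
test measures the concordance of two ordinations.

PERMANOVA here follows the Gower-centered inner-product partition of
McArdle–Anderson with continuous covariates fitted sequentially (type-I, as
in vegan's ``adonis2(..., by="terms")``); permutation p-values use the +1
correction.  The dbRDA constrained-inertia fraction equals the PERMANOVA R^2
for the same model and distance matrix by construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orth, svdvals
from scipy.stats import spearmanr
from skbio import DistanceMatrix

__all__ = [
    "PcaResult",
    "PermanovaResult",
    "DbrdaResult",
    "ProcrustesResult",
    "pca",
    "permanova",
    "dbrda",
    "spearman_screen",
    "procrustes_test",
    "gradient_analysis",
]


# ---------------------------------------------------------------------------
# helpers


def _as_square(dist) -> tuple[np.ndarray, list]:
    if isinstance(dist, DistanceMatrix):
        return dist.data.astype(float), list(dist.ids)
    arr = np.asarray(dist, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    return arr, list(range(arr.shape[0]))


def _gower(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix of a distance matrix."""
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _covariate_frame(covariates, n: int) -> pd.DataFrame:
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    if isinstance(covariates, pd.DataFrame):
        x = covariates.copy()
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        x = pd.DataFrame(arr, columns=[f"x{i + 1}" for i in range(arr.shape[1])])
    if len(x) != n:
        raise ValueError(f"covariates have {len(x)} rows but distance matrix has {n}")
    for col in x.columns:
        if np.ptp(x[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"covariate {col!r} is constant")
    return x.astype(float)


def _hat(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto span(1, x) (rank-safe)."""
    n = x.shape[0]
    design = np.column_stack([np.ones(n), x])
    q = orth(design)
    return q @ q.T


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    """Sample scores, variable loadings and eigenvalues of a PCA."""

    scores: pd.DataFrame  # samples x axes
    loadings: pd.DataFrame  # variables x axes, orthonormal columns
    eigenvalues: pd.Series
    proportion_explained: pd.Series
    means: pd.Series
    scales: pd.Series


def pca(variables: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of a samples x variables table.

    With ``standardize`` the decomposition is of the correlation matrix
    (constant variables are dropped with a warning); otherwise of the
    covariance matrix.  Axis signs are fixed so that the variable with the
    largest absolute loading on each axis loads positively.
    """
    x = pd.DataFrame(variables).astype(float)
    if x.isna().any().any():
        x = x.dropna(axis=0)
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("pca needs >=3 complete samples and >=2 variables")
    if standardize:
        sd = x.std(ddof=1)
        constant = sd.index[sd == 0].tolist()
        if constant:
            warnings.warn(f"dropping constant variables: {constant}", stacklevel=2)
            x = x.drop(columns=constant)
            sd = sd.drop(index=constant)
        means = x.mean()
        z = (x - means) / sd
        scales = sd
    else:
        means = x.mean()
        z = x - means
        scales = pd.Series(1.0, index=x.columns)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    n = z.shape[0]
    eig = s**2 / (n - 1)
    axes = [f"PC{i + 1}" for i in range(len(eig))]
    loadings = vt.T
    # sign convention: dominant variable of each axis loads positively
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            u[:, j] *= -1
    scores = u * s
    return PcaResult(
        scores=pd.DataFrame(scores, index=z.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=z.columns, columns=axes),
        eigenvalues=pd.Series(eig, index=axes),
        proportion_explained=pd.Series(eig / eig.sum(), index=axes),
        means=means,
        scales=scales,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table plus the permutation settings used."""

    table: pd.DataFrame  # index: terms + Residual + Total
    n_perm: int
    seed: int | None
    exhaustive: bool = False

    def r2(self, term) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term) -> float:
        return float(self.table.loc[term, "p"])


def _term_stats(g: np.ndarray, hats: list[np.ndarray], df_terms: list[int]):
    """Sequential sums of squares and pseudo-F for fixed projectors."""
    ss_total = np.trace(g)
    cum = [float(np.sum(h * g.T)) for h in hats]  # tr(H G)
    ss_terms = np.diff([0.0] + cum)
    ss_res = ss_total - cum[-1]
    df_res = g.shape[0] - 1 - sum(df_terms)
    f = (ss_terms / np.array(df_terms)) / (ss_res / df_res)
    return ss_terms, ss_res, df_res, f


def permanova(
    dist,
    covariates,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA of a distance matrix on covariates.

    Covariates (numeric; one term per column) are fitted sequentially in
    column order.  The permutation null shuffles sample identities of the
    Gower-centered matrix; ``p = (1 + #{F* >= F}) / (1 + n_perm)``.  With
    ``exhaustive`` all n! relabelings are enumerated (n <= 8) and
    ``p = #{F* >= F} / n!`` (the identity counts, so p >= 1/n!).
    """
    d, ids = _as_square(dist)
    n = d.shape[0]
    x = _covariate_frame(covariates, n)
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    g = _gower(d)

    terms = list(x.columns)
    hats, df_terms = [], []
    for k in range(1, len(terms) + 1):
        sub = x.iloc[:, :k].to_numpy()
        h = _hat(sub)
        df_terms.append(int(round(np.trace(h))) - 1 - sum(df_terms))
        hats.append(h)
    ss_terms, ss_res, df_res, f_obs = _term_stats(g, hats, df_terms)
    if df_res <= 0:
        raise ValueError("model saturates the degrees of freedom")

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration supported for n <= 8 only")
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            gp = g[np.ix_(perm, perm)]
            f_perm = _term_stats(gp, hats, df_terms)[3]
            count += f_perm >= f_obs - 1e-12
            total += 1
        pvals = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            f_perm = _term_stats(gp, hats, df_terms)[3]
            count += f_perm >= f_obs - 1e-12
        pvals = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm

    ss_total = np.trace(g)
    rows = []
    for i, t in enumerate(terms):
        rows.append(
            {
                "df": df_terms[i],
                "SumOfSqs": ss_terms[i],
                "R2": ss_terms[i] / ss_total,
                "F": f_obs[i],
                "p": pvals[i],
            }
        )
    rows.append({"df": df_res, "SumOfSqs": ss_res, "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"df": n - 1, "SumOfSqs": ss_total, "R2": 1.0, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows, index=terms + ["Residual", "Total"])
    return PermanovaResult(table=table, n_perm=n_used, seed=seed, exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# dbRDA


@dataclass
class DbrdaResult:
    """Constrained ordination of a dissimilarity matrix."""

    site_scores: pd.DataFrame  # samples x constrained axes
    eigenvalues: pd.Series  # constrained axes
    constrained_inertia: float
    total_inertia: float
    negative_eigenvalue_mass: float
    sample_ids: list = field(default_factory=list)

    @property
    def proportion_constrained(self) -> float:
        return self.constrained_inertia / self.total_inertia

    def otu_scores(self, abundances: pd.DataFrame) -> pd.DataFrame:
        """Correlate OTU abundances (samples x OTUs) with the site scores.

        Used to overlay the taxa that drive the constrained axes on a
        biplot.  Constant OTUs get NaN.
        """
        ab = abundances.loc[self.site_scores.index]
        out = {}
        for axis in self.site_scores.columns:
            s = self.site_scores[axis]
            out[axis] = ab.apply(lambda col: col.corr(s))
        return pd.DataFrame(out)


def dbrda(dist, constraints, sqrt_transform: bool = True, neg_tol: float = 0.05) -> DbrdaResult:
    """Distance-based redundancy analysis.

    Embeds the (optionally square-root transformed) dissimilarities via Gower
    centering, projects onto the constraint space and eigen-analyses the
    fitted inner products.  ``constrained_inertia / total_inertia`` equals the
    PERMANOVA R^2 of the same model on the same (transformed) distances.

    The square-root transform tames negative eigenvalues of semimetric
    indices such as Bray–Curtis; the remaining negative-eigenvalue mass is
    reported and warned about above ``neg_tol`` (fraction of total absolute
    eigenvalue mass).
    """
    d, ids = _as_square(dist)
    n = d.shape[0]
    x = _covariate_frame(constraints, n)
    if sqrt_transform:
        d = np.sqrt(d)
    g = _gower(d)
    eig_all = np.linalg.eigvalsh(g)
    neg_mass = float(np.abs(eig_all[eig_all < -1e-10]).sum())
    denom = float(np.abs(eig_all).sum())
    if denom > 0 and neg_mass / denom > neg_tol:
        warnings.warn(
            f"negative-eigenvalue mass {neg_mass / denom:.1%} of total exceeds {neg_tol:.0%}",
            stacklevel=2,
        )
    h = _hat(x.to_numpy())
    g_fit = h @ g @ h
    vals, vecs = np.linalg.eigh(g_fit)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int(np.linalg.matrix_rank(x.to_numpy() - x.to_numpy().mean(axis=0)))
    keep = [i for i in range(len(vals)) if vals[i] > 1e-10][:rank]
    axes = [f"dbRDA{i + 1}" for i in range(len(keep))]
    scores = vecs[:, keep] * np.sqrt(vals[keep])
    return DbrdaResult(
        site_scores=pd.DataFrame(scores, index=ids, columns=axes),
        eigenvalues=pd.Series(vals[keep], index=axes),
        constrained_inertia=float(np.trace(g_fit)),
        total_inertia=float(np.trace(g)),
        negative_eigenvalue_mass=neg_mass,
        sample_ids=ids,
    )


# ---------------------------------------------------------------------------
# OTU screen


def spearman_screen(table, axis, alpha: float = 0.05) -> pd.DataFrame:
    """Spearman rank correlation of each OTU's abundance with an axis.

    ``table`` is an :class:`~habitatlink.otu.OtuTable` or a samples-indexed
    DataFrame of abundances (samples x OTUs).  Constant OTU vectors yield
    NaN rho/p.  Returns a DataFrame (otu_id, rho, p, significant).
    """
    from .otu import OtuTable  # local import avoids a cycle

    if isinstance(table, OtuTable):
        ab = table.counts.T.astype(float)
    else:
        ab = pd.DataFrame(table).astype(float)
    axis = pd.Series(axis, index=ab.index) if not isinstance(axis, pd.Series) else axis
    ab = ab.loc[axis.index]
    if len(ab) < 5:
        raise ValueError("spearman screen needs at least 5 samples")
    rows = []
    for otu in ab.columns:
        v = ab[otu].to_numpy()
        if np.ptp(v) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = spearmanr(v, axis.to_numpy())
        rows.append(
            {
                "otu_id": otu,
                "rho": rho,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


# ---------------------------------------------------------------------------
# Procrustes Monte Carlo test


@dataclass
class ProcrustesResult:
    """Procrustean concordance of two score matrices."""

    statistic: float  # sum of singular values of X'Y after normalization
    p: float
    n_perm: int
    seed: int | None


def _normalize_scores(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    m = m - m.mean(axis=0)
    norm = np.sqrt((m**2).sum())
    if norm == 0:
        raise ValueError("rank-0 input: all rows identical")
    return m / norm


def procrustes_test(x, y, n_perm: int = 999, seed: int | None = None) -> ProcrustesResult:
    """Monte Carlo test on the sum of singular values of a Procrustes rotation.

    Both matrices are column-centered and scaled to unit total sum of
    squares; the statistic is the sum of singular values of X'Y (1 when one
    configuration is a rigid rotation of the other).  The null permutes the
    rows of Y.
    """
    x = _normalize_scores(np.atleast_2d(x))
    y = _normalize_scores(np.atleast_2d(y))
    if x.shape[0] != y.shape[0]:
        raise ValueError("score matrices must share their samples")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    stat = float(svdvals(x.T @ y).sum())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(x.shape[0])
        # re-center after permutation is a no-op (row permutation), re-use y
        if svdvals(x.T @ y[perm]).sum() >= stat - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return ProcrustesResult(statistic=stat, p=p, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# bundled gradient analysis


def gradient_analysis(
    dist,
    abiotic: pd.DataFrame,
    table=None,
    n_perm: int = 999,
    seed: int | None = None,
    n_axes: int = 2,
    alpha: float = 0.05,
) -> dict:
    """PCA of the abiotic table -> PERMANOVA on its leading axes -> dbRDA ->
    Spearman OTU screen on each significant axis.

    Returns one structured report: ``pca`` (PcaResult), ``axes`` used,
    ``permanova`` (PermanovaResult), ``dbrda`` (DbrdaResult) and
    ``otu_screen`` — a dict mapping every tested axis to a (possibly empty)
    DataFrame of significantly correlated OTUs.  Any stage error is re-raised
    with the stage name attached.
    """
    report: dict = {}
    stage = "pca"
    try:
        p = pca(abiotic, standardize=True)
        axes = list(p.scores.columns[:n_axes])
        report["pca"] = p
        report["axes"] = axes
        stage = "permanova"
        scores = p.scores[axes]
        perm = permanova(dist, scores, n_perm=n_perm, seed=seed)
        report["permanova"] = perm
        stage = "dbrda"
        report["dbrda"] = dbrda(dist, scores)
        stage = "spearman_screen"
        screens = {}
        for ax in axes:
            if table is not None and perm.p(ax) < alpha:
                scr = spearman_screen(table, scores[ax], alpha=alpha)
                screens[ax] = scr[scr["significant"]]
            else:
                screens[ax] = pd.DataFrame(columns=["rho", "p", "significant"])
        report["otu_screen"] = screens
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"gradient_analysis failed at stage {stage!r}: {exc}") from exc
    return report
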