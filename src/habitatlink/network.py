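"""Mixed-type association networks via robust binarization and Zhang's score.

The method links variables of heterogeneous nature — OTU abundances,
physicochemical measurements, pollution variables, organic-molecule
intensities, categorical indicators — without distributional assumptions:

1. every numeric variable is reduced to "exceptionally high or not" with the
   modified z-score, ``z_i = (x_i - med(x)) / MAD`` (median absolute
   deviation in the denominator; no consistency constant), thresholded
   one-sidedly so only exceptionally HIGH values are flagged;
2. the strength of association between two binary variables is Zhang's
   association-rule score, in [-1, +1] with 0 under independence;
3. an exact one-sided binomial test against the independence null
   ``K ~ Binomial(n, P(A) P(B))`` assesses significance of the observed
   co-occurrence count;
4. an edge joins two variables iff the Zhang score exceeds a threshold AND
   the binomial p-value is below alpha.

The default exceptionality threshold is 3.5 standard-deviation equivalents,
i.e. 3.5/0.6745 ≈ 5.19 in bare median-absolute-deviation units, matching the
classical modified-z-score outlier rule when the MAD is not rescaled to be
sigma-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import binom, spearmanr

#: Classical |modified z| > 3.5 outlier rule expressed in bare MAD units
#: (the formula above applies no 0.6745 sigma-consistency constant).
DEFAULT_Z_THRESHOLD = 3.5 / 0.6745

__all__ = [
    "DEFAULT_Z_THRESHOLD",
    "MadZeroError",
    "modified_zscore",
    "binarize",
    "exceptionality_matrix",
    "zhang_score",
    "binomial_edge_test",
    "build_network",
    "edge_table",
    "precision_recall",
]


class MadZeroError(ValueError):
    """The variable's median absolute deviation is zero: not binarizable."""


def modified_zscore(x) -> np.ndarray:
    """Robust z-score ``(x - med(x)) / MAD`` with MAD = median(|x - med(x)|).

    NaNs propagate; at least 3 finite values are required and a zero MAD
    raises :class:`MadZeroError`.
    """
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 3:
        raise ValueError("modified_zscore needs at least 3 finite values")
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    if mad == 0:
        raise MadZeroError("MAD is zero; variable cannot be binarized")
    return (x - med) / mad


def binarize(z, threshold: float = DEFAULT_Z_THRESHOLD) -> np.ndarray:
    """One-sided exceptionality indicator: 1 where z > threshold, else 0.

    Only exceptionally high values are flagged; NaNs stay NaN (as float).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(z, dtype=float)
    out = (z > threshold).astype(float)
    out[~np.isfinite(z)] = np.nan
    return out


def exceptionality_matrix(
    variables: pd.DataFrame, threshold: float = DEFAULT_Z_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binarize every numeric column of a samples x variables table.

    Returns ``(binary, audit)``: the 0/1 matrix (MAD-zero variables dropped)
    and a per-variable audit with the median, MAD, threshold and whether the
    variable was kept.
    """
    binary = {}
    audit_rows = []
    for col in variables.columns:
        x = variables[col].to_numpy(dtype=float)
        finite = x[np.isfinite(x)]
        med = np.median(finite) if finite.size else np.nan
        mad = np.median(np.abs(finite - med)) if finite.size else np.nan
        row = {"variable": col, "median": med, "mad": mad, "threshold": threshold}
        try:
            binary[col] = binarize(modified_zscore(x), threshold)
            row["kept"] = True
        except (ValueError, MadZeroError):
            row["kept"] = False
        audit_rows.append(row)
    audit = pd.DataFrame(audit_rows).set_index("variable")
    dropped = audit.index[~audit["kept"]].tolist()
    if dropped:
        warnings.warn(f"dropping {len(dropped)} non-binarizable variable(s)", stacklevel=2)
    return pd.DataFrame(binary, index=variables.index), audit


def zhang_score(a, b, direction: str = "max") -> float:
    """Zhang's association-rule score between two binary vectors.

    With supports P(A), P(B) and joint support P(AB) estimated as sample
    frequencies,

        Z(A->B) = (P(AB) - P(A)P(B)) /
                  max{ P(AB) (1 - P(A)),  P(A) (P(B) - P(AB)) }

    Z is in [-1, 1]: +1 at perfect association (A = B), -1 at perfect
    disassociation (A = not B), 0 under exact independence (a zero
    denominator also returns 0).  ``direction="max"`` (default) evaluates
    both rule directions and returns the larger score; ``"ab"`` evaluates
    only A->B.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and the same length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Zhang's score is undefined for a constant vector")

    def one_way(u, v):
        pu, pv, puv = u.mean(), v.mean(), (u * v).mean()
        denom = max(puv * (1 - pu), pu * (pv - puv))
        if denom == 0:
            return 0.0
        return (puv - pu * pv) / denom

    if direction == "ab":
        z = one_way(a, b)
    elif direction == "max":
        z = max(one_way(a, b), one_way(b, a))
    else:
        raise ValueError("direction must be 'max' or 'ab'")
    assert -1.0 - 1e-12 <= z <= 1.0 + 1e-12
    return float(np.clip(z, -1.0, 1.0))


def binomial_edge_test(a, b, p0: float | None = None) -> float:
    """One-sided exact binomial tail for the co-occurrence of two events.

    Under independence the co-occurrence count is K ~ Binomial(n, P(A)P(B));
    the p-value is P[K >= k_obs].  ``p0`` overrides the estimated null joint
    probability (e.g. when true supports are known by design).  Degenerate
    supports (0 or 1) return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and the same length")
    n = a.size
    pa, pb = a.mean(), b.mean()
    if p0 is None:
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            warnings.warn("degenerate support: p-value set to 1", stacklevel=2)
            return 1.0
        p0 = pa * pb
    k_obs = int(np.round((a * b).sum()))
    # exact upper tail P[K >= k]; sf(k-1) == 1 - cdf(k-1)
    return float(binom.sf(k_obs - 1, n, p0))


@dataclass
class AssociationEdge:
    source: str
    target: str
    zhang: float
    rho: float
    support_a: float
    support_b: float
    support_ab: float
    binom_p: float
    n: int


def build_network(
    binary: pd.DataFrame,
    kinds: dict | pd.Series | None = None,
    zhang_min: float = 0.25,
    alpha: float = 0.05,
) -> nx.Graph:
    """Score every unordered variable pair and keep the supported edges.

    ``binary`` is a samples x variables 0/1 matrix (categorical indicator
    variables such as colonization status enter directly as 0/1 columns;
    NaNs give pairwise-complete handling).  An undirected edge is retained
    iff ``zhang > zhang_min`` and ``binomial p < alpha``.  Pairs in which a
    vector is constant on the complete cases form no edge.  Each edge stores
    the Zhang score (max over directions), the binary Spearman correlation,
    both supports, the joint support, the p-value and the number of complete
    cases; an empty edge set is a valid result.
    """
    if binary.shape[1] < 2:
        raise ValueError("need at least 2 binarizable variables")
    g = nx.Graph(zhang_min=float(zhang_min), alpha=float(alpha))
    variables = list(binary.columns)
    for v in variables:
        kind = None
        if kinds is not None:
            kind = kinds.get(v) if isinstance(kinds, dict) else kinds.get(v, None)
        g.add_node(v, kind=str(kind) if kind is not None else "unknown")
    arr = binary.to_numpy(dtype=float)
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            a, b = arr[:, i], arr[:, j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                continue
            a, b = a[ok], b[ok]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            z = zhang_score(a, b, direction="max")
            p = binomial_edge_test(a, b)
            if z > zhang_min and p < alpha:
                rho = spearmanr(a, b)[0]
                g.add_edge(
                    variables[i],
                    variables[j],
                    zhang=float(z),
                    rho=float(rho),
                    support_a=float(a.mean()),
                    support_b=float(b.mean()),
                    support_ab=float((a * b).mean()),
                    binom_p=float(p),
                    n=int(ok.sum()),
                )
    return g


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Flat edge list of an association graph (one row per retained edge)."""
    rows = [
        {"source": u, "target": v, **attrs} for u, v, attrs in graph.edges(data=True)
    ]
    cols = ["source", "target", "zhang", "rho", "support_a", "support_b",
            "support_ab", "binom_p", "n"]
    return pd.DataFrame(rows, columns=cols)


def precision_recall(graph: nx.Graph, truth_pairs) -> tuple[float, float]:
    """Exact-set precision/recall of recovered edges against a truth list."""
    found = {frozenset(e) for e in graph.edges()}
    truth = {frozenset(p) for p in truth_pairs}
    tp = len(found & truth)
    precision = tp / len(found) if found else (1.0 if not truth else 0.0)
    recall = tp / len(truth) if truth else 1.0
    return precision, recall
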