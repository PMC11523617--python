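"""OTU count-table preprocessing and diversity.

Implements the amplicon-side preprocessing applied to each marker dataset
(16S bacteria, ITS fungi, 18S microeukaryotes): removal of contaminant OTUs
using the negative extraction/PCR controls, removal of globally rare OTUs,
rarefaction to a common depth, and Shannon / Bray–Curtis diversity.

The count table is held as a pandas DataFrame of nonnegative integers with
OTUs as rows and samples as columns; Bray–Curtis dissimilarities are returned
as a :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from skbio import DistanceMatrix

SAMPLE_TYPES = ("NC", "C", "L", "NEG")

__all__ = [
    "OtuTable",
    "filter_contaminants",
    "filter_rare",
    "rarefy",
    "shannon",
    "alpha_diversity",
    "bray_curtis",
]


@dataclass
class OtuTable:
    """Counts of taxa x samples with optional taxonomy and sample metadata.

    counts: DataFrame indexed by OTU id, one column per sample, nonnegative
    integers.  taxonomy: per-OTU lineage strings.  sample_meta: per-sample
    ``garden_id`` / ``sample_type`` / ``marker`` table indexed by sample id.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("OTU ids and sample ids must be unique")
        arr = c.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers (read counts)")
        self.counts = c.astype(np.int64)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(c.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.sample_totals()
        if (totals == 0).any():
            raise ValueError("cannot compute relative abundance with zero-total samples")
        return self.counts / totals

    def subset_samples(self, sample_ids) -> "OtuTable":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[self.sample_meta.index.intersection(sample_ids)]
        return OtuTable(self.counts[list(sample_ids)], self.taxonomy, meta)


def filter_contaminants(table: OtuTable, neg_ids) -> OtuTable:
    """Remove contaminant OTUs flagged by the negative controls.

    An OTU detected in any negative control is removed unless its maximal
    relative abundance across study samples is at least 10 times its maximal
    relative abundance across the negative controls.  Negative controls are
    dropped from the output.  Comparisons use per-sample relative abundances
    so that controls sequenced at a different depth are handled sensibly.
    """
    neg_ids = list(neg_ids)
    if not neg_ids:
        raise ValueError("neg_ids must be nonempty")
    unknown = set(neg_ids) - set(table.sample_ids)
    if unknown:
        raise ValueError(f"unknown negative-control samples: {sorted(unknown)}")
    study_ids = [s for s in table.sample_ids if s not in neg_ids]
    if not study_ids:
        raise ValueError("no study samples left after excluding negatives")

    totals = table.sample_totals()
    rel = table.counts / totals.replace(0, np.nan)
    neg_rel = rel[neg_ids].max(axis=1).fillna(0.0)
    study_rel = rel[study_ids].max(axis=1).fillna(0.0)
    detected_in_neg = table.counts[neg_ids].sum(axis=1) > 0
    keep = ~detected_in_neg | (study_rel >= 10.0 * neg_rel)
    return OtuTable(
        table.counts.loc[keep, study_ids],
        table.taxonomy[keep] if table.taxonomy is not None else None,
        table.sample_meta.drop(index=neg_ids, errors="ignore")
        if table.sample_meta is not None
        else None,
    )


def filter_rare(table: OtuTable, fraction: float = 0.00005) -> OtuTable:
    """Drop OTUs whose total count is below ``fraction`` of all reads.

    The default 0.00005 is the usual 0.005 % low-abundance cutoff.  OTUs
    exactly at the threshold are retained.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be within [0, 1]")
    grand_total = int(table.counts.to_numpy().sum())
    if grand_total <= 0:
        raise ValueError("table has no reads")
    threshold = fraction * grand_total
    keep = table.counts.sum(axis=1) >= threshold
    return OtuTable(
        table.counts.loc[keep],
        table.taxonomy[keep] if table.taxonomy is not None else None,
        table.sample_meta,
    )


def rarefy(table: OtuTable, depth: int, seed=None) -> OtuTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped with a warning.  The
    draw is multivariate hypergeometric and reproducible given ``seed``
    (an int or a ``numpy.random.Generator``).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = table.sample_totals()
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: {shallow}", stacklevel=2
        )
    kept = [s for s in table.sample_ids if s not in shallow]
    cols = {}
    for s in kept:
        col = table.counts[s].to_numpy()
        if totals[s] == depth:
            cols[s] = col.copy()
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    out = pd.DataFrame(cols, index=table.counts.index)
    meta = None
    if table.sample_meta is not None:
        meta = table.sample_meta.drop(index=shallow, errors="ignore")
    return OtuTable(out, table.taxonomy, meta)


def shannon(counts) -> float:
    """Shannon index H' in nats for one sample's OTU counts."""
    x = np.asarray(counts, dtype=float)
    if x.sum() <= 0:
        raise ValueError("sample has no reads")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    # scipy normalizes and skips zero categories; natural log by default
    return float(entropy(x))


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon index and sequencing depth."""
    rows = [
        {"sample_id": s, "shannon": shannon(table.counts[s]), "depth": int(table.counts[s].sum())}
        for s in table.sample_ids
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity matrix, d(a,b) = sum|a-b| / sum(a+b)."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if (table.sample_totals() == 0).any():
        raise ValueError("all samples must have positive totals")
    mat = table.counts.to_numpy().T.astype(float)  # samples x OTUs
    dist = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(dist, ids=table.sample_ids)
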