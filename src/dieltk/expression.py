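"""Expression time-series container, normalization, folding and interpolation.

This module is the shared data backbone of the toolkit.  Diel expression
experiments sample transcript abundance on a regular Zeitgeber-time (ZT)
grid -- typically every 3 or 4 h over 48-72 h with 2-3 biological
replicates per timepoint.  Downstream analyses need three derived views
of those data:

* gene-wise z-scores, so microarray intensities and RNA-seq FPKM live on
  a common scale;
* 24 h period-folded replicate-mean profiles (cycles beyond the first are
  treated as extra replicates at ``zt mod 24``);
* hourly linear interpolations of the folded profiles, so datasets
  sampled on 3 h and 4 h grids become directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "SampleMeta",
    "ExpressionMatrix",
    "read_expression",
    "zscore_normalize",
    "replicate_mean_profile",
    "interpolate_hourly",
    "hourly_profile",
    "hourly_profile_matrix",
    "hierarchical_order",
]

_PHOTOPERIODS = {"ND", "LD"}


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample column: ZT time (hours), replicate index,
    species tag and photoperiod (ND = 12:12, LD = 16:8)."""

    sample_id: str
    zt: float
    replicate: int
    species: str = ""
    photoperiod: str = "ND"

    def __post_init__(self) -> None:
        if not (0 <= self.zt < 72):
            raise ValueError(f"zt must lie in [0, 72): got {self.zt}")
        if self.replicate < 1:
            raise ValueError("replicate indices start at 1")
        if self.photoperiod not in _PHOTOPERIODS:
            raise ValueError(f"photoperiod must be one of {_PHOTOPERIODS}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample ZT metadata."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    normalized: bool = False
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def zts(self) -> np.ndarray:
        return np.array([s.zt for s in self.samples], dtype=float)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._index[gene]]
        except KeyError:
            raise KeyError(f"unknown gene: {gene}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def fold(self, period: float = 24.0) -> tuple[np.ndarray, list[np.ndarray]]:
        """Group sample columns by ``zt mod period``.

        Returns the sorted unique folded ZT values and, for each, the
        array of column indices observed at that circular time.
        """
        folded = np.round(self.zts % period, 9)
        uniq = np.unique(folded)
        groups = [np.flatnonzero(folded == z) for z in uniq]
        return uniq, groups

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=[s.sample_id for s in self.samples],
        )


def read_expression(path, meta_path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus its sample-metadata TSV.

    The expression table's first column is ``gene_id``; the metadata table
    must provide ``sample_id, zt, replicate, species, photoperiod`` for
    every sample column.  Samples are ordered by (zt, replicate).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    meta = meta.set_index("sample_id")
    missing = [c for c in df.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().values)[0]
        raise ValueError(
            f"non-numeric expression value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    samples = [
        SampleMeta(
            sample_id=sid,
            zt=float(meta.at[sid, "zt"]),
            replicate=int(meta.at[sid, "replicate"]),
            species=str(meta.at[sid, "species"]) if "species" in meta.columns else "",
            photoperiod=str(meta.at[sid, "photoperiod"])
            if "photoperiod" in meta.columns
            else "ND",
        )
        for sid in df.columns
    ]
    order = sorted(range(len(samples)), key=lambda i: (samples[i].zt, samples[i].replicate))
    samples = [samples[i] for i in order]
    values = bad.values[:, order]
    return ExpressionMatrix(list(df.index), samples, values, normalized=False)


def zscore_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score (sample sd, n-1 denominator).

    Constant genes cannot be scaled; they are mapped to all-zero rows and
    recorded in ``constant_genes`` so rhythm testing and network
    construction can skip them.  Normalizing twice is refused: it would
    silently destroy the constant-gene bookkeeping.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd_safe = np.where(constant[:, None], 1.0, sd)
    vals = (m.values - mu) / sd_safe
    vals[constant, :] = 0.0
    return ExpressionMatrix(
        list(m.gene_ids),
        list(m.samples),
        vals,
        normalized=True,
        constant_genes=[g for g, c in zip(m.gene_ids, constant) if c],
    )


def replicate_mean_profile(
    m: ExpressionMatrix, gene: str, period: float | None = None
) -> dict[float, float]:
    """Mean expression per distinct ZT (optionally folded at ``period``).

    With ``period`` set, cycles beyond the first act as additional
    replicates at ``zt mod period``.
    """
    row = m.row(gene)
    if period is None:
        zts = np.round(m.zts, 9)
    else:
        zts = np.round(m.zts % period, 9)
    return {float(z): float(row[zts == z].mean()) for z in np.unique(zts)}


def interpolate_hourly(profile: dict[float, float], period: float = 24.0) -> np.ndarray:
    """Linearly interpolate a folded profile onto the integer-hour grid.

    The day is treated as circular: the segment from the last observed ZT
    back to the first observed ZT (+period) fills the wrap-around gap.
    Values at observed grid hours are reproduced exactly.
    """
    if len(profile) < 2:
        raise ValueError("at least two distinct timepoints are required")
    zts = np.array(sorted(profile), dtype=float)
    if zts[0] < 0 or zts[-1] >= period:
        raise ValueError(f"profile times must lie in [0, {period})")
    vals = np.array([profile[z] for z in zts], dtype=float)
    xp = np.concatenate([zts, [zts[0] + period]])
    fp = np.concatenate([vals, [vals[0]]])
    hours = np.arange(int(period), dtype=float)
    # hours before the first observation belong to the wrap-around segment
    shifted = np.where(hours < zts[0], hours + period, hours)
    return np.interp(shifted, xp, fp)


def hourly_profile(m: ExpressionMatrix, gene: str, period: float = 24.0) -> np.ndarray:
    """Folded replicate-mean profile of ``gene`` on the hourly grid."""
    return interpolate_hourly(replicate_mean_profile(m, gene, period=period), period)


def hourly_profile_matrix(
    m: ExpressionMatrix, genes: list[str], period: float = 24.0
) -> np.ndarray:
    """Stack hourly profiles for ``genes`` into a (len(genes), period) array."""
    return np.vstack([hourly_profile(m, g, period) for g in genes]) if genes else np.empty((0, int(period)))


def hierarchical_order(m: ExpressionMatrix, genes: list[str]) -> list[str]:
    """Leaf order of an average-linkage, correlation-distance dendrogram.

    Used to sort genes by expression-profile similarity (heatmap row
    order).  Deterministic for a fixed input; constant profiles are given
    maximal distance (2.0) to everything.
    """
    if not genes:
        return []
    missing = [g for g in genes if g not in m]
    if missing:
        raise KeyError(f"unknown genes: {missing}")
    if len(genes) == 1:
        return list(genes)
    data = np.vstack([m.row(g) for g in genes])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = pdist(data, metric="correlation")
    dist = np.where(np.isfinite(dist), dist, 2.0)
    order = leaves_list(linkage(dist, method="average"))
    return [genes[i] for i in order]
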