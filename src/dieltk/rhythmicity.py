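"""Nonparametric detection of 24 h rhythmic expression and diel clustering.

The rhythm test is a phase-scanning umbrella rank statistic.  For a gene
sampled on a regular grid, observations are folded at the 24 h period so
replicates and additional cycles pool at each circular timepoint.  A
rhythmic gene rises monotonically from its trough to its peak and falls
afterwards; the Mack-Wolfe umbrella statistic measures exactly that kind
of ordered alternative from ranks alone, making the test robust to
waveform shape and to any monotone (affine or not) transformation of the
expression values.  Because the true peak phase is unknown, the statistic
is evaluated for every candidate peak position on the folded grid (the
ordering is rotated so that the assumed trough, opposite the candidate
peak, comes first) and the best phase's one-sided normal p-value is
Bonferroni-corrected by the number of phases scanned.  A small exact
permutation backend and a parametric cosinor F-test are provided as
cross-checks.

Rhythmic genes are characterised by their peak and trough ZT on the
folded replicate-mean profile and assigned to one of 16 diel clusters:
the 24 h day is partitioned into Dawn [ZT21, 3), Day [3, 9), Dusk
[9, 15) and Night [15, 21), and the cluster label is the (peak interval,
trough interval) pair.  Merging clusters by peak interval yields the
4-way summary clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, hourly_profile, replicate_mean_profile

__all__ = [
    "DIEL_INTERVALS",
    "INTERVAL_NAMES",
    "RhythmResult",
    "interval_of",
    "mack_wolfe",
    "rhythm_test",
    "peak_trough",
    "assign_cluster",
    "merge_by_peak",
    "cluster_mean_profile",
    "run_rhythm_analysis",
]

# half-open circular spans [left, right); Dawn wraps midnight-light-on
DIEL_INTERVALS: dict[str, tuple[float, float]] = {
    "Dawn": (21.0, 3.0),
    "Day": (3.0, 9.0),
    "Dusk": (9.0, 15.0),
    "Night": (15.0, 21.0),
}
INTERVAL_NAMES = tuple(DIEL_INTERVALS)


@dataclass(frozen=True)
class RhythmResult:
    gene_id: str
    p_value: float
    rhythmic: bool
    peak_zt: float | None
    trough_zt: float | None
    cluster: tuple[str, str] | None


def interval_of(zt: float) -> str:
    """Diel interval containing ``zt`` (each interval owns its left edge)."""
    z = zt % 24.0
    if z >= 21.0 or z < 3.0:
        return "Dawn"
    if z < 9.0:
        return "Day"
    if z < 15.0:
        return "Dusk"
    return "Night"


def _pairwise_u(data: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """U[g, i, j] = #{(a in i, b in j): x_b > x_a} + 0.5 * ties, per gene."""
    k = len(groups)
    n_genes = data.shape[0]
    u = np.zeros((n_genes, k, k))
    for i in range(k):
        xi = data[:, groups[i]]
        for j in range(i + 1, k):
            xj = data[:, groups[j]]
            gt = (xj[:, None, :] > xi[:, :, None]).sum(axis=(1, 2))
            eq = (xj[:, None, :] == xi[:, :, None]).sum(axis=(1, 2))
            u[:, i, j] = gt + 0.5 * eq
            u[:, j, i] = len(groups[i]) * len(groups[j]) - u[:, i, j]
    return u


def _umbrella_moments(sizes: np.ndarray, peak: int) -> tuple[float, float]:
    """Null mean and variance of the Mack-Wolfe statistic, peak at
    1-based position ``peak`` among groups of the given sizes."""
    n = np.asarray(sizes, dtype=float)
    n_p = n[peak - 1]
    n1 = n[:peak].sum()
    n2 = n[peak - 1:].sum()
    ntot = n.sum()
    mean = (n1**2 + n2**2 - (n**2).sum() - n_p**2) / 4.0
    var = (
        2 * (n1**3 + n2**3)
        + 3 * (n1**2 + n2**2)
        - (n**2 * (2 * n + 3)).sum()
        - n_p**2 * (2 * n_p + 3)
        + 12 * n_p * n1 * n2
        - 12 * n_p**2 * ntot
    ) / 72.0
    return float(mean), float(var)


def mack_wolfe(groups: list[np.ndarray], peak: int) -> tuple[float, float, float]:
    """Umbrella statistic with known peak (1-based group position).

    Returns (A, null mean, null variance).  A sums Mann-Whitney counts
    concordant with an increase up to the peak group and a decrease
    after it.
    """
    if not 1 <= peak <= len(groups):
        raise ValueError("peak position out of range")
    data = np.concatenate(groups)[None, :]
    idx, off = [], 0
    for g in groups:
        idx.append(np.arange(off, off + len(g)))
        off += len(g)
    u = _pairwise_u(data, idx)[0]
    k = len(groups)
    a = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            if j <= peak - 1:
                a += u[i, j]
            elif i >= peak - 1:
                a += u[j, i]
    mean, var = _umbrella_moments(np.array([len(g) for g in groups]), peak)
    return float(a), mean, var


def _scan_orders(k: int) -> list[tuple[list[int], int]]:
    """For each candidate peak index on the circular grid, the rotated
    group order placing the assumed trough first, plus the 1-based peak
    position inside that order (k//2 + 1, a symmetric umbrella)."""
    h = k // 2
    out = []
    for p0 in range(k):
        order = [(p0 - h + t) % k for t in range(k)]
        out.append((order, h + 1))
    return out


def _umbrella_scan_z(data: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene max standardized umbrella statistic over scanned phases,
    returned as a (n_genes, k) matrix of Z scores (one per phase)."""
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    u = _pairwise_u(data, groups)
    zs = np.empty((data.shape[0], k))
    for col, (order, peak) in enumerate(_scan_orders(k)):
        a = np.zeros(data.shape[0])
        for i in range(k):
            for j in range(i + 1, k):
                gi, gj = order[i], order[j]
                if j <= peak - 1:
                    a += u[:, gi, gj]
                elif i >= peak - 1:
                    a += u[:, gj, gi]
        mean, var = _umbrella_moments(sizes[order], peak)
        zs[:, col] = (a - mean) / np.sqrt(var) if var > 0 else 0.0
    return zs


def _fold_groups(
    zts: np.ndarray, period: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    folded = np.round(np.asarray(zts, dtype=float) % period, 9)
    uniq = np.unique(folded)
    if len(uniq) < 2:
        raise ValueError("at least two distinct timepoints per period required")
    diffs = np.diff(uniq)
    if not np.allclose(diffs, diffs[0], atol=1e-6):
        raise ValueError("irregular sampling grid after period folding")
    if not np.isclose(len(uniq) * diffs[0], period, atol=1e-6):
        raise ValueError(
            "sampling grid does not tile the period "
            f"({len(uniq)} points x {diffs[0]} h != {period} h)"
        )
    span = np.asarray(zts, dtype=float).max() - np.asarray(zts, dtype=float).min()
    if span + diffs[0] < period - 1e-6:
        raise ValueError("series does not cover one full period")
    groups = [np.flatnonzero(folded == z) for z in uniq]
    return uniq, groups


def _matrix_pvalues(
    data: np.ndarray, groups: list[np.ndarray]
) -> np.ndarray:
    zs = _umbrella_scan_z(data, groups)
    k = len(groups)
    p_best = stats.norm.sf(zs.max(axis=1))
    return np.minimum(1.0, k * p_best)


def rhythm_test(
    values: np.ndarray,
    zts: np.ndarray,
    period: float = 24.0,
    method: str = "umbrella",
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """p-value for 24 h rhythmicity of one series.

    ``values``/``zts`` are matched observation and sampling-time vectors;
    replicates and extra cycles simply repeat (folded) ZT values.

    methods: ``umbrella`` (normal approximation, default), ``permutation``
    (exact null of the max standardized umbrella statistic over phases,
    seeded) and ``cosinor`` (first-harmonic F-test cross-check).
    """
    values = np.asarray(values, dtype=float)
    zts = np.asarray(zts, dtype=float)
    if values.shape != zts.shape:
        raise ValueError("values and zts must have equal length")
    _, groups = _fold_groups(zts, period)
    data = values[None, :]
    if method == "umbrella":
        return float(_matrix_pvalues(data, groups)[0])
    if method == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        obs = _umbrella_scan_z(data, groups).max()
        perms = np.vstack(
            [rng.permutation(values) for _ in range(n_perm)]
        )
        null = _umbrella_scan_z(perms, groups).max(axis=1)
        return float((1 + np.sum(null >= obs - 1e-12)) / (n_perm + 1))
    if method == "cosinor":
        x = np.column_stack(
            [
                np.ones_like(zts),
                np.cos(2 * np.pi * zts / period),
                np.sin(2 * np.pi * zts / period),
            ]
        )
        beta, rss_full, *_ = np.linalg.lstsq(x, values, rcond=None)
        resid = values - x @ beta
        rss1 = float(resid @ resid)
        rss0 = float(np.sum((values - values.mean()) ** 2))
        df2 = len(values) - 3
        if df2 <= 0 or rss1 <= 0:
            return 1.0 if rss0 <= rss1 + 1e-12 else 0.0
        f = ((rss0 - rss1) / 2) / (rss1 / df2)
        return float(stats.f.sf(f, 2, df2))
    raise ValueError(f"unknown method: {method}")


def peak_trough(
    m: ExpressionMatrix, gene: str, period: float = 24.0
) -> tuple[float, float]:
    """Peak and trough ZT of the period-folded replicate-mean profile.

    Ties are broken toward the earliest ZT.  Constant profiles have no
    defined peak and raise.
    """
    prof = replicate_mean_profile(m, gene, period=period)
    zts = np.array(sorted(prof))
    vals = np.array([prof[z] for z in zts])
    if np.ptp(vals) == 0:
        raise ValueError(f"gene {gene}: constant profile, peak undefined")
    return float(zts[np.argmax(vals)]), float(zts[np.argmin(vals)])


def assign_cluster(peak_zt: float, trough_zt: float) -> tuple[str, str]:
    """16-way diel cluster label: (peak interval, trough interval)."""
    return interval_of(peak_zt), interval_of(trough_zt)


def merge_by_peak(
    labels: dict[str, tuple[str, str]]
) -> dict[str, list[str]]:
    """Merge the 16 clusters into 4 by peak interval; sizes are additive."""
    merged: dict[str, list[str]] = {name: [] for name in INTERVAL_NAMES}
    for gene in sorted(labels):
        merged[labels[gene][0]].append(gene)
    return merged


def cluster_mean_profile(
    members: list[str], m: ExpressionMatrix, period: float = 24.0
) -> np.ndarray:
    """Pointwise mean of member hourly profiles."""
    if not members:
        raise ValueError("empty cluster")
    return np.mean([hourly_profile(m, g, period) for g in members], axis=0)


def run_rhythm_analysis(
    m: ExpressionMatrix,
    alpha: float = 0.01,
    period: float = 24.0,
    method: str = "umbrella",
) -> pd.DataFrame:
    """Rhythm-test every gene and label the rhythmic ones.

    Returns a DataFrame indexed by gene id with columns p_value,
    rhythmic, peak_zt, trough_zt, cluster_peak, cluster_trough.  Genes
    flagged constant during normalization (or constant in the raw
    matrix) are reported arrhythmic with p = 1.
    """
    _, groups = _fold_groups(m.zts, period)
    skip = set(m.constant_genes) | {
        g for g, row in zip(m.gene_ids, m.values) if np.ptp(row) == 0
    }
    testable = [g for g in m.gene_ids if g not in skip]
    rows = {}
    if testable:
        data = np.vstack([m.row(g) for g in testable])
        if method == "umbrella":
            pvals = _matrix_pvalues(data, groups)
        else:
            pvals = np.array(
                [rhythm_test(d, m.zts, period, method=method) for d in data]
            )
        for g, p in zip(testable, pvals):
            rhythmic = bool(p < alpha)
            if rhythmic:
                pk, tr = peak_trough(m, g, period)
                cp, ct = assign_cluster(pk, tr)
            else:
                pk = tr = np.nan
                cp = ct = ""
            rows[g] = (p, rhythmic, pk, tr, cp, ct)
    for g in skip:
        rows[g] = (1.0, False, np.nan, np.nan, "", "")
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["p_value", "rhythmic", "peak_zt", "trough_zt", "cluster_peak", "cluster_trough"],
    )
    df.index.name = "gene_id"
    return df.loc[m.gene_ids]
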