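"""Cross-species conservation of diel expression: expresologues and the
Zsummary module-preservation statistic.

An *expresologue* is an orthologous gene pair whose daily expression
patterns agree: both genes are rhythmic and either fall in the same
16-way diel cluster or their hourly profiles correlate above 0.98.

Module preservation asks a stronger question: does a whole co-expression
module defined in a reference species keep its internal correlation
structure in a test species?  Following the permutation-Z composite
approach, four statistics are computed for the module's counterparts in
the test species -- two density statistics (mean intra-module
correlation; mean intra-module adjacency at the network threshold) and
two connectivity statistics (correlation of intramodular connectivity
vectors between species; correlation of the vectorized intra-module
correlation matrices) -- and each is standardized against random
same-size gene sets drawn from the test species.  Zdensity and
Zconnectivity are the medians of their two component Z scores and
Zsummary is their mean; Zsummary < 2 indicates no preservation, 2-10
moderate and > 10 high preservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, hourly_profile_matrix
from .orthology import OrthologueMap

__all__ = [
    "ExpresologuePair",
    "PreservationResult",
    "call_expresologues",
    "expresologue_cluster_enrichment",
    "zsummary",
    "resolve_one_to_one",
]


@dataclass(frozen=True)
class ExpresologuePair:
    gene_a: str
    gene_b: str
    basis: str  # SAME_CLUSTER, HIGH_CORRELATION or BOTH
    r: float


@dataclass
class PreservationResult:
    module_id: str
    z_density: float
    z_connectivity: float
    z_summary: float
    n_permutations: int

    @property
    def verdict(self) -> str:
        if self.z_summary < 2:
            return "NONE"
        if self.z_summary <= 10:
            return "MODERATE"
        return "HIGH"


def _profile_corr(pa: np.ndarray, pb: np.ndarray) -> float:
    if np.ptp(pa) == 0 or np.ptp(pb) == 0:
        return np.nan
    return float(np.corrcoef(pa, pb)[0, 1])


def call_expresologues(
    ortho: OrthologueMap,
    rhythm_a: pd.DataFrame,
    rhythm_b: pd.DataFrame,
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    r_threshold: float = 0.98,
    period: float = 24.0,
) -> list[ExpresologuePair]:
    """Keep orthologous pairs whose diel patterns agree.

    Both genes must be rhythmic; the pair is an expresologue iff it
    shares the 16-way cluster label or its hourly-profile Pearson r
    strictly exceeds ``r_threshold``.  Pairs whose genes lack a rhythm
    result are skipped with a warning.
    """
    out = []
    for pair in ortho:
        a, b = pair.gene_a, pair.gene_b
        if a not in rhythm_a.index or b not in rhythm_b.index:
            warnings.warn(f"no rhythm result for pair ({a}, {b}); skipped")
            continue
        ra, rb = rhythm_a.loc[a], rhythm_b.loc[b]
        if not (bool(ra.rhythmic) and bool(rb.rhythmic)):
            continue
        prof_a = hourly_profile_matrix(m_a, [a], period)[0]
        prof_b = hourly_profile_matrix(m_b, [b], period)[0]
        r = _profile_corr(prof_a, prof_b)
        same_cluster = (ra.cluster_peak, ra.cluster_trough) == (
            rb.cluster_peak,
            rb.cluster_trough,
        )
        high_corr = bool(np.isfinite(r) and r > r_threshold)
        if same_cluster or high_corr:
            basis = (
                "BOTH"
                if same_cluster and high_corr
                else "SAME_CLUSTER" if same_cluster else "HIGH_CORRELATION"
            )
            out.append(ExpresologuePair(a, b, basis, float(r)))
    return out


def expresologue_cluster_enrichment(
    cluster_genes: set[str],
    pairs: list[ExpresologuePair],
    background: set[str],
    side: str = "a",
) -> float:
    """One-sided Fisher exact p for expresologue over-representation in a
    cluster, against the rhythmic-gene background."""
    if not cluster_genes:
        raise ValueError("empty cluster")
    if not cluster_genes <= background:
        raise ValueError("cluster genes must be a subset of the background")
    has = {p.gene_a if side == "a" else p.gene_b for p in pairs} & background
    k = len(cluster_genes & has)
    table = [
        [k, len(cluster_genes) - k],
        [len(has) - k, len(background) - len(cluster_genes) - (len(has) - k)],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def resolve_one_to_one(
    ortho: OrthologueMap,
    module: list[str],
    m_ref: ExpressionMatrix,
    m_test: ExpressionMatrix,
    period: float = 24.0,
) -> dict[str, str]:
    """Map each module gene to a single test-species counterpart.

    Genes with several orthologues take the partner with the highest
    hourly-profile correlation (avoids double counting); genes without
    any mapped partner are omitted.
    """
    out = {}
    for g in module:
        candidates = [t for t in sorted(ortho.targets_of(g)) if t in m_test]
        if not candidates or g not in m_ref:
            continue
        if len(candidates) == 1:
            out[g] = candidates[0]
            continue
        prof = hourly_profile_matrix(m_ref, [g], period)[0]
        cand_profs = hourly_profile_matrix(m_test, candidates, period)
        rs = [_profile_corr(prof, cp) for cp in cand_profs]
        out[g] = candidates[int(np.nanargmax(rs))]
    return out


def _module_stats(
    r_ref: np.ndarray, r_test: np.ndarray, adjacency_threshold: float
) -> np.ndarray:
    """(density: mean cor, mean adjacency; connectivity: kIM cor, cor-matrix cor)."""
    d = r_ref.shape[0]
    iu = np.triu_indices(d, k=1)
    mean_cor = r_test[iu].mean()
    mean_adj = (r_test[iu] > adjacency_threshold).mean()
    kim_ref = r_ref.sum(axis=1) - 1.0
    kim_test = r_test.sum(axis=1) - 1.0
    c_kim = _safe_corr(kim_ref, kim_test)
    c_cor = _safe_corr(r_ref[iu], r_test[iu])
    return np.array([mean_cor, mean_adj, c_kim, c_cor])


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def zsummary(
    module: list[str],
    m_ref: ExpressionMatrix,
    m_test: ExpressionMatrix,
    correspondence: dict[str, str],
    n_perm: int = 200,
    seed: int | None = None,
    adjacency_threshold: float = 0.95,
    period: float = 24.0,
    module_id: str = "module",
) -> PreservationResult:
    """Permutation-Z composite preservation of ``module`` in the test species.

    ``correspondence`` maps module genes (reference ids) to their test
    counterparts; see :func:`resolve_one_to_one`.  The permutation null
    redraws the test-side gene set (same size) uniformly from the test
    matrix with the reference side fixed.
    """
    mapped = [g for g in module if g in correspondence]
    if len(mapped) < 5:
        raise ValueError(
            f"module must map >= 5 genes into the test species; got {len(mapped)}"
        )
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    test_ids = [correspondence[g] for g in mapped]
    prof_ref = hourly_profile_matrix(m_ref, mapped, period)
    prof_test = hourly_profile_matrix(m_test, test_ids, period)
    r_ref = np.corrcoef(prof_ref)
    r_test = np.corrcoef(prof_test)
    observed = _module_stats(r_ref, r_test, adjacency_threshold)

    pool = [g for g in m_test.gene_ids if g not in set(m_test.constant_genes)]
    pool_profs = hourly_profile_matrix(m_test, pool, period)
    pool_profs = pool_profs[np.ptp(pool_profs, axis=1) > 0]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, 4))
    d = len(mapped)
    for b in range(n_perm):
        idx = rng.choice(len(pool_profs), size=d, replace=False)
        r_perm = np.corrcoef(pool_profs[idx])
        null[b] = _module_stats(r_ref, r_perm, adjacency_threshold)

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.empty(4)
    for i in range(4):
        if sd[i] == 0:
            warnings.warn("zero permutation sd; Z set to +inf")
            z[i] = np.inf if observed[i] > mean[i] else -np.inf
        else:
            z[i] = (observed[i] - mean[i]) / sd[i]
    z_density = float(np.median(z[:2]))
    z_connectivity = float(np.median(z[2:]))
    return PreservationResult(
        module_id=module_id,
        z_density=z_density,
        z_connectivity=z_connectivity,
        z_summary=(z_density + z_connectivity) / 2.0,
        n_permutations=n_perm,
    )
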