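"""Functional enrichment: Fisher-exact GO-term over-representation and
hypergeometric pathway enrichment, both with Benjamini-Hochberg control.

Per-term tests are "classic" (no ontology-graph decorrelation): each
term's annotated genes are contrasted against the whole-genome
background in a one-sided 2x2 test.  Terms whose annotated-in-set gene
lists coincide exactly are collapsed to one representative row, removing
the most blatant redundancy among nested terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "EnrichmentRow",
    "read_annotations",
    "fisher_enrichment",
    "pathway_enrichment",
    "bh_adjust",
    "collapse_redundant",
]


@dataclass
class AnnotationTable:
    """term_id -> annotated gene set, plus optional human-readable labels."""

    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def restrict(self, universe: set[str]) -> "AnnotationTable":
        return AnnotationTable(
            {t: g & universe for t, g in self.terms.items()}, dict(self.labels)
        )


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    label: str
    k: int  # set genes with term
    K: int  # background genes with term
    n: int  # set size
    N: int  # universe size
    p_value: float
    q_value: float
    significant: bool

    @property
    def ratio(self) -> str:
        """k/K, the paper-style 'in-set / total annotated' ratio."""
        return f"{self.k}/{self.K}"


def read_annotations(path) -> AnnotationTable:
    """Annotation TSV: gene_id, term_id[, term_label]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    label_col = df.columns[2] if len(df.columns) > 2 else None
    for r in df.itertuples(index=False):
        gene, term = r[0], r[1]
        terms.setdefault(term, set()).add(gene)
        if label_col is not None:
            labels[term] = r[2]
    return AnnotationTable(terms, labels)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _enrich(
    gene_set: set[str],
    annotations: AnnotationTable,
    universe: set[str],
    tail,
    alpha: float,
    use_q: bool,
) -> list[EnrichmentRow]:
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    ann = annotations.restrict(universe)
    n, n_univ = len(gene_set), len(universe)
    rows = []
    for term in sorted(ann.terms):
        genes = ann.terms[term]
        big_k = len(genes)
        if big_k == 0:
            continue
        k = len(genes & gene_set)
        p = tail(k, big_k, n, n_univ)
        rows.append((term, k, big_k, p))
    if not rows:
        return []
    qs = bh_adjust([r[3] for r in rows])
    out = [
        EnrichmentRow(
            term_id=term,
            label=annotations.labels.get(term, term),
            k=k,
            K=big_k,
            n=n,
            N=n_univ,
            p_value=float(p),
            q_value=float(q),
            significant=bool((q if use_q else p) < alpha),
        )
        for (term, k, big_k, p), q in zip(rows, qs)
    ]
    return sorted(out, key=lambda r: (r.p_value, r.term_id))


def _fisher_tail(k: int, big_k: int, n: int, n_univ: int) -> float:
    table = [[k, n - k], [big_k - k, n_univ - big_k - (n - k)]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _hypergeom_tail(k: int, big_k: int, n: int, n_univ: int) -> float:
    return float(stats.hypergeom.sf(k - 1, n_univ, big_k, n))


def fisher_enrichment(
    gene_set: set[str],
    annotations: AnnotationTable,
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """One-sided Fisher exact over-representation per term, flagged at
    p < ``alpha``, sorted by ascending p."""
    return _enrich(gene_set, annotations, universe, _fisher_tail, alpha, use_q=False)


def pathway_enrichment(
    gene_set: set[str],
    pathway_table: AnnotationTable,
    universe: set[str],
    q_cutoff: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation per pathway, BH-adjusted and
    filtered at q < ``q_cutoff``."""
    rows = _enrich(
        gene_set, pathway_table, universe, _hypergeom_tail, q_cutoff, use_q=True
    )
    return [r for r in rows if r.significant]


def collapse_redundant(
    rows: list[EnrichmentRow],
    annotations: AnnotationTable,
    gene_set: set[str],
) -> list[EnrichmentRow]:
    """Merge terms whose annotated-in-set gene lists coincide exactly,
    keeping the most significant representative of each group."""
    seen: dict[frozenset[str], EnrichmentRow] = {}
    for row in rows:  # rows are sorted by ascending p
        sig = frozenset(annotations.terms.get(row.term_id, set()) & gene_set)
        if sig not in seen:
            seen[sig] = row
    return sorted(seen.values(), key=lambda r: (r.p_value, r.term_id))


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.label, r.k, r.K, r.n, r.N, r.p_value, r.q_value, r.significant)
            for r in rows
        ],
        columns=["term_id", "label", "k", "K", "n", "N", "p", "q", "significant"],
    )
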