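"""Multiple Bidirectional Best Hit (MBBH) orthology with domain filtering.

Classical Bidirectional Best Hit (BBH) orthology breaks down between
distantly related species with very unequal gene-family sizes: when one
ancestral gene expanded into a large family in one lineage, only a single
family member can be the reciprocal best hit.  MBBH generalises BBH by
keeping, for every query protein, its N best global-alignment hits in the
other proteome ("initial best hits"), requiring reciprocity within those
top-N lists, and then discarding reciprocal pairs that do not share at
least one annotated protein domain.  Proteins left without any MBBH
partner can still be assigned putative orthologues through an exact
domain-architecture match (same domains, same order, same count).

Alignment scores are optimal global (Needleman-Wunsch) affine-gap scores
under a configurable substitution matrix, BLOSUM62 with gap open 10 /
extend 0.5 by default.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "Proteome",
    "DomainHit",
    "DomainArchitecture",
    "OrthoPair",
    "OrthologueMap",
    "ScoringConfig",
    "align_score",
    "top_n_hits",
    "mbbh",
    "architecture_orthologues",
    "family_size_stats",
    "read_fasta_proteome",
    "read_domain_table",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}


@dataclass
class Proteome:
    """A species tag plus a protein_id -> amino-acid sequence map."""

    species: str
    records: dict[str, str]

    def __post_init__(self) -> None:
        for pid, seq in self.records.items():
            if not seq:
                raise ValueError(f"{self.species}:{pid}: empty sequence")
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"{self.species}:{pid}: illegal residue(s) {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DomainHit:
    domain_id: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad domain coordinates: {self}")


@dataclass
class DomainArchitecture:
    """Ordered, non-overlapping domain hits along one protein."""

    protein_id: str
    hits: list[DomainHit]

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: h.start)
        for a, b in itertools.pairwise(self.hits):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.protein_id}: overlapping domains {a} / {b}"
                )

    @property
    def domain_ids(self) -> tuple[str, ...]:
        """Domain ids in positional order (the architecture signature)."""
        return tuple(h.domain_id for h in self.hits)

    @property
    def domain_set(self) -> frozenset[str]:
        return frozenset(h.domain_id for h in self.hits)


@dataclass(frozen=True)
class OrthoPair:
    gene_a: str
    gene_b: str
    evidence: str  # "MBBH" or "ARCHITECTURE"
    score: float | None = None


@dataclass
class OrthologueMap:
    pairs: list[OrthoPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            key = (p.gene_a, p.gene_b)
            if key in seen:
                raise ValueError(f"duplicate orthologue pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def pair_set(self) -> set[tuple[str, str]]:
        return {(p.gene_a, p.gene_b) for p in self.pairs}

    def genes_a(self) -> set[str]:
        return {p.gene_a for p in self.pairs}

    def genes_b(self) -> set[str]:
        return {p.gene_b for p in self.pairs}

    def targets_of(self, gene: str, direction: str = "a2b") -> set[str]:
        if direction == "a2b":
            return {p.gene_b for p in self.pairs if p.gene_a == gene}
        return {p.gene_a for p in self.pairs if p.gene_b == gene}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.gene_a, p.gene_b, p.evidence, p.score) for p in self.pairs],
            columns=["gene_a", "gene_b", "evidence", "score"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "OrthologueMap":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        return cls(
            [
                OrthoPair(
                    r.gene_a,
                    r.gene_b,
                    r.evidence,
                    None if pd.isna(r.score) else float(r.score),
                )
                for r in df.itertuples()
            ]
        )


@dataclass(frozen=True)
class ScoringConfig:
    """Global-alignment scoring parameters.

    ``gap_open`` is the penalty for the first residue of a gap and
    ``gap_extend`` for each further residue (both subtracted).  X scores
    0 against every residue, a neutral treatment of ambiguity codes.
    ``normalize`` divides the raw score by the shorter sequence length.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    normalize: bool = False


def _build_aligner(config: ScoringConfig) -> Align.PairwiseAligner:
    sub = substitution_matrices.load(config.matrix)
    sub = sub.copy()
    if "X" in sub.alphabet:
        i = sub.alphabet.index("X")
        sub[i, :] = 0.0
        sub[:, i] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


_ALIGNER_CACHE: dict[ScoringConfig, Align.PairwiseAligner] = {}


def align_score(seq_a: str, seq_b: str, config: ScoringConfig | None = None) -> float:
    """Optimal global affine-gap alignment score between two proteins."""
    config = config or ScoringConfig()
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"illegal residue(s): {sorted(bad)}")
    if config not in _ALIGNER_CACHE:
        _ALIGNER_CACHE[config] = _build_aligner(config)
    score = float(_ALIGNER_CACHE[config].score(seq_a, seq_b))
    if config.normalize:
        score /= min(len(seq_a), len(seq_b))
    return score


def _score_table(
    source: Proteome, target: Proteome, config: ScoringConfig
) -> dict[str, dict[str, float]]:
    return {
        q: {t: align_score(qs, ts, config) for t, ts in target.records.items()}
        for q, qs in source.records.items()
    }


def _rank(scores: dict[str, float], n: int) -> list[tuple[str, float]]:
    # deterministic tie rule: higher score first, then lexicographic id
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def top_n_hits(
    query: str,
    source: Proteome,
    target: Proteome,
    n: int,
    config: ScoringConfig | None = None,
) -> list[tuple[str, float]]:
    """The ``n`` best-scoring target proteins for ``query`` ("initial
    best hits").  Targets smaller than ``n`` return everything ranked."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if query not in source.records:
        raise KeyError(f"unknown query protein: {query}")
    config = config or ScoringConfig()
    qs = source.records[query]
    scores = {t: align_score(qs, ts, config) for t, ts in target.records.items()}
    return _rank(scores, n)


def _shares_domain(
    p: str,
    q: str,
    dom_a: dict[str, DomainArchitecture],
    dom_b: dict[str, DomainArchitecture],
    keep_unannotated: bool,
) -> bool:
    arch_p = dom_a.get(p)
    arch_q = dom_b.get(q)
    if arch_p is None or arch_q is None or not arch_p.hits or not arch_q.hits:
        # Pfam coverage is incomplete; the filter is inapplicable, not failed
        return keep_unannotated
    return bool(arch_p.domain_set & arch_q.domain_set)


def mbbh(
    a: Proteome,
    b: Proteome,
    n: int = 20,
    dom_a: dict[str, DomainArchitecture] | None = None,
    dom_b: dict[str, DomainArchitecture] | None = None,
    config: ScoringConfig | None = None,
    keep_unannotated: bool = True,
) -> OrthologueMap:
    """Multiple Bidirectional Best Hit orthologue detection.

    A pair (p, q) is emitted iff q is among p's top-``n`` hits in b, p is
    among q's top-``n`` hits in a, and p and q share at least one domain
    id (pairs where either member lacks any annotation pass the filter
    when ``keep_unannotated``).  Scores stored are a->b alignment scores.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or ScoringConfig()
    dom_a = dom_a or {}
    dom_b = dom_b or {}
    ab = _score_table(a, b, config)
    top_ab = {p: {t for t, _ in _rank(ab[p], n)} for p in a.records}
    top_ba = {
        q: {t for t, _ in _rank({p: ab[p][q] for p in a.records}, n)}
        for q in b.records
    }
    pairs = [
        OrthoPair(p, q, "MBBH", ab[p][q])
        for p in sorted(a.records)
        for q in sorted(top_ab[p])
        if p in top_ba[q] and _shares_domain(p, q, dom_a, dom_b, keep_unannotated)
    ]
    return OrthologueMap(pairs)


def architecture_orthologues(
    orphans_a: set[str],
    dom_a: dict[str, DomainArchitecture],
    dom_b: dict[str, DomainArchitecture],
    min_arch_len: int = 1,
) -> OrthologueMap:
    """Domain-architecture fallback for proteins without an MBBH partner.

    A pair is emitted iff the ordered domain-id tuples match exactly
    (same domains, same order, same count).  ``min_arch_len`` can exclude
    single-domain architectures, whose match is weaker evidence (widely
    shared domains do not pin down orthology on their own).
    """
    by_arch: dict[tuple[str, ...], list[str]] = {}
    for q, arch in dom_b.items():
        sig = arch.domain_ids
        if len(sig) >= min_arch_len and sig:
            by_arch.setdefault(sig, []).append(q)
    pairs = []
    for p in sorted(orphans_a):
        arch = dom_a.get(p)
        if arch is None or len(arch.domain_ids) < max(min_arch_len, 1):
            continue
        for q in sorted(by_arch.get(arch.domain_ids, [])):
            pairs.append(OrthoPair(p, q, "ARCHITECTURE", None))
    return OrthologueMap(pairs)


def family_size_stats(
    omap: OrthologueMap, direction: str = "a2b"
) -> tuple[float, Counter]:
    """Mean number of targets per source gene with >= 1 target, plus the
    full target-count histogram.  Measures gene-family amplification."""
    if len(omap) == 0:
        raise ValueError("empty orthologue map")
    counts = Counter()
    for p in omap:
        src = p.gene_a if direction == "a2b" else p.gene_b
        counts[src] += 1
    hist = Counter(counts.values())
    mean = sum(counts.values()) / len(counts)
    return mean, hist


def read_fasta_proteome(path, species: str) -> Proteome:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate protein id {rec.id} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return Proteome(species, records)


def read_domain_table(path) -> dict[str, DomainArchitecture]:
    """Domain TSV: protein_id, domain_id, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_id": str})
    out: dict[str, DomainArchitecture] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        hits = [
            DomainHit(r.domain_id, int(r.start), int(r.end)) for r in grp.itertuples()
        ]
        out[str(pid)] = DomainArchitecture(str(pid), hits)
    return out
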