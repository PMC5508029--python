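"""Seeded generators for proteome, domain and diel-expression fixtures.

The generators emulate the features of real comparative diel datasets
that the analysis modules are sensitive to: gene families with unequal
duplication counts and shared or lineage-exclusive domain architectures;
and diel expression with a controllable rhythmic fraction, cosine-like
waveforms with adjustable peak sharpness, set peak phases, replicate
noise and 3 h / 4 h sampling grids over 24-72 h.  Every generator emits
a ground-truth table so downstream modules can be scored without any
external data, and every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleMeta
from .orthology import DomainArchitecture, DomainHit, Proteome

__all__ = [
    "FamilySpec",
    "ProteomeSpec",
    "DielSpec",
    "make_proteomes",
    "make_diel_expression",
    "make_preserved_module_pair",
    "diel_waveform",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FamilySpec:
    """One ancestral gene family: its length, per-species copy numbers
    (0 = absent: a lineage-exclusive family), the per-copy substitution
    rate and the shared domain architecture."""

    name: str
    length: int = 120
    copies: dict[str, int] = field(default_factory=dict)
    rate: float = 0.05
    domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 0.9):
            raise ValueError("substitution rate must lie in [0, 0.9]")
        if any(c < 0 for c in self.copies.values()):
            raise ValueError("copy numbers must be >= 0")
        if self.length < 10:
            raise ValueError("family length must be >= 10")

    def __hash__(self):  # copies dict is conceptually frozen
        return hash((self.name, self.length, tuple(sorted(self.copies.items())), self.rate, self.domains))


@dataclass(frozen=True)
class ProteomeSpec:
    families: tuple[FamilySpec, ...]
    seed: int = 0


@dataclass(frozen=True)
class DielSpec:
    """Design of a simulated diel expression experiment.

    Defaults mirror a typical plant diel RNA profiling design: 48 h of
    sampling every 4 h with 3 replicates, half the transcriptome
    rhythmic, unit-amplitude cosine waveforms and replicate noise sd 0.5
    (signal-to-noise 2, a clearly rhythmic transcript).  Arrhythmic
    genes are pure Gaussian noise with the same sd scaled to 1.
    """

    n_genes: int = 100
    rhythmic_fraction: float = 0.5
    amplitude: float = 1.0
    noise_sd: float = 0.5
    sharpness: float = 1.0
    replicates: int = 3
    interval: float = 4.0
    span: float = 48.0
    phases: tuple[float, ...] | None = None  # None: uniform random in [0, 24)
    species: str = "synthetic"
    photoperiod: str = "ND"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rhythmic_fraction <= 1.0):
            raise ValueError("rhythmic_fraction must lie in [0, 1]")
        if self.interval <= 0 or self.span <= 0:
            raise ValueError("interval and span must be positive")
        if abs(self.span / self.interval - round(self.span / self.interval)) > 1e-9:
            raise ValueError("span must be a multiple of the sampling interval")
        if not (24.0 - 1e-9 <= self.span <= 72.0 + 1e-9):
            raise ValueError("span must lie in [24, 72] h")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.phases is not None and any(not 0 <= p < 24 for p in self.phases):
            raise ValueError("phases must lie in [0, 24)")


def _domain_hits(domains: tuple[str, ...], length: int) -> list[DomainHit]:
    if not domains:
        return []
    seg = length // len(domains)
    hits = []
    for j, dom in enumerate(domains):
        start = j * seg + 1
        end = min(start + max(seg - 3, 1) - 1, length)
        hits.append(DomainHit(dom, start, end))
    return hits


def make_proteomes(
    spec: ProteomeSpec,
) -> tuple[dict[str, Proteome], dict[str, dict[str, DomainArchitecture]], pd.DataFrame]:
    """Generate per-species proteomes, domain tables and a truth table.

    Each family descends from one uniform-random ancestor; every copy
    substitutes a ``rate`` fraction of positions independently.  The
    truth table lists (family, species, protein_id) so orthologous
    groups can be recovered exactly.
    """
    rng = np.random.default_rng(spec.seed)
    species = sorted({s for f in spec.families for s in f.copies})
    records: dict[str, dict[str, str]] = {s: {} for s in species}
    domains: dict[str, dict[str, DomainArchitecture]] = {s: {} for s in species}
    truth_rows = []
    for fam in spec.families:
        ancestor = rng.choice(_AA, size=fam.length)
        hits = _domain_hits(fam.domains, fam.length)
        for sp in species:
            for c in range(fam.copies.get(sp, 0)):
                seq = ancestor.copy()
                mutate = rng.random(fam.length) < fam.rate
                n_mut = int(mutate.sum())
                if n_mut:
                    # substitute with a uniformly chosen *different* residue
                    repl = rng.choice(_AA, size=n_mut)
                    same = repl == seq[mutate]
                    while same.any():
                        repl[same] = rng.choice(_AA, size=int(same.sum()))
                        same = repl == seq[mutate]
                    seq[mutate] = repl
                pid = f"{sp}_{fam.name}_{c + 1}"
                records[sp][pid] = "".join(seq)
                if hits:
                    domains[sp][pid] = DomainArchitecture(pid, list(hits))
                truth_rows.append((fam.name, sp, pid))
    proteomes = {s: Proteome(s, records[s]) for s in species}
    truth = pd.DataFrame(truth_rows, columns=["family", "species", "protein_id"])
    return proteomes, domains, truth


def diel_waveform(
    zt: np.ndarray, phase: float, amplitude: float = 1.0, sharpness: float = 1.0
) -> np.ndarray:
    """Sign-preserving sharpened cosine peaking at ``phase``.

    sharpness > 1 narrows the peak (sign(c) * |c|**sharpness), emulating
    transcripts with narrow versus broad expression peaks.
    """
    c = np.cos(2 * np.pi * (np.asarray(zt, dtype=float) - phase) / 24.0)
    return amplitude * np.sign(c) * np.abs(c) ** sharpness


def _sample_grid(spec: DielSpec) -> list[SampleMeta]:
    samples = []
    for zt in np.arange(0.0, spec.span, spec.interval):
        for rep in range(1, spec.replicates + 1):
            samples.append(
                SampleMeta(
                    sample_id=f"ZT{zt:g}_r{rep}",
                    zt=float(zt),
                    replicate=rep,
                    species=spec.species,
                    photoperiod=spec.photoperiod,
                )
            )
    return samples


def make_diel_expression(spec: DielSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a diel expression matrix plus a gene-level truth table.

    The first ``round(n_genes * rhythmic_fraction)`` genes are rhythmic:
    waveform(zt - phase) plus N(0, noise_sd) per observation.  The rest
    are arrhythmic: pure N(0, 1) noise.  Truth columns: gene_id,
    rhythmic, phase.
    """
    rng = np.random.default_rng(spec.seed)
    samples = _sample_grid(spec)
    zts = np.array([s.zt for s in samples])
    n_rhythmic = int(round(spec.n_genes * spec.rhythmic_fraction))
    gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    if spec.phases is None:
        phases = rng.uniform(0.0, 24.0, size=n_rhythmic)
    else:
        phases = np.array(
            [spec.phases[i % len(spec.phases)] for i in range(n_rhythmic)]
        )
    values = np.empty((spec.n_genes, len(samples)))
    for i in range(spec.n_genes):
        if i < n_rhythmic:
            signal = diel_waveform(zts, phases[i], spec.amplitude, spec.sharpness)
            values[i] = signal + rng.normal(0.0, spec.noise_sd, size=len(samples))
        else:
            values[i] = rng.normal(0.0, 1.0, size=len(samples))
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "rhythmic": [i < n_rhythmic for i in range(spec.n_genes)],
            "phase": [float(phases[i]) if i < n_rhythmic else np.nan for i in range(spec.n_genes)],
        }
    )
    matrix = ExpressionMatrix(gene_ids, samples, values, normalized=False)
    return matrix, truth


def make_preserved_module_pair(
    size: int = 50,
    n_background: int = 450,
    noise_ref: float = 0.2,
    noise_test: float = 0.2,
    preserved: bool = True,
    seed: int = 0,
    interval_ref: float = 4.0,
    interval_test: float = 3.0,
    span: float = 48.0,
    replicates: int = 3,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str], dict[str, str]]:
    """Reference/test expression-matrix pair for module preservation.

    Module genes share one seeded cosine waveform (plus independent
    Gaussian noise) in the reference species; in the test species they
    either follow the same waveform (``preserved``) or are replaced by
    independent unit-variance noise.  Background genes are rhythmic with
    uniform random phases in both species.  Returns (m_ref, m_test,
    module gene ids, ref->test correspondence).
    """
    if size < 5:
        raise ValueError("module size must be >= 5")
    rng = np.random.default_rng(seed)
    base_phase = float(rng.uniform(0.0, 24.0))

    def build(prefix: str, interval: float, noise: float, module_rhythmic: bool, rs) -> ExpressionMatrix:
        spec = DielSpec(
            n_genes=1, interval=interval, span=span, replicates=replicates,
            species=prefix,
        )
        samples = _sample_grid(spec)
        zts = np.array([s.zt for s in samples])
        gene_ids = [f"{prefix}_M{i + 1:04d}" for i in range(size)] + [
            f"{prefix}_B{i + 1:04d}" for i in range(n_background)
        ]
        values = np.empty((size + n_background, len(samples)))
        for i in range(size):
            if module_rhythmic:
                values[i] = diel_waveform(zts, base_phase) + rs.normal(
                    0.0, noise, size=len(samples)
                )
            else:
                values[i] = rs.normal(0.0, 1.0, size=len(samples))
        for i in range(n_background):
            phase = rs.uniform(0.0, 24.0)
            values[size + i] = diel_waveform(zts, phase) + rs.normal(
                0.0, noise, size=len(samples)
            )
        return ExpressionMatrix(gene_ids, samples, values, normalized=False)

    m_ref = build("ref", interval_ref, noise_ref, True, rng)
    m_test = build("test", interval_test, noise_test, preserved, rng)
    module = [f"ref_M{i + 1:04d}" for i in range(size)]
    correspondence = {f"ref_M{i + 1:04d}": f"test_M{i + 1:04d}" for i in range(size)}
    return m_ref, m_test, module, correspondence
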