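"""Shared fixtures: small seeded expression matrices, toy proteomes and
a coherent two-species dataset for the integration tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dieltk.expression import ExpressionMatrix, SampleMeta
from dieltk.orthology import DomainArchitecture, DomainHit, Proteome
from dieltk.synthetic import DielSpec, diel_waveform, make_diel_expression


def grid_samples(interval=4.0, span=48.0, replicates=3, species="sp"):
    return [
        SampleMeta(f"ZT{zt:g}_r{r}", float(zt), r, species)
        for zt in np.arange(0.0, span, interval)
        for r in range(1, replicates + 1)
    ]


@pytest.fixture
def small_matrix():
    """20 genes x (6 ZT x 2 reps), half rhythmic, seeded."""
    m, truth = make_diel_expression(
        DielSpec(n_genes=20, rhythmic_fraction=0.5, replicates=2, seed=5)
    )
    return m, truth


@pytest.fixture
def toy_proteomes():
    """Two tiny proteomes with an obvious correspondence and domains."""
    seqs_a = {
        "a1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
        "a2": "MSSHHHHLLLEDEDGDGDVVVTTTAAAKKKQQ",
        "a3": "MWWWCCCPPPGGGFFFYYYLLLIIIVVVSSTT",
    }
    seqs_b = {
        "b1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVR",
        "b2": "MSSHHHHLLLEDEDGDGDVVVTTTAAAKKKQE",
        "b3": "MWWWCCCPPPGGGFFFYYYLLLIIIVVVSSTA",
    }
    dom_a = {
        "a1": DomainArchitecture("a1", [DomainHit("PF001", 1, 15)]),
        "a2": DomainArchitecture("a2", [DomainHit("PF002", 1, 15)]),
        "a3": DomainArchitecture("a3", [DomainHit("PF003", 1, 15)]),
    }
    dom_b = {
        "b1": DomainArchitecture("b1", [DomainHit("PF001", 1, 15)]),
        "b2": DomainArchitecture("b2", [DomainHit("PF002", 1, 15)]),
        "b3": DomainArchitecture("b3", [DomainHit("PF003", 1, 15)]),
    }
    return Proteome("a", seqs_a), Proteome("b", seqs_b), dom_a, dom_b


def phase_cohort_matrix(
    phases, genes_per_cohort=5, interval=3.0, span=24.0, replicates=1,
    noise_sd=0.0, jitter=0.0, seed=0, prefix="g",
):
    """Cosine genes grouped in phase cohorts, optional jitter and noise."""
    rng = np.random.default_rng(seed)
    samples = grid_samples(interval, span, replicates)
    zts = np.array([s.zt for s in samples])
    ids, rows, cohort = [], [], {}
    for ci, phase in enumerate(phases):
        for gi in range(genes_per_cohort):
            gid = f"{prefix}{ci}_{gi}"
            ids.append(gid)
            cohort[gid] = ci
            ph = phase + rng.uniform(-jitter, jitter)
            rows.append(
                diel_waveform(zts, ph) + rng.normal(0, noise_sd, zts.size)
            )
    m = ExpressionMatrix(ids, samples, np.vstack(rows))
    return m, cohort


FAMILY_PHASE = {"fam1": 12.0, "fam2": 0.0, "fam3": 6.0, "fam4": 18.0}


def expression_for_proteome(protein_ids, interval, seed, n_noise=6):
    """Diel expression keyed to a proteome: family members share a phase,
    plus unannotated arrhythmic noise genes."""
    rng = np.random.default_rng(seed)
    samples = grid_samples(interval=interval, span=48.0, replicates=2)
    zts = np.array([s.zt for s in samples])
    ids, rows = [], []
    for pid in protein_ids:
        fam = pid.split("_")[1]
        ids.append(pid)
        rows.append(
            diel_waveform(zts, FAMILY_PHASE[fam]) + rng.normal(0, 0.3, zts.size)
        )
    for i in range(n_noise):
        ids.append(f"noise{i}")
        rows.append(rng.normal(0, 1, zts.size))
    return ExpressionMatrix(ids, samples, np.vstack(rows))


@pytest.fixture(scope="session")
def two_species_inputs(tmp_path_factory):
    """On-disk inputs for a coherent two-species comparative run:
    FASTA + domain tables from the proteome generator and expression
    matrices whose gene ids are the protein ids."""
    from dieltk.cli import write_expression_tsv
    from dieltk.synthetic import FamilySpec, ProteomeSpec, make_proteomes

    root = tmp_path_factory.mktemp("fixture")
    spec = ProteomeSpec(
        (
            FamilySpec("fam1", 60, {"spa": 6, "spb": 6}, 0.04, ("PF1",)),
            FamilySpec("fam2", 60, {"spa": 2, "spb": 4}, 0.04, ("PF2", "PF3")),
            FamilySpec("fam3", 60, {"spa": 1, "spb": 1}, 0.04, ("PF4",)),
            FamilySpec("fam4", 60, {"spa": 2}, 0.04, ("PF5",)),
        ),
        seed=71,
    )
    proteomes, domains, truth = make_proteomes(spec)
    paths = {}
    for sp, interval, eseed in (("spa", 4.0, 72), ("spb", 3.0, 73)):
        fasta = root / f"{sp}.fasta"
        fasta.write_text(
            "".join(f">{p}\n{s}\n" for p, s in proteomes[sp].records.items())
        )
        dom = root / f"{sp}_domains.tsv"
        pd.DataFrame(
            [
                (pid, h.domain_id, h.start, h.end)
                for pid, arch in domains[sp].items()
                for h in arch.hits
            ],
            columns=["protein_id", "domain_id", "start", "end"],
        ).to_csv(dom, sep="\t", index=False)
        m = expression_for_proteome(list(proteomes[sp].records), interval, eseed)
        write_expression_tsv(m, root / f"{sp}_expr.tsv", root / f"{sp}_meta.tsv")
        paths[sp] = {
            "name": sp,
            "fasta": str(fasta),
            "domains": str(dom),
            "expression": str(root / f"{sp}_expr.tsv"),
            "metadata": str(root / f"{sp}_meta.tsv"),
        }
    anno = root / "spa_go.tsv"
    fam1 = [p for p in proteomes["spa"].records if "_fam1_" in p]
    fam23 = [p for p in proteomes["spa"].records if "_fam2_" in p or "_fam3_" in p]
    pd.DataFrame(
        [(g, "GO:0000001", "dusk peaking") for g in fam1]
        + [(g, "GO:0000002", "dawn machinery") for g in fam23],
        columns=["gene_id", "term_id", "term_label"],
    ).to_csv(anno, sep="\t", index=False)
    paths["spa"]["annotations"] = str(anno)
    return root, paths


def pipeline_config(root, paths, name="config.yaml", seed=7, **overrides):
    import yaml

    params = dict(n=6, alpha=0.01, n_random=50, n_perm=50, seed=seed)
    params.update(overrides)
    cfg = {"species_a": paths["spa"], "species_b": paths["spb"], "params": params}
    path = root / name
    path.write_text(yaml.safe_dump(cfg))
    return path


def write_matrix(m: ExpressionMatrix, expr_path, meta_path):
    m.to_frame().to_csv(expr_path, sep="\t")
    pd.DataFrame(
        [(s.sample_id, s.zt, s.replicate, s.species, s.photoperiod) for s in m.samples],
        columns=["sample_id", "zt", "replicate", "species", "photoperiod"],
    ).to_csv(meta_path, sep="\t", index=False)
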