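"""MBBH orthology: alignment scoring, top-N ranking, reciprocity,
domain filtering and the architecture fallback."""

import numpy as np
import pytest

from dieltk.orthology import (
    DomainArchitecture,
    DomainHit,
    OrthologueMap,
    OrthoPair,
    Proteome,
    ScoringConfig,
    align_score,
    architecture_orthologues,
    family_size_stats,
    mbbh,
    read_domain_table,
    read_fasta_proteome,
    top_n_hits,
)
from dieltk.synthetic import FamilySpec, ProteomeSpec, make_proteomes
from oracles import enumerate_global_score, mbbh_oracle, substitution_score


class TestAlignScore:
    def test_single_residue_blosum_entry(self):
        assert align_score("A", "A") == 4.0

    def test_self_alignment_is_diagonal_sum(self):
        seq = "MKTAYIAKQR"
        expected = sum(substitution_score(c, c) for c in seq)
        assert align_score(seq, seq) == pytest.approx(expected)

    def test_symmetry(self):
        a, b = "MKTAYI", "MKAYIR"
        assert align_score(a, b) == align_score(b, a)

    def test_x_scores_zero(self):
        assert align_score("X", "W") == 0.0
        assert align_score("X", "X") == 0.0

    def test_illegal_residue_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            align_score("MK1", "MK")
        with pytest.raises(ValueError):
            align_score("", "MK")

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            la, lb = rng.integers(3, 7, size=2)
            a = "".join(rng.choice(aas, la))
            b = "".join(rng.choice(aas, lb))
            assert align_score(a, b) == pytest.approx(
                enumerate_global_score(a, b)
            ), (a, b)

    def test_normalized_mode(self):
        cfg = ScoringConfig(normalize=True)
        assert align_score("AA", "AA", cfg) == pytest.approx(4.0)


class TestTopN:
    def test_small_target_returns_all(self, toy_proteomes):
        a, b, *_ = toy_proteomes
        hits = top_n_hits("a1", a, b, n=20)
        assert len(hits) == 3
        assert hits[0][0] == "b1"  # near-identical sequence ranks first

    def test_scores_non_increasing_and_tie_rule(self):
        a = Proteome("a", {"q": "MKTAYI"})
        b = Proteome("b", {"t2": "MKTAYI", "t1": "MKTAYI", "t3": "WWWWWW"})
        hits = top_n_hits("q", a, b, n=2)
        assert [h[0] for h in hits] == ["t1", "t2"]  # lexicographic on ties
        scores = [h[1] for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_matches_bruteforce_ranking(self):
        proteomes, _, _ = make_proteomes(
            ProteomeSpec(
                (
                    FamilySpec("f1", 40, {"s1": 1, "s2": 4}, 0.1),
                    FamilySpec("f2", 40, {"s1": 1, "s2": 4}, 0.1),
                ),
                seed=3,
            )
        )
        src, tgt = proteomes["s1"], proteomes["s2"]
        for q in src.records:
            hits = top_n_hits(q, src, tgt, n=3)
            scores = {t: align_score(src.records[q], s) for t, s in tgt.records.items()}
            expected = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
            assert hits == expected

    def test_invalid_n_and_query(self, toy_proteomes):
        a, b, *_ = toy_proteomes
        with pytest.raises(ValueError):
            top_n_hits("a1", a, b, n=0)
        with pytest.raises(KeyError):
            top_n_hits("zz", a, b, n=1)


def _synthetic_pair(seed=0, rate=0.05):
    proteomes, domains, truth = make_proteomes(
        ProteomeSpec(
            (
                FamilySpec("f1", 50, {"s1": 2, "s2": 3}, rate, ("PF001",)),
                FamilySpec("f2", 50, {"s1": 1, "s2": 4}, rate, ("PF002", "PF003")),
                FamilySpec("f3", 50, {"s1": 3, "s2": 3}, rate, ("PF004",)),
            ),
            seed=seed,
        )
    )
    return proteomes["s1"], proteomes["s2"], domains["s1"], domains["s2"]


class TestMBBH:
    def test_identical_proteomes_self_map(self, toy_proteomes):
        a, _, dom_a, _ = toy_proteomes
        b = Proteome("b", dict(a.records))
        omap = mbbh(a, b, n=1, dom_a=dom_a, dom_b=dom_a)
        assert {(p.gene_a, p.gene_b) for p in omap} == {
            (g, g) for g in a.records
        }

    def test_reciprocal_pair_without_shared_domain_removed(self):
        a = Proteome("a", {"p": "MKTAYIAKQR"})
        b = Proteome("b", {"q": "MKTAYIAKQR"})
        dom_a = {"p": DomainArchitecture("p", [DomainHit("PF001", 1, 5)])}
        dom_b = {"q": DomainArchitecture("q", [DomainHit("PF999", 1, 5)])}
        assert len(mbbh(a, b, n=1, dom_a=dom_a, dom_b=dom_b)) == 0

    def test_unannotated_member_passes_filter_by_default(self):
        a = Proteome("a", {"p": "MKTAYIAKQR"})
        b = Proteome("b", {"q": "MKTAYIAKQR"})
        dom_a = {"p": DomainArchitecture("p", [DomainHit("PF001", 1, 5)])}
        assert len(mbbh(a, b, n=1, dom_a=dom_a, dom_b={})) == 1
        assert len(mbbh(a, b, n=1, dom_a=dom_a, dom_b={}, keep_unannotated=False)) == 0

    def test_matches_bruteforce_oracle(self):
        a, b, dom_a, dom_b = _synthetic_pair(seed=1)
        scores = {
            (p, q): align_score(a.records[p], b.records[q])
            for p in a.records
            for q in b.records
        }
        for n in (1, 2, 5):
            got = mbbh(a, b, n=n, dom_a=dom_a, dom_b=dom_b).pair_set()
            want = mbbh_oracle(
                lambda p, q: scores[(p, q)],
                sorted(a.records),
                sorted(b.records),
                n,
                dom_a,
                dom_b,
            )
            assert got == want

    def test_n1_without_domains_is_classical_bbh(self):
        a, b, *_ = _synthetic_pair(seed=2)
        got = mbbh(a, b, n=1).pair_set()
        # classical BBH oracle: unique argmax both ways
        scores = {
            (p, q): align_score(a.records[p], b.records[q])
            for p in a.records
            for q in b.records
        }
        want = set()
        for p in a.records:
            best_q = min(b.records, key=lambda q: (-scores[(p, q)], q))
            best_p = min(a.records, key=lambda x: (-scores[(x, best_q)], x))
            if best_p == p:
                want.add((p, best_q))
        assert got == want

    def test_monotone_in_n(self):
        a, b, dom_a, dom_b = _synthetic_pair(seed=4)
        sets = [
            mbbh(a, b, n=n, dom_a=dom_a, dom_b=dom_b).pair_set() for n in (1, 2, 4, 8)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_invariant_under_input_order(self):
        a, b, dom_a, dom_b = _synthetic_pair(seed=5)
        a_rev = Proteome("s1", dict(reversed(list(a.records.items()))))
        b_rev = Proteome("s2", dict(reversed(list(b.records.items()))))
        assert (
            mbbh(a, b, n=2, dom_a=dom_a, dom_b=dom_b).pair_set()
            == mbbh(a_rev, b_rev, n=2, dom_a=dom_a, dom_b=dom_b).pair_set()
        )

    def test_invalid_n(self, toy_proteomes):
        a, b, *_ = toy_proteomes
        with pytest.raises(ValueError):
            mbbh(a, b, n=0)


class TestArchitectureFallback:
    def _arch(self, pid, *domains):
        hits = [
            DomainHit(d, 10 * i + 1, 10 * i + 8) for i, d in enumerate(domains)
        ]
        return DomainArchitecture(pid, hits)

    def test_exact_tuple_match(self):
        dom_a = {"p": self._arch("p", "PF00010", "PF00011")}
        dom_b = {"q": self._arch("q", "PF00010", "PF00011")}
        pairs = architecture_orthologues({"p"}, dom_a, dom_b).pair_set()
        assert pairs == {("p", "q")}

    def test_order_matters(self):
        dom_a = {"p": self._arch("p", "PF00010", "PF00011")}
        dom_b = {"q": self._arch("q", "PF00011", "PF00010")}
        assert len(architecture_orthologues({"p"}, dom_a, dom_b)) == 0

    def test_min_arch_len_excludes_single_domain(self):
        dom_a = {"p": self._arch("p", "PF00010")}
        dom_b = {"q": self._arch("q", "PF00010")}
        assert len(architecture_orthologues({"p"}, dom_a, dom_b)) == 1
        assert (
            len(architecture_orthologues({"p"}, dom_a, dom_b, min_arch_len=2)) == 0
        )

    def test_shuffled_fixture_matches_tuple_equality_oracle(self):
        rng = np.random.default_rng(8)
        pool = ["PF1", "PF2", "PF3"]
        dom_a, dom_b = {}, {}
        for i in range(12):
            sig = tuple(rng.choice(pool, size=rng.integers(1, 4)))
            (dom_a if i < 6 else dom_b)[f"p{i}"] = self._arch(f"p{i}", *sig)
        got = architecture_orthologues(set(dom_a), dom_a, dom_b).pair_set()
        want = {
            (p, q)
            for p in dom_a
            for q in dom_b
            if dom_a[p].domain_ids == dom_b[q].domain_ids
        }
        assert got == want

    def test_no_annotation_means_no_match(self):
        assert len(architecture_orthologues({"p"}, {}, {})) == 0


class TestFamilySize:
    def test_one_to_one_mean(self):
        omap = OrthologueMap([OrthoPair("a1", "b1", "MBBH", 1.0)])
        mean, hist = family_size_stats(omap)
        assert mean == 1.0
        assert hist == {1: 1}

    def test_mixed_counts(self):
        omap = OrthologueMap(
            [
                OrthoPair("a1", "b1", "MBBH", 1.0),
                OrthoPair("a1", "b2", "MBBH", 1.0),
                OrthoPair("a2", "b3", "MBBH", 1.0),
            ]
        )
        mean, hist = family_size_stats(omap)
        assert mean == 1.5
        assert hist == {2: 1, 1: 1}

    def test_random_map_vs_independent_counting(self):
        rng = np.random.default_rng(9)
        pairs = {
            (f"a{rng.integers(5)}", f"b{rng.integers(20)}") for _ in range(30)
        }
        omap = OrthologueMap([OrthoPair(a, b, "MBBH", 0.0) for a, b in pairs])
        mean, _ = family_size_stats(omap)
        per_source = {}
        for a, b in pairs:
            per_source.setdefault(a, set()).add(b)
        assert mean == pytest.approx(
            sum(len(v) for v in per_source.values()) / len(per_source)
        )

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            family_size_stats(OrthologueMap([]))


class TestIO:
    def test_fasta_and_domain_roundtrip(self, tmp_path, toy_proteomes):
        a, _, dom_a, _ = toy_proteomes
        fasta = tmp_path / "a.fasta"
        fasta.write_text(
            "".join(f">{pid}\n{seq}\n" for pid, seq in a.records.items())
        )
        loaded = read_fasta_proteome(fasta, "a")
        assert loaded.records == a.records
        dom_tsv = tmp_path / "a_dom.tsv"
        rows = ["protein_id\tdomain_id\tstart\tend"]
        for pid, arch in dom_a.items():
            rows += [f"{pid}\t{h.domain_id}\t{h.start}\t{h.end}" for h in arch.hits]
        dom_tsv.write_text("\n".join(rows) + "\n")
        loaded_dom = read_domain_table(dom_tsv)
        assert {p: a.domain_ids for p, a in loaded_dom.items()} == {
            p: a.domain_ids for p, a in dom_a.items()
        }

    def test_orthomap_tsv_roundtrip(self, tmp_path):
        omap = OrthologueMap(
            [OrthoPair("a1", "b1", "MBBH", 12.5), OrthoPair("a2", "b2", "ARCHITECTURE", None)]
        )
        path = tmp_path / "o.tsv"
        omap.write_tsv(path)
        back = OrthologueMap.read_tsv(path)
        assert back.pair_set() == omap.pair_set()

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainArchitecture("p", [DomainHit("A", 1, 10), DomainHit("B", 5, 20)])

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            OrthologueMap(
                [OrthoPair("a", "b", "MBBH", 1.0), OrthoPair("a", "b", "MBBH", 2.0)]
            )
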