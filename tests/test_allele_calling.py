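"""Clone collapsing, chimera screening, divergence and diagnostic SNPs."""

import numpy as np
import pytest

from caninascope.allele_calling import (
    CloneAlignment,
    collapse_clones,
    detect_chimeras,
    find_diagnostic_snps,
    pairwise_divergence,
)

BASES = "ACGT"


def _random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def _mutate_at(seq, positions, rng):
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in BASES if b != s[p]])
    return "".join(s)


def _make_alignment(seqs, names=None, locus="loc", mask=None):
    names = names or [f"c{i}" for i in range(len(seqs))]
    L = len(seqs[0])
    return CloneAlignment(locus, names, list(seqs), coding_mask=mask or [(0, L - L % 3)])


class TestCollapseClones:
    def test_identical_clones_one_allele(self, rng):
        seq = _random_seq(rng, 300)
        alleles = collapse_clones(_make_alignment([seq] * 20))
        assert len(alleles.labels) == 1
        assert alleles.support[alleles.labels[0]] == 20
        assert alleles.consensi[alleles.labels[0]] == seq

    def test_two_well_separated_groups(self, rng):
        a = _random_seq(rng, 600)
        b = _mutate_at(a, rng.choice(600, size=30, replace=False), rng)
        alleles = collapse_clones(_make_alignment([a] * 10 + [b] * 10), max_intra_allele_diff=4)
        assert len(alleles.labels) == 2
        assert sorted(alleles.support.values()) == [10, 10]

    def test_planted_singleton_flagged(self, rng):
        base = _random_seq(rng, 600)
        groups = [base]
        for _ in range(2):
            groups.append(_mutate_at(base, rng.choice(600, size=25, replace=False), rng))
        seqs, names = [], []
        for gi, g in enumerate(groups):
            for c in range(5):
                seqs.append(g)
                names.append(f"g{gi}c{c}")
        # a 1-substitution error variant joins its parent cluster under
        # single linkage; a sequence far from every group is the flagged
        # singleton
        lone = _mutate_at(base, rng.choice(600, size=40, replace=False), rng)
        seqs.append(lone)
        names.append("lone")
        alleles = collapse_clones(_make_alignment(seqs, names), min_clones=2)
        assert len(alleles.labels) == 3
        assert alleles.singletons == ["lone"]

    def test_order_invariance(self, rng):
        a = _random_seq(rng, 400)
        b = _mutate_at(a, rng.choice(400, size=20, replace=False), rng)
        seqs = [a] * 6 + [b] * 4
        names = [f"c{i}" for i in range(10)]
        fwd = collapse_clones(_make_alignment(seqs, names))
        perm = np.random.default_rng(0).permutation(10)
        rev = collapse_clones(
            _make_alignment([seqs[i] for i in perm], [names[i] for i in perm])
        )
        assert fwd.consensi == rev.consensi
        assert fwd.support == rev.support

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            CloneAlignment("loc", [], [])


class TestPairwiseDivergence:
    def test_identity(self, rng):
        s = _random_seq(rng, 500)
        assert pairwise_divergence(s, s) == 0.0

    def test_two_in_thousand(self, rng):
        a = _random_seq(rng, 1000)
        b = _mutate_at(a, [10, 500], rng)
        assert pairwise_divergence(a, b) == pytest.approx(0.2)

    def test_gap_columns_fully_excluded(self):
        a = "AC--GT"
        b = "ACTTGA"
        # compared columns: 0,1,4,5 -> one mismatch at 5
        assert pairwise_divergence(a, b) == pytest.approx(100 / 4)

    def test_against_naive_column_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(30, 120))
            a = list(_random_seq(rng, n))
            b = list(_random_seq(rng, n))
            for i in range(n):  # sprinkle gaps
                if rng.random() < 0.05:
                    a[i] = "-"
                if rng.random() < 0.05:
                    b[i] = "-"
            a, b = "".join(a), "".join(b)
            num = den = 0
            for x, y in zip(a, b):
                if "-" in (x, y):
                    continue
                den += 1
                num += x != y
            want = 100 * num / den if den else 0.0
            assert pairwise_divergence(a, b) == pytest.approx(want)
            assert pairwise_divergence(b, a) == pytest.approx(pairwise_divergence(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_divergence("ACGT", "ACG")


def _two_allele_set(rng, L=900, ndiff=20):
    a = _random_seq(rng, L)
    pos = sorted(rng.choice(L, size=ndiff, replace=False))
    b = _mutate_at(a, pos, rng)
    aln = _make_alignment([a] * 5 + [b] * 5)
    return a, b, collapse_clones(aln), aln


class TestDetectChimeras:
    def test_consensus_clone_is_clean(self, rng):
        a, b, alleles, aln = _two_allele_set(rng)
        reports = detect_chimeras(aln, alleles)
        assert all(r.verdict == "clean" for r in reports)

    def test_constructed_chimera_recovered_with_breakpoint(self, rng):
        a, b, alleles, _ = _two_allele_set(rng, L=900, ndiff=24)
        chimera = a[:600] + b[600:]
        aln = _make_alignment([a] * 5 + [b] * 5 + [chimera],
                              names=[f"c{i}" for i in range(10)] + ["chi"])
        report = {r.clone: r for r in detect_chimeras(aln, alleles)}["chi"]
        assert report.verdict == "chimeric"
        lo, hi = report.breakpoint
        assert lo <= 600 <= hi

    def test_planted_chimeras_always_flagged(self, rng):
        # both flanks carry ample diagnostic sites, so the mosaic's
        # improvement always clears the evidence threshold
        for trial in range(10):
            a = _random_seq(rng, 600)
            pos = np.concatenate([rng.choice(300, 8, replace=False),
                                  300 + rng.choice(300, 8, replace=False)])
            b = _mutate_at(a, pos, rng)
            alleles = collapse_clones(_make_alignment([a] * 5 + [b] * 5))
            chimera = a[:300] + b[300:]
            aln = _make_alignment([a] * 5 + [b] * 5 + [chimera],
                                  names=[f"c{i}" for i in range(10)] + ["chi"])
            report = {r.clone: r for r in detect_chimeras(aln, alleles)}["chi"]
            assert report.verdict == "chimeric"

    def test_false_positive_rate_on_noisy_clean_clones(self, rng):
        a, b, alleles, _ = _two_allele_set(rng, L=1000, ndiff=25)
        n = 200
        seqs, names = [], []
        for i in range(n):
            parent = a if i % 2 == 0 else b
            errs = np.flatnonzero(rng.random(1000) < 0.001)
            seqs.append(_mutate_at(parent, errs, rng))
            names.append(f"n{i}")
        aln = _make_alignment(seqs, names)
        reports = detect_chimeras(aln, alleles)
        fp = sum(r.verdict == "chimeric" for r in reports) / n
        assert fp < 0.05


class TestFindDiagnosticSnps:
    def test_singleton_carrier_found(self):
        seqs = {
            "x-1": "AAAAAAAGAAAAAA",
            "x-2": "AAAAAAAAAAAAAA",
            "x-3": "AAAAAAAAAAAAAA",
            "x-4": "AAAAAAAAAAAAAA",
        }
        from caninascope.allele_calling import AlleleSet
        alleles = AlleleSet("x", seqs, {k: 5 for k in seqs}, {}, [])
        snps = find_diagnostic_snps(alleles, [(0, 12)])
        assert len(snps) == 1
        assert snps[0].position == 7
        assert snps[0].diagnostic_base == "G"
        assert snps[0].carrier_alleles == frozenset({"x-1"})

    def test_shared_carrier_pair(self):
        seqs = {
            "x-1": "AAAAAAATAAAAAA",
            "x-2": "AAAAAAATAAAAAA",
            "x-3": "AAAAAAAAAAAAAA",
            "x-4": "AAAAAAAAAAAAAA",
        }
        from caninascope.allele_calling import AlleleSet
        alleles = AlleleSet("x", seqs, {k: 5 for k in seqs}, {}, [])
        snps = find_diagnostic_snps(alleles, [(0, 12)])
        assert len(snps) == 1
        # a 2-vs-2 split: either complementary pair is a valid assay
        assert snps[0].carrier_alleles in (
            frozenset({"x-1", "x-2"}), frozenset({"x-3", "x-4"})
        )

    def test_monomorphic_alignment_gives_empty_list(self):
        from caninascope.allele_calling import AlleleSet
        seqs = {"x-1": "ACGTACGTACGT", "x-2": "ACGTACGTACGT"}
        alleles = AlleleSet("x", seqs, {k: 5 for k in seqs}, {}, [])
        assert find_diagnostic_snps(alleles, [(0, 12)]) == []

    def test_emitted_positions_inside_mask_and_gap_free(self, rng):
        a = _random_seq(rng, 300)
        b = _mutate_at(a, rng.choice(300, size=12, replace=False), rng)
        from caninascope.allele_calling import AlleleSet
        alleles = AlleleSet("x", {"x-1": a, "x-2": b}, {"x-1": 5, "x-2": 5}, {}, [])
        mask = [(30, 240)]
        for snp in find_diagnostic_snps(alleles, mask):
            assert 30 <= snp.position < 240
            assert a[snp.position] != "-" and b[snp.position] != "-"
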