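"""Codon-level dN/dS machinery against exhaustive and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from symcore import selection as sel


def brute_profile(codon):
    """Independent neighbour enumeration against the genetic code."""
    syn = nonsyn = stop = 0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        nb = codon[:pos] + base + codon[pos + 1 :]
        if sel.GENETIC_CODE[nb] == "*":
            stop += 1
        elif sel.GENETIC_CODE[nb] == sel.GENETIC_CODE[codon]:
            syn += 1
        else:
            nonsyn += 1
    return syn, nonsyn, stop


class TestCodonProfile:
    def test_alanine_theoretical_ratio(self):
        p = sel.codon_profile("GCT")
        assert (p.syn_neighbors, p.syn_fraction) == (3, pytest.approx(1 / 3))

    def test_tryptophan_has_no_synonymous_neighbors(self):
        p = sel.codon_profile("TGG")
        assert p.syn_neighbors == 0
        assert p.stop_neighbors == 2
        assert p.syn_fraction == 0.0

    def test_every_sense_codon_matches_brute_force(self):
        total = 0
        for codon in sel.SENSE_CODONS:
            p = sel.codon_profile(codon)
            assert (
                p.syn_neighbors,
                p.nonsyn_neighbors,
                p.stop_neighbors,
            ) == brute_profile(codon)
            assert p.syn_neighbors + p.nonsyn_neighbors + p.stop_neighbors == 9
            total += 9
        assert total == 549

    @pytest.mark.parametrize("bad", ["TAA", "TGA", "TAG", "AC", "ACGT", "AXG"])
    def test_rejects_stops_and_invalid(self, bad):
        with pytest.raises(ValueError):
            sel.codon_profile(bad)


def pathway_oracle(a, b):
    """Explicit pathway enumeration, written independently of the library."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, steps, ok = a, [], True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if sel.GENETIC_CODE[nxt] == "*":
                ok = False
                break
            steps.append(sel.GENETIC_CODE[cur] == sel.GENETIC_CODE[nxt])
            cur = nxt
        if ok:
            results.append((sum(steps), len(steps) - sum(steps)))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestCodonPairDiffs:
    def test_identical(self):
        assert sel.codon_pair_diffs("GCT", "GCT") == (0.0, 0.0)

    def test_single_step(self):
        assert sel.codon_pair_diffs("GCT", "GCA") == (1.0, 0.0)
        assert sel.codon_pair_diffs("TTT", "TTA") == (0.0, 1.0)

    def test_two_step_pathway_average(self):
        assert sel.codon_pair_diffs("TTT", "GTA") == pytest.approx(
            pathway_oracle("TTT", "GTA")
        )

    def test_all_sense_pairs_match_pathway_oracle(self):
        rng = np.random.default_rng(7)
        idx = rng.integers(0, 61, size=(300, 2))
        for i, j in idx:
            a, b = sel.SENSE_CODONS[i], sel.SENSE_CODONS[j]
            expected = pathway_oracle(a, b)
            got = sel.codon_pair_diffs(a, b)
            if expected is not None:
                assert got == pytest.approx(expected)
            else:
                # blocked pathways fall back to position-wise classification
                assert got[0] + got[1] == sum(
                    x != y for x, y in zip(a, b)
                )


def naive_gene_dnds(row_a, row_b):
    """Brute-force reimplementation: explicit codon loop, no lookup tables."""
    sd = nd = s_sites = 0.0
    n_codons = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if sel.GENETIC_CODE[ca] == "*" or sel.GENETIC_CODE[cb] == "*":
            continue
        n_codons += 1
        diff = pathway_oracle(ca, cb)
        if diff is None:
            syn = nonsyn = 0
            for pos in range(3):
                if ca[pos] == cb[pos]:
                    continue
                nxt = ca[:pos] + cb[pos] + ca[pos + 1 :]
                if (
                    sel.GENETIC_CODE[nxt] == "*"
                    or sel.GENETIC_CODE[nxt] != sel.GENETIC_CODE[ca]
                ):
                    nonsyn += 1
                else:
                    syn += 1
            diff = (syn, nonsyn)
        sd += diff[0]
        nd += diff[1]
        fa = brute_profile(ca)
        fb = brute_profile(cb)
        sfa = fa[0] / (fa[0] + fa[1])
        sfb = fb[0] / (fb[0] + fb[1])
        s_sites += 3 * (sfa + sfb) / 2
    if n_codons == 0:
        return math.nan
    n_sites = 3 * n_codons - s_sites
    ps, pn = sd / s_sites, nd / n_sites
    if ps >= 0.75 or pn >= 0.75:
        return math.nan
    ds = -0.75 * math.log(1 - 4 * ps / 3)
    dn = -0.75 * math.log(1 - 4 * pn / 3)
    if ds <= 0:
        return math.nan
    return dn / ds


def random_codon_rows(rng, n_codons, p_sub):
    a = "".join(
        sel.SENSE_CODONS[i] for i in rng.integers(0, 61, size=n_codons)
    )
    b = list(a)
    for i in rng.integers(0, 3 * n_codons, size=rng.poisson(3 * n_codons * p_sub)):
        b[i] = "ACGT"[rng.integers(0, 4)]
    b = "".join(b)
    # knock stop codons back to the original
    fixed = []
    for i in range(0, len(b), 3):
        cb = b[i : i + 3]
        fixed.append(a[i : i + 3] if sel.GENETIC_CODE.get(cb) == "*" else cb)
    return a, "".join(fixed)


class TestGeneDnds:
    def test_identical_rows_undefined(self):
        row = "GCTAAA" * 30
        assert math.isnan(sel.gene_dnds_pair(row, row))

    def test_pure_synonymous_ratio_zero(self):
        # 100 codons, two synonymous changes only
        a = "GCT" + "AAA" * 99
        b = "GCC" + "AAA" * 98 + "AAG"
        assert sel.gene_dnds_pair(a, b) == 0.0

    def test_matches_naive_oracle_on_random_pairs(self, rng):
        for _ in range(30):
            a, b = random_codon_rows(rng, 200, 0.05)
            got = sel.gene_dnds_pair(a, b)
            want = naive_gene_dnds(a, b)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-9)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_codon_rows(rng, 120, 0.08)
            x, y = sel.gene_dnds_pair(a, b), sel.gene_dnds_pair(b, a)
            assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y)

    def test_gap_and_n_codons_skipped(self):
        a = "GCT" + "AAA" * 9
        b = "GC-" + "AAA" * 8 + "ANA"
        # both irregular codons skipped -> no differences, undefined
        assert math.isnan(sel.gene_dnds_pair(a, b))

    def test_frame_violation_raises(self):
        with pytest.raises(ValueError):
            sel.gene_dnds_pair("GCTA", "GCTA")


class TestGeneMeanDnds:
    def test_mean_excludes_undefined(self):
        order = ["a", "b", "c"]
        m = np.array(
            [
                [np.nan, 1.0, 2.0],
                [1.0, np.nan, np.nan],
                [2.0, np.nan, np.nan],
            ]
        )
        assert sel.gene_mean_dnds(m, order, order) == pytest.approx(1.5)

    def test_all_undefined_is_excluded(self):
        order = ["a", "b"]
        m = np.full((2, 2), np.nan)
        assert math.isnan(sel.gene_mean_dnds(m, order, order))

    def test_matches_brute_force_on_fixture(self, rng):
        n = 6
        m = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.8:
                    m[i, j] = m[j, i] = rng.random() * 2
        order = [f"s{i}" for i in range(n)]
        vals = [
            m[i, j]
            for i in range(n)
            for j in range(i + 1, n)
            if not np.isnan(m[i, j])
        ]
        assert sel.gene_mean_dnds(m, order, order) == pytest.approx(
            np.mean(vals)
        )


class TestClassifySelection:
    @pytest.mark.parametrize(
        "mean,se,label",
        [(1.571, 0.050, "D"), (1.013, 0.026, "N"), (1.009, 0.142, "N"), (0.272, 0.111, "P")],
    )
    def test_published_style_intervals(self, mean, se, label):
        assert sel.classify_selection(mean, se) == label

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            sel.classify_selection(1.0, -0.1)
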