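"""IUPAC scanning and hypergeometric enrichment."""

from itertools import product
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pifdawn import (
    MotifDefinition,
    PipelineError,
    category_enrichment,
    enrich_gene_set,
    genes_with_motif,
    hypergeom_enrichment,
    reverse_complement,
    scan_motif,
)
from pifdawn.motifs import IUPAC_CODES

GBOX = MotifDefinition("GBOX", "CACGTG")
PBE = MotifDefinition("PBE", "CACATG")
EXT = MotifDefinition("EXT", "CACRTGGG")
ABRE = MotifDefinition("ABRE", "ACGTGGC")


def expand_iupac(iupac):
    return ["".join(w) for w in product(*(IUPAC_CODES[c] for c in iupac))]


def scan_oracle(seq, motif):
    """Expand the pattern to concrete words; substring-search each, both
    strands, at every offset."""
    seq = seq.upper()
    hits = set()
    words = expand_iupac(motif.iupac)
    for i in range(len(seq) - len(motif.iupac) + 1):
        window = seq[i : i + len(motif.iupac)]
        if window in words:
            hits.add((i, "+"))
        if not motif.is_palindromic and reverse_complement(window) in words:
            hits.add((i, "-"))
    return sorted(hits)


class TestScanMotif:
    def test_palindrome_reports_single_site(self):
        assert scan_motif("AACACGTGTT", GBOX) == [(2, "+")]

    def test_pbe_minus_strand_site(self):
        # revcomp(CACATG) = CATGTG, present at offset 2
        assert scan_motif("AACATGTGTT", PBE) == [(2, "-")]

    def test_extended_element_expansions(self):
        assert scan_motif("CACGTGGG", EXT) == [(0, "+")]
        assert scan_motif("CACATGGG", EXT) == [(0, "+")]
        for other in ("CACCTGGG", "CACTTGGG"):
            assert all(s != "+" for _, s in scan_motif(other, EXT))

    def test_overlapping_matches_all_reported(self):
        m = MotifDefinition("AA", "AA")
        assert [pos for pos, _ in scan_motif("AAAA", m)] == [0, 1, 2]

    def test_sequence_n_matches_only_motif_n(self):
        assert scan_motif("CANGTG", GBOX) == []
        m = MotifDefinition("anymid", "CANGTG")
        assert (0, "+") in scan_motif("CANGTG", m)
        assert (0, "+") in scan_motif("CACGTG", m)

    def test_invalid_letter_named_in_error(self):
        with pytest.raises(PipelineError, match="'U'"):
            MotifDefinition("bad", "CACGUG")
        with pytest.raises(PipelineError):
            scan_motif("", GBOX)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=8, max_size=120))
    @pytest.mark.parametrize("motif", [GBOX, PBE, EXT, ABRE], ids=lambda m: m.name)
    def test_matches_expand_and_substring_oracle(self, motif, seq):
        assert scan_motif(seq, motif) == scan_oracle(seq, motif)


class TestGenesWithMotif:
    def test_exact_promoter_included(self):
        assert genes_with_motif({"g1": "CACGTG", "g2": "AAAAAA"}, GBOX) == {"g1"}

    def test_minus_strand_counts(self):
        assert genes_with_motif({"g1": "TTCATGTGTT"}, PBE) == {"g1"}

    def test_background_rate_matches_closed_form(self, rng):
        n, length = 1000, 100
        bases = np.array(list("ACGT"))
        promoters = {
            f"g{i}": "".join(rng.choice(bases, size=length)) for i in range(n)
        }
        # CACGTG is its own reverse complement, so minus-strand hits
        # coincide with plus-strand hits: L-5 windows, no factor 2
        hits = len(genes_with_motif(promoters, GBOX))
        p_hit = 1.0 - (1.0 - 4.0 ** -6) ** (length - 5)
        sd = np.sqrt(n * p_hit * (1 - p_hit))
        assert abs(hits - n * p_hit) <= 3 * sd


def hypergeom_oracle(k, n, K, N):
    """Brute-force upper tail from the counting definition."""
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1)) / comb(
        N, n
    )


class TestHypergeom:
    @pytest.mark.parametrize(
        "k, n, K, N, expected",
        [
            (5, 5, 10, 10, 1.0),            # every background gene has the motif
            (3, 5, 4, 10, 66 / 252),        # C(4,3)C(6,2)+C(4,4)C(6,1) over C(10,5)
            (0, 5, 4, 10, 1.0),             # full tail
        ],
    )
    def test_worked_examples(self, k, n, K, N, expected):
        assert hypergeom_enrichment(k, n, K, N) == pytest.approx(expected, abs=1e-12)

    def test_bound_violations_rejected(self):
        for bad in [(6, 5, 4, 10), (3, 11, 4, 10), (3, 5, 11, 10), (-1, 5, 4, 10)]:
            with pytest.raises(PipelineError):
                hypergeom_enrichment(*bad)

    def test_complement_identity(self):
        from scipy.stats import hypergeom

        for (k, n, K, N) in [(3, 8, 5, 20), (1, 4, 10, 25), (7, 10, 12, 30)]:
            upper = hypergeom_enrichment(k, n, K, N)
            lower = hypergeom.cdf(k - 1, N, K, n)
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_enrichment(k, 10, 12, 30) for k in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(1, 30))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        assert hypergeom_enrichment(k, n, K, N) == pytest.approx(
            hypergeom_oracle(k, n, K, N), abs=1e-12
        )


class TestEnrichGeneSet:
    def _promoters(self):
        return {
            "g1": "CACGTGAA",
            "g2": "AACACGTG",
            "g3": "AAAAAAAA",
            "g4": "TTCATGTG",   # PBE on minus strand
        }

    def test_self_enrichment_is_null(self):
        prom = self._promoters()
        (res,) = enrich_gene_set(prom, [GBOX], set(prom), set(prom))
        assert res.k / res.n == res.K / res.N
        assert res.p_value >= 0.5

    def test_missing_promoter_rejected(self):
        with pytest.raises(PipelineError, match="g9"):
            enrich_gene_set(self._promoters(), [GBOX], {"g1"}, {"g1", "g9"})

    def test_set_outside_background_rejected(self):
        with pytest.raises(PipelineError):
            enrich_gene_set(self._promoters(), [GBOX], {"g1", "g9"}, {"g1", "g2"})

    def test_composite_union_vs_cooccurrence(self):
        prom = self._promoters()
        comps = {"GBOX+PBE": ["GBOX", "PBE"]}
        (gb, pbe, union) = enrich_gene_set(
            prom, [GBOX, PBE], set(prom), set(prom), composites=comps
        )
        assert union.K == 3  # g1, g2 (G-box) + g4 (PBE)
        (_, _, both) = enrich_gene_set(
            prom, [GBOX, PBE], set(prom), set(prom),
            composites=comps, composite_mode="all",
        )
        assert both.K == 0


class TestCategoryEnrichment:
    def test_category_covering_everything_is_null(self):
        ann = {f"g{i}": ["all"] for i in range(10)}
        (res,) = category_enrichment(ann, {"g0", "g1"}, set(ann))
        assert res.p_value == pytest.approx(1.0)

    def test_category_exactly_the_set_is_most_extreme_table(self):
        N, n = 12, 4
        background = {f"g{i}" for i in range(N)}
        gene_set = {f"g{i}" for i in range(n)}
        ann = {g: ["hit"] for g in gene_set}
        (res,) = category_enrichment(ann, gene_set, background)
        assert res.p_value == pytest.approx(1 / comb(N, n), abs=1e-15)

    def test_empty_category_gives_p_one(self):
        background = {"g0", "g1", "g2"}
        ann = {"outside": ["ghost"], "g0": ["real"]}
        results = {r.name: r for r in category_enrichment(ann, {"g0"}, background)}
        assert results["ghost"].k == 0
        assert results["ghost"].p_value == 1.0
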