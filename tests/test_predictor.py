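"""Frequencies, evolutionary distances, landscape assembly and variants."""

import numpy as np
import pytest

from mutland.conservation import ConservationProfile, SequenceTree, conservation_profile
from mutland.predictor import (
    AA_INDEX,
    AMINO_ACIDS,
    REDUCED_ALPHABET_11,
    VariantError,
    combined_score,
    evolutionary_distance,
    parse_mutant,
    reduced_class_map,
    reduced_frequencies,
    single_landscape,
)

from conftest import make_alignment, random_alignment


def flat_profile(aln, levels=None):
    """Conservation profile with prescribed levels (uniform by default)."""
    if levels is None:
        levels = np.ones(aln.L)
    tree = SequenceTree(linkage=np.empty((0, 4)), n_leaves=aln.n)
    return ConservationProfile(levels=np.asarray(levels, float), tree=tree, m_min=2)


class TestReducedFrequencies:
    def test_pure_column_class_frequency_one(self):
        aln = make_alignment(["LA", "LA", "LA"])
        ft = reduced_frequencies(aln, pseudocount=0.0)
        cmap = reduced_class_map()
        assert ft.reduced[0, cmap["L"]] == 1.0

    def test_same_class_symbols_merge(self):
        aln = make_alignment(["DA", "EA", "DA", "EA"])
        ft = reduced_frequencies(aln, pseudocount=0.0)
        cmap = reduced_class_map()
        assert ft.reduced[0, cmap["D"]] == 1.0
        assert ft.full[0, AA_INDEX["D"]] == 0.5

    def test_weighted_counts(self):
        # weights (1/2, 1/2, 1) over residues (D, D, K): classes DE=0.5, KR=0.5
        aln = make_alignment(["DA", "DA", "KA"])
        ft = reduced_frequencies(aln, weights=[0.5, 0.5, 1.0], pseudocount=0.0)
        cmap = reduced_class_map()
        assert ft.reduced[0, cmap["D"]] == pytest.approx(0.5)
        assert ft.reduced[0, cmap["K"]] == pytest.approx(0.5)

    def test_gaps_excluded_from_denominator(self):
        aln = make_alignment(["DA", "-A", "-A"])
        ft = reduced_frequencies(aln, pseudocount=0.0)
        assert ft.reduced[0, reduced_class_map()["D"]] == 1.0

    def test_pseudocount_spreads_mass(self):
        aln = make_alignment(["DA", "DA"])
        ft = reduced_frequencies(aln, pseudocount=1.0)
        assert np.all(ft.reduced > 0.0)
        assert ft.reduced.sum(axis=1) == pytest.approx([1.0, 1.0])

    def test_alphabet_must_partition(self):
        with pytest.raises(ValueError):
            reduced_frequencies(make_alignment(["AA"]), groups=("AC", "DE"))

    def test_eleven_classes_cover_alphabet(self):
        assert sorted("".join(REDUCED_ALPHABET_11)) == sorted(AMINO_ACIDS)
        assert len(REDUCED_ALPHABET_11) == 11


class TestEvolutionaryDistance:
    def test_wildtype_distance_zero(self):
        aln = make_alignment(["ACDE", "GCDE", "AWDE"])
        cons = flat_profile(aln)
        for i, wt in enumerate(aln.query):
            assert evolutionary_distance(aln, cons, i, wt) == 0.0

    def test_single_mismatch_closed_form(self):
        # witness identical to query except b at i; uniform conservation
        aln = make_alignment(["ACDE", "GCDE"])
        cons = flat_profile(aln)
        assert evolutionary_distance(aln, cons, 0, "G") == pytest.approx(1 / 4)

    def test_unobserved_is_nan(self):
        aln = make_alignment(["ACDE", "GCDE"])
        cons = flat_profile(aln)
        assert np.isnan(evolutionary_distance(aln, cons, 1, "W"))

    def test_conservation_weighting(self):
        # mismatch at a high-conservation position costs more
        aln = make_alignment(["AAAA", "CAAA", "AAAC"])
        cons = flat_profile(aln, [0.8, 0.1, 0.1, 0.1])
        d_front = evolutionary_distance(aln, cons, 0, "C")   # row 1
        d_back = evolutionary_distance(aln, cons, 3, "C")    # row 2
        assert d_front == pytest.approx(0.8 / 1.1)
        assert d_back == pytest.approx(0.1 / 1.1)

    def test_gap_counts_as_mismatch(self):
        aln = make_alignment(["ACDE", "G-DE"])
        cons = flat_profile(aln)
        assert evolutionary_distance(aln, cons, 0, "G") == pytest.approx(2 / 4)


class TestSingleLandscape:
    def test_wildtype_cells_zero_and_min_minus_one(self, rng):
        aln = random_alignment(rng, 10, 12)
        cons = conservation_profile(aln)
        scape = single_landscape(aln, cons)
        wt_idx = [AA_INDEX[a] for a in aln.query]
        assert np.all(scape.scores[np.arange(aln.L), wt_idx] == 0.0)
        assert scape.scores.min() == pytest.approx(-1.0)
        assert np.all(scape.scores <= 0.0)
        assert np.all(np.isfinite(scape.scores))

    def test_duplicated_query_msa_all_substitutions_equally_bad(self):
        aln = make_alignment(["ACDE"] * 4)
        scape = single_landscape(aln, conservation_profile(aln))
        wt_idx = [AA_INDEX[a] for a in aln.query]
        non_wt = np.ones_like(scape.scores, dtype=bool)
        non_wt[np.arange(4), wt_idx] = False
        assert np.all(scape.scores[non_wt] == -1.0)
        assert np.all(scape.scores[~non_wt] == 0.0)

    def test_observed_tolerant_beats_unobserved_constrained(self, clade_fixture):
        cons = conservation_profile(clade_fixture)
        scape = single_landscape(clade_fixture, cons)
        # W is observed nowhere; G at the shuffled low-conservation position 6
        # is observed in close homologs
        s_observed = scape.score(6, "G")
        s_unobserved = scape.score(5, "W")
        assert s_observed > s_unobserved

    def test_conservation_gating_on_matched_columns(self, clade_fixture):
        cons = conservation_profile(clade_fixture)
        scape = single_landscape(clade_fixture, cons)
        assert cons.levels[4] > cons.levels[5]
        for aa in AMINO_ACIDS:
            if aa == "A":
                continue
            assert scape.score(5, aa) <= scape.score(6, aa) + 1e-12

    def test_witness_monotonicity(self, rng):
        aln = random_alignment(rng, 12, 8)
        i, b = next(
            (i, b)
            for i in range(aln.L)
            for b in "WCHP"
            if b != aln.query[i] and not (aln.matrix[:, i] == b).any()
        )
        before = single_landscape(aln, conservation_profile(aln)).score(i + 1, b)
        witness = aln.query[:i] + b + aln.query[i + 1:]
        rows = [aln.row(k) for k in range(aln.n)] + [witness]
        grown = make_alignment(rows)
        after = single_landscape(grown, conservation_profile(grown)).score(i + 1, b)
        assert after >= before - 1e-12

    def test_row_order_invariance(self, rng):
        aln = random_alignment(rng, 10, 8)
        base = single_landscape(aln, conservation_profile(aln)).scores
        perm = list(rng.permutation(10))
        shuffled = make_alignment(["".join(aln.matrix[k]) for k in perm])
        # landscape is defined relative to the query; keep row 0 the query
        perm0 = [0] + [p for p in perm if p != 0]
        shuffled = make_alignment(["".join(aln.matrix[k]) for k in perm0])
        other = single_landscape(shuffled, conservation_profile(shuffled)).scores
        assert np.allclose(other, base)

    def test_wide_and_long_exports(self, tmp_path, rng):
        aln = random_alignment(rng, 6, 5)
        scape = single_landscape(aln, conservation_profile(aln))
        wide = tmp_path / "scape.tsv"
        long = tmp_path / "scape.csv"
        scape.write_wide_tsv(wide)
        scape.write_long_csv(long)
        import pandas as pd

        w = pd.read_csv(wide, sep="\t", index_col=0)
        assert w.shape == (5, 20)
        l = pd.read_csv(long)
        assert list(l.columns) == ["mutant", "score"]
        assert len(l) == 5 * 19


class TestVariants:
    def test_parse_single(self):
        q = parse_mutant("A3G", "CCACC")
        assert q.substitutions == [(3, "A", "G")]

    def test_parse_multiple(self):
        q = parse_mutant("C1W:A3G", "CCACC")
        assert len(q) == 2

    def test_offset_shifts_numbering(self):
        q = parse_mutant("A10G", "CCACC", offset=7)
        assert q.substitutions == [(3, "A", "G")]

    @pytest.mark.parametrize("bad", ["", "A3", "3G", "A3g", "A0G", "A99G", "AxG"])
    def test_malformed_or_out_of_range(self, bad):
        with pytest.raises(VariantError):
            parse_mutant(bad, "CCACC")

    def test_wildtype_mismatch(self):
        with pytest.raises(VariantError, match="position 3"):
            parse_mutant("G3A", "CCACC")

    def test_duplicate_position_rejected(self):
        with pytest.raises(VariantError, match="duplicate"):
            parse_mutant("A3G:A3W", "CCACC")

    def test_synonymous_scores_zero(self, rng):
        aln = random_alignment(rng, 6, 5)
        scape = single_landscape(aln, conservation_profile(aln))
        wt = scape.query[2]
        q = parse_mutant(f"{wt}3{wt}", scape.query)
        assert combined_score(scape, q) == 0.0

    def test_multi_substitution_additivity(self, rng):
        aln = random_alignment(rng, 6, 6)
        scape = single_landscape(aln, conservation_profile(aln))
        q = scape.query
        singles = [f"{q[0]}1C", f"{q[2]}3W", f"{q[5]}6H"]
        singles = [s for s in singles if s[0] != s[-1]]
        triple = ":".join(singles)
        total = combined_score(scape, parse_mutant(triple, q))
        parts = sum(combined_score(scape, parse_mutant(s, q)) for s in singles)
        assert total == pytest.approx(parts)
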