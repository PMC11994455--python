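"""Library design: tiling, concatenation, de Bruijn sampling, mutagenesis,
reverse translation."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    MAGEA3_CONTEXT,
    MAGEA3_SPAN,
    PP65_TILE,
    SIINFEKL_CONTEXT,
    SIINFEKL_SPAN,
)
from epimap import (
    AA_ORDER,
    CodonTable,
    EpimapError,
    ProteinRecord,
    TilingSpec,
    add_adaptors,
    concat_nterm_fragments,
    debruijn_sample_tiles,
    reverse_translate,
    saturation_mutagenesis,
    tile_protein,
)
from epimap.tiling import kmer_multiset


def brute_force_tiles(L, window, offset, include_cterm):
    """Independent enumeration of expected tile intervals."""
    if L <= window:
        return [(0, L)]
    spans = []
    start = 0
    while start + window <= L:
        spans.append((start, start + window))
        start += offset
    if include_cterm and spans[-1][1] != L:
        spans.append((L - window, L))
    return spans


class TestTileProtein:
    def test_protein_of_window_length_gives_one_tile(self):
        prot = ProteinRecord("P1", "A" * 56)
        tiles = tile_protein(prot, TilingSpec(window=56, offset=28))
        assert len(tiles) == 1
        assert (tiles[0].start, tiles[0].end) == (0, 56)

    @pytest.mark.parametrize("L", [57, 100, 561, 90, 113])
    @pytest.mark.parametrize("window,offset", [(56, 28), (90, 22)])
    def test_matches_brute_force_enumeration_and_covers_protein(self, L, window, offset):
        rng = np.random.default_rng(L * window)
        seq = "".join(np.array(list(AA_ORDER))[rng.integers(20, size=L)])
        tiles = tile_protein(ProteinRecord("P", seq), TilingSpec(window, offset))
        expected = brute_force_tiles(L, window, offset, include_cterm=True)
        assert [(t.start, t.end) for t in tiles] == expected
        covered = set()
        for t in tiles:
            assert t.sequence == seq[t.start : t.end]
            covered.update(range(t.start, t.end))
        assert covered == set(range(L))

    def test_cterm_tile_flagged_and_omittable(self):
        prot = ProteinRecord("P1", "A" * 61)
        with_c = tile_protein(prot, TilingSpec(window=56, offset=28))
        assert with_c[-1].kind == "c_terminal" and with_c[-1].end == 61
        without = tile_protein(prot, TilingSpec(window=56, offset=28, include_cterm=False))
        assert all(t.kind == "internal" for t in without)

    def test_printed_cmv_tile_carries_its_class_i_epitope(self):
        # the published pp65 tile embeds the NLV 9-mer epitope
        assert "NLVPMVATV" in PP65_TILE


class TestConcatNterm:
    def _prots(self, n, length=40):
        rng = np.random.default_rng(7)
        aa = np.array(list(AA_ORDER))
        return [
            ProteinRecord(f"P{i}", "M" + "".join(aa[rng.integers(20, size=length - 1)]))
            for i in range(n)
        ]

    def test_three_proteins_one_tile_of_ninety(self):
        tiles = concat_nterm_fragments(self._prots(3))
        assert len(tiles) == 1
        assert len(tiles[0].sequence) == 3 * 30
        assert tiles[0].kind == "n_term_concat"

    def test_spacer_precedes_each_fragment(self):
        prots = self._prots(3)
        tile = concat_nterm_fragments(prots)[0]
        for k, p in enumerate(prots):
            unit = tile.sequence[30 * k : 30 * (k + 1)]
            assert unit == "D" + p.sequence[:29]

    def test_remainder_forms_shorter_tile(self):
        tiles = concat_nterm_fragments(self._prots(4))
        assert [len(t.sequence) for t in tiles] == [90, 30]

    def test_short_protein_uses_whole_sequence(self):
        prots = self._prots(3) + [ProteinRecord("S", "MKV")]
        tiles = concat_nterm_fragments(prots)
        assert [len(t.sequence) for t in tiles] == [90, 4]

    def test_non_methionine_start_skipped_with_warning(self):
        prots = self._prots(3) + [ProteinRecord("X", "KVLMA" * 8)]
        with pytest.warns(UserWarning, match="does not start with M"):
            tiles = concat_nterm_fragments(prots)
        assert len(tiles) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(EpimapError):
            concat_nterm_fragments([])


class TestSaturationMutagenesis:
    def test_siinfekl_context_yields_228_mutants(self):
        tiles = saturation_mutagenesis(SIINFEKL_CONTEXT, SIINFEKL_SPAN, flank=2)
        mutants = [t for t in tiles if t.kind == "mutant"]
        assert len(mutants) == 228
        assert sum(t.kind == "wt_control" for t in tiles) == 2

    def test_magea3_context_yields_247_mutants(self):
        tiles = saturation_mutagenesis(MAGEA3_CONTEXT, MAGEA3_SPAN, flank=2)
        assert sum(t.kind == "mutant" for t in tiles) == 247

    def test_single_position_no_flank_gives_19_mutants(self):
        tiles = saturation_mutagenesis("ACDEF", (2, 3), flank=0)
        mutants = [t for t in tiles if t.kind == "mutant"]
        assert len(mutants) == 19
        assert {t.meta.mut_aa for t in mutants} == set(AA_ORDER) - {"D"}

    def test_span_out_of_bounds_rejected(self):
        with pytest.raises(EpimapError, match="outside"):
            saturation_mutagenesis("ACDEF", (0, 3), flank=1)

    @given(
        epitope_len=st.integers(1, 6),
        flank=st.integers(0, 2),
        pad=st.integers(0, 4),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_mutant_count_identity_and_single_substitution(
        self, epitope_len, flank, pad, seed
    ):
        rng = np.random.default_rng(seed)
        aa = np.array(list(AA_ORDER))
        L = epitope_len + 2 * flank + 2 * pad
        context = "".join(aa[rng.integers(20, size=L)])
        span = (pad + flank, pad + flank + epitope_len)
        tiles = saturation_mutagenesis(context, span, flank=flank)
        mutants = [t for t in tiles if t.kind == "mutant"]
        assert len(mutants) == 19 * (epitope_len + 2 * flank)
        assert len({t.sequence for t in mutants}) == len(mutants)
        for t in mutants:
            diffs = [k for k, (a, b) in enumerate(zip(t.sequence, context)) if a != b]
            assert diffs == [t.meta.position]


class TestReverseTranslate:
    def test_translation_round_trip_for_every_oligo(self):
        tiles = saturation_mutagenesis("ACDEFGHIKL", (3, 6), flank=1)
        oligos = reverse_translate(tiles, n_variants=2, seed=5)
        peptides = {t.tile_id: t.sequence for t in tiles}
        assert len(oligos) == 2 * len(tiles)
        for o in oligos:
            assert str(Seq(o.insert_nt).translate()) == peptides[o.tile_id]

    def test_variants_pairwise_distinct(self):
        tiles = saturation_mutagenesis("ACDEFGHIKL", (3, 6), flank=0)
        oligos = reverse_translate(tiles, n_variants=3, seed=1)
        for tile_id in {o.tile_id for o in oligos}:
            inserts = [o.insert_nt for o in oligos if o.tile_id == tile_id]
            assert len(set(inserts)) == len(inserts)

    def test_deterministic_given_seed(self):
        tiles = saturation_mutagenesis("ACDEFGHIKL", (3, 6), flank=1)
        a = reverse_translate(tiles, n_variants=2, seed=42)
        b = reverse_translate(tiles, n_variants=2, seed=42)
        assert a == b

    def test_empty_tile_list_gives_empty_oligo_list(self):
        assert reverse_translate([], n_variants=2, seed=0) == []

    def test_impossible_distinct_variants_rejected(self):
        single = CodonTable(
            codons={aa: ("ATG",) for aa in AA_ORDER},
            weights={aa: (1.0,) for aa in AA_ORDER},
        )
        tiles = saturation_mutagenesis("MMM", (1, 2), flank=0)[:1]
        with pytest.raises(EpimapError, match="distinct"):
            reverse_translate(tiles, codon_table=single, n_variants=2, seed=0)


class TestAddAdaptors:
    def test_simple_concatenation(self):
        oligos = reverse_translate(
            saturation_mutagenesis("MKV", (1, 2), flank=0)[:1], n_variants=1, seed=0
        )
        [done] = add_adaptors(oligos, "AA", "TT")
        assert done.full_nt == "AA" + done.insert_nt + "TT"

    def test_empty_adaptors_leave_insert(self):
        oligos = reverse_translate(
            saturation_mutagenesis("MKV", (1, 2), flank=0)[:1], n_variants=1, seed=0
        )
        [done] = add_adaptors(oligos, "", "")
        assert done.full_nt == done.insert_nt

    def test_non_nucleotide_adaptor_rejected(self):
        with pytest.raises(EpimapError, match="non-ACGT"):
            add_adaptors([], "ACGU", "")


def coverage_counts(proteins, tiles, k):
    """Multiplicity of every proteome k-mer across selected tiles."""
    all_kmers = set()
    for p in proteins:
        all_kmers.update(kmer_multiset(p.sequence, k))
    counts = {km: 0 for km in sorted(all_kmers)}
    for t in tiles:
        for km in kmer_multiset(t.sequence, k):
            counts[km] += 1
    return np.array(list(counts.values()), dtype=float)


class TestDeBruijnSampling:
    def _proteome(self, seed=3, n=4, L=30):
        rng = np.random.default_rng(seed)
        aa = np.array(list(AA_ORDER))
        return [
            ProteinRecord(f"P{i}", "".join(aa[rng.integers(20, size=L)]))
            for i in range(n)
        ]

    def test_saturation_equals_exhaustive_tiling(self):
        prots = self._proteome(n=2, L=15)
        n_starts = sum(len(p) - 12 + 1 for p in prots)
        tiles = debruijn_sample_tiles(prots, window=12, target_count=n_starts, k=3)
        assert len(tiles) == n_starts
        assert {t.tile_id for t in tiles} == {
            f"{p.id}|{s}-{s + 12}" for p in prots for s in range(len(p) - 11)
        }

    def test_deterministic_given_seed(self):
        prots = self._proteome()
        a = debruijn_sample_tiles(prots, window=12, target_count=5, k=3, seed=9)
        b = debruijn_sample_tiles(prots, window=12, target_count=5, k=3, seed=9)
        assert a == b

    def test_target_exceeding_candidates_rejected(self):
        prots = self._proteome(n=1, L=13)
        with pytest.raises(EpimapError, match="exceeds"):
            debruijn_sample_tiles(prots, window=12, target_count=3, k=3)

    def test_disjoint_proteins_get_one_tile_each(self):
        # two proteins with disjoint k-mer content; the optimal (minimum
        # coverage variance) 2-subset takes one tile from each, verified by
        # brute force over all 2-subsets
        prots = [ProteinRecord("A", "ACDEFGHIKL"), ProteinRecord("B", "MNPQRSTVWY")]
        from epimap.tiling import _candidate_tiles

        cands = _candidate_tiles(prots, 9)
        best_var = min(
            coverage_counts(prots, pair, 3).var()
            for pair in itertools.combinations(cands, 2)
        )
        tiles = debruijn_sample_tiles(prots, window=9, target_count=2, k=3, seed=0)
        assert {t.parent_id for t in tiles} == {"A", "B"}
        assert coverage_counts(prots, tiles, 3).var() == pytest.approx(best_var)

    def test_never_worse_than_uniform_random_starts(self):
        prots = self._proteome(seed=5, n=5, L=25)
        from epimap.tiling import _candidate_tiles

        cands = _candidate_tiles(prots, 10)
        greedy_vars, random_vars = [], []
        for seed in range(20):
            tiles = debruijn_sample_tiles(prots, window=10, target_count=8, k=3, seed=seed)
            greedy_vars.append(coverage_counts(prots, tiles, 3).var())
            rng = np.random.default_rng(seed)
            picks = rng.choice(len(cands), size=8, replace=False)
            random_vars.append(
                coverage_counts(prots, [cands[i] for i in picks], 3).var()
            )
        assert np.mean(greedy_vars) <= np.mean(random_vars)
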