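"""Virtual digestion: site scanning, fragment accounting, gel matching."""

import itertools

import numpy as np
import pytest

from linrep.digest import (
    ENZYMES,
    FragmentSet,
    GelModel,
    RestrictionEnzyme,
    digest_genome,
    digest_replicon,
    find_sites,
    match_bands,
    migration_position,
    visible_fragments,
)
from linrep.io import Replicon

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_force_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Position-by-position IUPAC comparison on the top strand (oracle)."""
    m = len(enzyme.site)
    cuts = set()
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in IUPAC[c] for j, c in enumerate(enzyme.site)):
            cuts.add(i + enzyme.cut_offset)
    return sorted(cuts)


def random_seq(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(p))])


class TestFindSites:
    def test_drai_worked_example(self):
        assert find_sites(Replicon("t", "AAATTTAAACCC"), ENZYMES["DraI"]) == [6]

    def test_asei_worked_example(self):
        assert find_sites(Replicon("t", "GGATTAATGG"), ENZYMES["AseI"]) == [4]

    def test_no_site(self):
        assert find_sites(Replicon("t", "GGGGGG"), ENZYMES["DraI"]) == []

    def test_n_never_matches(self):
        assert find_sites(Replicon("t", "TTTNAA" + "TTTAAA"), ENZYMES["DraI"]) == [9]

    def test_overlapping_occurrences_each_cut(self):
        # TTTAAA twice overlapping in TTTAAATTTAAA plus the shifted TTTAAA..
        seq = "TTTAAATTTAAA"
        assert find_sites(Replicon("t", seq), ENZYMES["DraI"]) == [3, 9]

    def test_circular_site_across_origin(self):
        # site split by the origin: AAA...TTT wraps to TTTAAA
        seq = "AAA" + "G" * 20 + "TTT"
        assert find_sites(Replicon("t", seq, "circular"), ENZYMES["DraI"]) == [0]
        assert find_sites(Replicon("t", seq, "linear"), ENZYMES["DraI"]) == []

    def test_offset_outside_site_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            RestrictionEnzyme("bad", "GCTCTTC", 8)

    def test_non_palindromic_bottom_strand(self):
        # GACGC is non-palindromic; its bottom-strand occurrence shows up on
        # the top strand as GCGTC and the cut maps back to len(site) - offset.
        enz = RestrictionEnzyme("custom", "GACGC", 5)
        seq = "TT" + "GCGTC" + "TTTT"
        assert find_sites(Replicon("t", seq), enz) == [2]
        # a top-strand occurrence cuts at offset from the site start
        assert find_sites(Replicon("t", "TTGACGCTT"), enz) == [7]

    def test_agrees_with_biopython_on_random_sequences(self, rng):
        from Bio.Restriction import AseI as BioAseI
        from Bio.Restriction import DraI as BioDraI
        from Bio.Seq import Seq

        for _ in range(10):
            s = random_seq(rng, 4000, p=(0.4, 0.1, 0.1, 0.4))
            for name, ref in (("DraI", BioDraI), ("AseI", BioAseI)):
                mine = find_sites(Replicon("r", s), ENZYMES[name])
                theirs = sorted(p - 1 for p in ref.search(Seq(s), linear=True))
                assert mine == theirs
                mine_c = find_sites(Replicon("r", s, "circular"), ENZYMES[name])
                theirs_c = sorted((p - 1) % len(s) for p in ref.search(Seq(s), linear=False))
                assert mine_c == theirs_c

    def test_agrees_with_brute_force_scan(self, rng):
        enzymes = list(ENZYMES.values()) + [RestrictionEnzyme("amb", "GRNTYC", 2)]
        for _ in range(30):
            s = random_seq(rng, int(rng.integers(50, 3000)), p=(0.35, 0.15, 0.15, 0.35))
            enz = enzymes[int(rng.integers(len(enzymes)))]
            if enz.is_palindromic:
                assert find_sites(Replicon("r", s), enz) == brute_force_sites(s, enz)


class TestDigest:
    def test_one_cut_two_fragments(self):
        fs = digest_replicon(Replicon("t", "AAATTTAAACCC"), ENZYMES["DraI"])
        assert sorted(fs.fragments) == [6, 6]

    def test_single_cut_linearizes_circle(self):
        fs = digest_replicon(Replicon("t", "AAATTTAAACCC", "circular"), ENZYMES["DraI"])
        assert fs.fragments == (12,)

    def test_uncut_returns_whole_length(self):
        fs = digest_replicon(Replicon("t", "G" * 12), ENZYMES["DraI"])
        assert fs.fragments == (12,)

    def test_conservation_on_random_sequences(self, rng):
        for _ in range(20):
            s = random_seq(rng, int(rng.integers(100, 5000)), p=(0.4, 0.1, 0.1, 0.4))
            for topo in ("linear", "circular"):
                for enz in ENZYMES.values():
                    fs = digest_replicon(Replicon("r", s, topo), enz)
                    assert fs.total_bp == len(s)

    def test_circular_rotation_invariance(self, rng):
        for _ in range(10):
            s = random_seq(rng, 2000, p=(0.4, 0.1, 0.1, 0.4))
            k = int(rng.integers(1, 2000))
            rot = s[k:] + s[:k]
            a = digest_replicon(Replicon("r", s, "circular"), ENZYMES["DraI"])
            b = digest_replicon(Replicon("r", rot, "circular"), ENZYMES["DraI"])
            assert a.counter() == b.counter()

    def test_genome_digest_is_multiset_union(self):
        r1 = Replicon("a", "AAATTTAAACCC")
        r2 = Replicon("b", "G" * 500)
        fs = digest_genome([r1, r2], ENZYMES["DraI"])
        assert sorted(fs.fragments) == [6, 6, 500]
        assert fs.total_bp == r1.length + r2.length

    def test_two_uncut_replicons_two_fragments(self):
        fs = digest_genome(
            [Replicon("a", "G" * 100), Replicon("b", "C" * 80)], ENZYMES["DraI"]
        )
        assert len(fs) == 2


class TestGelModel:
    def test_visibility_threshold(self):
        fs = FragmentSet(("x",), "DraI", (50000, 31000, 29000), "linear")
        vis, removed = visible_fragments(fs, GelModel(min_visible_bp=30000))
        assert vis.fragments == (50000, 31000) and removed == 1

    def test_empty_set(self):
        fs = FragmentSet(("x",), "DraI", (), "linear")
        vis, removed = visible_fragments(fs, GelModel())
        assert vis.fragments == () and removed == 0

    @pytest.mark.parametrize(("size", "pos"), [(1e5, 40.0), (1e6, 20.0)])
    def test_migration_closed_form(self, size, pos):
        gel = GelModel(calibration=(140.0, 20.0))
        value, compressed = migration_position(size, gel)
        assert value == pytest.approx(pos) and not compressed

    def test_migration_monotone_decreasing(self):
        gel = GelModel()
        assert migration_position(2e5, gel)[0] < migration_position(1e5, gel)[0]

    def test_out_of_range_flagged_compressed(self):
        gel = GelModel(resolvable_range=(30000.0, 1e6))
        _pos, compressed = migration_position(2e6, gel)
        assert compressed


def brute_force_match(preds, obs, tol):
    """Exhaustive max-cardinality min-error assignment (oracle for small n)."""
    best = (0, 0.0)
    for k in range(min(len(preds), len(obs)), -1, -1):
        candidates = []
        for psub in itertools.permutations(range(len(preds)), k):
            for osub in itertools.combinations(range(len(obs)), k):
                errs = [abs(preds[p] - obs[o]) / obs[o] for p, o in zip(psub, osub)]
                if all(e <= tol for e in errs):
                    candidates.append(sum(errs))
        if candidates:
            return k, min(candidates)
    return best


class TestMatchBands:
    def test_three_way_worked_example(self):
        fs = FragmentSet(("x",), "DraI", (400000, 300000, 100000, 20000), "linear")
        rep = match_bands(fs, [410000, 305000, 98000], GelModel(), 0.05)
        assert rep.n_matched == 3
        assert rep.unmatched_predicted_visible == ()
        assert rep.unmatched_observed == ()
        assert rep.n_invisible == 1

    def test_identity_match_zero_error(self):
        fs = FragmentSet(("x",), "E", (100000,), "linear")
        rep = match_bands(fs, [100000])
        assert rep.matches == ((100000, 100000, 0.0),)

    def test_out_of_tolerance(self):
        fs = FragmentSet(("x",), "E", (100000,), "linear")
        rep = match_bands(fs, [200000], rel_tol=0.05)
        assert rep.n_matched == 0
        assert rep.unmatched_predicted_visible == (100000,)
        assert rep.unmatched_observed == (200000,)

    def test_agrees_with_exhaustive_assignment(self, rng):
        for _ in range(25):
            preds = sorted(rng.integers(30000, 900000, size=4), reverse=True)
            obs = [int(p * (1 + rng.normal(0, 0.04))) for p in preds[:3]]
            fs = FragmentSet(("x",), "E", tuple(int(p) for p in preds), "linear")
            rep = match_bands(fs, obs, GelModel(), 0.05)
            k, best_err = brute_force_match([int(p) for p in preds], obs, 0.05)
            direct = [m for m in rep.matches]
            assert rep.n_matched == k
            assert sum(e for _, _, e in direct) == pytest.approx(best_err, abs=1e-9)

    def test_cardinality_bound(self, rng):
        preds = tuple(int(x) for x in rng.integers(30000, 500000, size=6))
        obs = [float(x) for x in rng.integers(30000, 500000, size=4)]
        fs = FragmentSet(("x",), "E", preds, "linear")
        rep = match_bands(fs, obs)
        assert rep.n_matched <= min(len(preds), len(obs))

    def test_comigrating_fragments_share_a_band(self):
        fs = FragmentSet(("x",), "E", (100500, 100000), "linear")
        rep = match_bands(fs, [100200], rel_tol=0.05)
        assert rep.n_matched == 1
        assert rep.unmatched_predicted_visible == ()
        assert len(rep.comigration_groups) == 1
        band, members = rep.comigration_groups[0]
        assert band == 100200 and set(members) == {100000, 100500}

    def test_negative_band_rejected(self):
        fs = FragmentSet(("x",), "E", (100000,), "linear")
        with pytest.raises(ValueError):
            match_bands(fs, [-5.0])


class TestEnzymeParsing:
    def test_builtin_table(self):
        assert ENZYMES["DraI"].site == "TTTAAA" and ENZYMES["DraI"].cut_offset == 3
        assert ENZYMES["AseI"].cut_offset == 2
        assert ENZYMES["BfrI"].cut_offset == 1
        assert ENZYMES["XbaI"].cut_offset == 1
        assert all(e.is_palindromic for e in ENZYMES.values())

    def test_custom_site_caret_syntax(self):
        enz = RestrictionEnzyme.parse("TTT^AAA")
        assert enz.site == "TTTAAA" and enz.cut_offset == 3

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme.parse("NotAnEnzyme")
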