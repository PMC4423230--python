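import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulink import cne_scan as cs
from regulink.genome_io import AlignmentBlock, Interval, MafRow, SpeciesMeta

from _oracles import interval_union, oracle_scan, random_alignment


def _block(texts: dict[str, str], reference="ref", ref_start=100) -> AlignmentBlock:
    rows = {}
    for sp, txt in texts.items():
        start = ref_start if sp == reference else 500
        rows[sp] = MafRow(sp, "chrX" if sp == reference else "c1", start,
                          len(txt.replace("-", "")), "+", 100_000, txt)
    return AlignmentBlock(rows, reference)


def _column(ref_base: str, others: list[str]) -> dict[str, str]:
    col = {"ref": ref_base}
    for i, b in enumerate(others):
        col[f"sp{i}"] = b
    return col


class TestColumnConservation:
    def test_seven_species_one_substitution_is_conserved(self):
        # the minimal configuration: reference plus seven aligned species
        col = _column("A", ["A"] * 6 + ["C"])
        assert cs.column_conserved(col, "ref", cs.ScanParams())

    def test_seven_species_two_substitutions_not_conserved(self):
        col = _column("A", ["A"] * 5 + ["C", "G"])
        assert not cs.column_conserved(col, "ref", cs.ScanParams())

    def test_below_species_minimum_never_conserved(self):
        col = _column("A", ["A"] * 5)  # 6 rows total, 5 beyond reference
        assert not cs.column_conserved(col, "ref", cs.ScanParams())

    def test_gap_rows_do_not_count_as_aligned(self):
        col = _column("A", ["A"] * 7 + ["-"] * 3)
        assert cs.column_conserved(col, "ref", cs.ScanParams())
        col = _column("A", ["A"] * 6 + ["-"] * 4)
        assert not cs.column_conserved(col, "ref", cs.ScanParams())

    def test_allowed_mismatches_scales_with_alignment_depth(self):
        p = cs.ScanParams()
        assert p.allowed_mismatches(8) == 1
        assert p.allowed_mismatches(17) == 3   # ceil(2.04)
        assert p.allowed_mismatches(25) == 3   # exactly 3.0


class TestMasking:
    def test_exon_covering_block_masks_everything(self):
        texts = {"ref": "ACGTACGTACGTACGT", **{f"sp{i}": "ACGTACGTACGTACGT" for i in range(7)}}
        block = _block(texts)
        mask = cs.mask_columns(block, [Interval("chrX", 0, 10_000)], [])
        assert mask.all()
        assert cs.scan_block(block, cs.ScanParams(),
                             [Interval("chrX", 0, 10_000)], []) == []

    def test_no_masks_masks_nothing_on_gapless_block(self):
        texts = {"ref": "ACGTACGTAC"}
        block = _block(texts)
        assert not cs.mask_columns(block).any()

    def test_partial_mask_counts_columns(self):
        texts = {"ref": "ACGTACGTACGTACGTACGT"}  # gapless, starts at 100
        block = _block(texts)
        mask = cs.mask_columns(block, [Interval("chrX", 105, 110)], [])
        assert mask.sum() == 5
        assert list(np.flatnonzero(mask)) == [5, 6, 7, 8, 9]

    def test_reference_gap_columns_masked(self):
        texts = {"ref": "ACG--TAC"}
        block = _block(texts)
        assert list(cs.mask_columns(block)) == [False] * 3 + [True] * 2 + [False] * 3


class TestCoresAndExtension:
    def test_ten_conserved_columns_form_one_core(self):
        cons = np.array([True] * 10)
        assert cs.find_cores(cons, cs.ScanParams()) == [(0, 10)]

    def test_two_nonconserved_in_window_no_core(self):
        cons = np.array([True] * 4 + [False, False] + [True] * 4)
        assert cs.find_cores(cons, cs.ScanParams()) == []

    def test_cores_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        p = cs.ScanParams()
        for _ in range(50):
            cons = rng.random(200) < 0.85
            got = cs.find_cores(cons, p)
            wins = [(i, i + 10) for i in range(191) if cons[i:i + 10].sum() >= 9]
            merged = []  # strictly-overlapping windows union into one seed
            for a, b in wins:
                if merged and a < merged[-1][1]:
                    merged[-1] = (merged[-1][0], b)
                else:
                    merged.append((a, b))
            assert [(int(a), int(b)) for a, b in got] == merged

    def test_extension_crosses_three_gap_but_not_four(self):
        p = cs.ScanParams()
        cons = np.array([True] * 10 + [False] * 3 + [True] * 2)
        assert cs.extend_seed((0, 10), cons, p) == (0, 15)
        cons = np.array([True] * 10 + [False] * 4 + [True] * 2)
        assert cs.extend_seed((0, 10), cons, p) == (0, 10)

    def test_extension_trims_to_conserved_ends(self):
        p = cs.ScanParams()
        cons = np.array([False, True] + [True] * 9 + [False, False])
        lo, hi = cs.extend_seed((1, 11), cons, p)
        assert cons[lo] and cons[hi - 1]

    def test_extension_matches_scalar_walk(self):
        rng = np.random.default_rng(11)
        p = cs.ScanParams()
        for _ in range(50):
            cons = rng.random(500) < 0.8
            masked = rng.random(500) < 0.05
            seeds = cs.find_cores(cons & ~masked, p, masked)
            for seed in seeds:
                got = cs.extend_seed(seed, cons & ~masked, p, masked)
                exp = _walk(seed, (cons & ~masked).tolist(), masked.tolist(), p)
                assert got == exp


def _walk(seed, cons, masked, p):
    n = len(cons)
    lo, hi = seed
    run, j = 0, hi
    while j < n and not masked[j]:
        if cons[j]:
            run = 0
        else:
            run += 1
            if run > p.max_nonconserved_run:
                break
        j += 1
    hi = j
    run, i = 0, lo - 1
    while i >= 0 and not masked[i]:
        if cons[i]:
            run = 0
        else:
            run += 1
            if run > p.max_nonconserved_run:
                break
        i -= 1
    lo = i + 1
    while lo < hi and not cons[lo]:
        lo += 1
    while hi > lo and not cons[hi - 1]:
        hi -= 1
    return lo, hi


class TestScannerEquivalence:
    def test_scan_block_equals_brute_force(self):
        rng = np.random.default_rng(202)
        p = cs.ScanParams()
        for _ in range(150):
            texts, spans = random_alignment(rng)
            block = _block(texts)
            got = sorted((c.interval.start, c.interval.end, c.species_set)
                         for c in cs.scan_block(block, p,
                                                [Interval("chrX", s, e) for s, e in spans], []))
            exp = sorted(oracle_scan(texts, "ref", p, spans, 100))
            assert got == exp

    def test_called_elements_avoid_masks_and_contain_core(self):
        rng = np.random.default_rng(303)
        p = cs.ScanParams()
        for _ in range(30):
            texts, spans = random_alignment(rng)
            block = _block(texts)
            masked = cs.mask_columns(block, [Interval("chrX", s, e) for s, e in spans], [])
            cons = cs.conserved_columns(block, p) & ~masked
            for cne in cs.scan_block(block, p, [Interval("chrX", s, e) for s, e in spans], []):
                lo = cne.interval.start - 100
                hi = cne.interval.end - 100
                assert not masked[lo:hi].any()
                counts = np.convolve(cons[lo:hi].astype(int), np.ones(10, int), "valid")
                assert (counts >= 9).any()


SPECIES_META = {
    "ref": SpeciesMeta("ref", "Reference", 1000),
    "chimp": SpeciesMeta("chimp", "Boreoeutheria", 1000),
    "mouse": SpeciesMeta("mouse", "Boreoeutheria", 1000),
    "elephant": SpeciesMeta("elephant", "Atlantogenata", 1000),
    "opossum": SpeciesMeta("opossum", "MonotremesMarsupials", 1000),
    "chicken": SpeciesMeta("chicken", "SauropsidsAmphibians", 1000),
    "medaka": SpeciesMeta("medaka", "Teleosts", 1000),
}


class TestConservationScore:
    def test_group_maxima_sum(self):
        assert cs.conservation_score({
            "Boreoeutheria": 97, "Atlantogenata": 68, "MonotremesMarsupials": 62,
            "SauropsidsAmphibians": 54, "Teleosts": 49}) == 330

    def test_single_group(self):
        assert cs.conservation_score({"Boreoeutheria": 97}) == 97

    def test_group_max_taken_within_group(self):
        # two Boreoeutheria at 97 and 80: only the max enters the sum
        assert cs.conservation_score({"Boreoeutheria": 97}) == \
            cs.conservation_score({"Boreoeutheria": max(97, 80)})

    def test_percent_identity_ignores_double_gaps(self):
        assert cs.percent_identity("AC-GT", "AC--T") == 100.0 * 3 / 3
        assert cs.percent_identity("ACGT", "ACGA") == 75.0
        assert cs.percent_identity("----", "ACGT") is None

    def test_score_cne_matches_hand_computation(self):
        ref = "ACGTACGTAC"
        texts = {
            "ref": ref,
            "chimp": "ACGTACGTAC",       # 100
            "mouse": "ACGTACGAAC",       # 90
            "elephant": "ACGAACGAAC",    # 80
            "opossum": "ACGAACAAAC",     # 70
            "chicken": "TCGAACAAAC",     # 60
            "medaka": "TCGAACAATC",      # 50
        }
        block = _block(texts)
        cne = cs.CNE("x", Interval("chrX", 100, 110),
                     frozenset(texts) - {"ref"}, {})
        score = cs.score_cne(cne, block, 0, 10, SPECIES_META)
        assert score == 100 + 80 + 70 + 60 + 50

    def test_score_invariant_to_species_order(self):
        rng = np.random.default_rng(5)
        ident = {}
        for sp in ("chimp", "mouse", "elephant"):
            ident[sp] = float(rng.integers(50, 100))
        by_group = {}
        for sp, pid in ident.items():
            g = SPECIES_META[sp].phylo_group
            by_group[g] = max(by_group.get(g, 0), pid)
        forward = cs.conservation_score(by_group)
        assert forward == cs.conservation_score(dict(reversed(list(by_group.items()))))


def _toy_cne(cid, start, end, species, locs):
    return cs.CNE(cid, Interval("chrX", start, end), frozenset(species), locs)


class TestFusion:
    def _pair(self, gap, same_species=True, adjacent=True):
        species = ["s%d" % i for i in range(8)]
        locs_a = {sp: Interval("c1", 1000, 1100) for sp in species}
        shift = 1150 if adjacent else 5000
        locs_b = {sp: Interval("c1", shift, shift + 100) for sp in species}
        a = _toy_cne("a", 100, 200, species, locs_a)
        b_species = species if same_species else species[:-1] + ["other"]
        b = _toy_cne("b", 200 + gap, 300 + gap, b_species,
                     {sp: locs_b[sp] if sp in locs_b else Interval("c1", shift, shift + 100)
                      for sp in b_species})
        return a, b

    def test_fuse_close_same_pattern(self):
        a, b = self._pair(gap=50)
        fused = cs.fuse_cnes([a, b])
        assert len(fused) == 1
        assert fused[0].interval == Interval("chrX", 100, 350)

    def test_no_fuse_when_far_apart(self):
        a, b = self._pair(gap=150)
        assert len(cs.fuse_cnes([a, b])) == 2

    def test_no_fuse_on_different_species_sets(self):
        a, b = self._pair(gap=50, same_species=False)
        assert len(cs.fuse_cnes([a, b])) == 2

    def test_no_fuse_with_intervening_element(self):
        species = ["s%d" % i for i in range(8)]
        # c sits between a and b in species coordinates -> a,b not consecutive
        a = _toy_cne("a", 100, 200, species, {sp: Interval("c1", 1000, 1100) for sp in species})
        b = _toy_cne("b", 250, 350, species, {sp: Interval("c1", 1400, 1500) for sp in species})
        c = _toy_cne("c", 5000, 5100, species, {sp: Interval("c1", 1200, 1300) for sp in species})
        fused = cs.fuse_cnes([a, b, c])
        assert len(fused) == 3

    def test_fusion_idempotent_on_simulator_output(self, scan_result):
        once = cs.fuse_cnes(scan_result.cnes)
        twice = cs.fuse_cnes(once)
        assert [(c.interval.start, c.interval.end) for c in once] == \
               [(c.interval.start, c.interval.end) for c in twice]

    def test_transitive_chain(self):
        species = ["s%d" % i for i in range(8)]
        cnes = []
        for i in range(3):
            locs = {sp: Interval("c1", 1000 + 150 * i, 1100 + 150 * i) for sp in species}
            cnes.append(_toy_cne(f"c{i}", 100 + 150 * i, 200 + 150 * i, species, locs))
        fused = cs.fuse_cnes(cnes)
        assert len(fused) == 1 and fused[0].interval.end == 500


class TestMergeExternal:
    def test_disjoint_concatenation(self):
        cnes = [_toy_cne("a", 100, 200, ["s%d" % i for i in range(8)], {})]
        ext = [Interval("chrX", 1000, 1100)]
        merged = cs.merge_external(cnes, ext)
        assert len(merged) == 2
        assert merged[1].species_set == frozenset()
        assert merged[1].source == "external"

    def test_overlap_union(self):
        cnes = [_toy_cne("a", 100, 200, ["s%d" % i for i in range(8)], {})]
        ext = [Interval("chrX", 150, 260)]
        (m,) = cs.merge_external(cnes, ext)
        assert (m.interval.start, m.interval.end) == (100, 260)
        assert m.species_set  # native species data kept

    def test_counts_match_sweep_line_union(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            native = [(int(a), int(a) + int(rng.integers(10, 100)))
                      for a in rng.integers(0, 5000, size=10)]
            ext = [(int(a), int(a) + int(rng.integers(10, 100)))
                   for a in rng.integers(0, 5000, size=10)]
            cnes = [_toy_cne(f"c{i}", s, e, ["s%d" % k for k in range(8)], {})
                    for i, (s, e) in enumerate(native)]
            merged = cs.merge_external(cnes, [Interval("chrX", s, e) for s, e in ext])
            assert len(merged) == len(interval_union(native + ext))


@given(st.integers(8, 60))
@settings(max_examples=60, deadline=None)
def test_substitution_allowance_monotone_in_depth(n_aligned):
    """Deeper columns never tolerate fewer substitutions, and the allowance
    stays below the mismatch fraction's ceiling."""
    p = cs.ScanParams()
    a = p.allowed_mismatches(n_aligned)
    assert a >= 1
    assert p.allowed_mismatches(n_aligned + 1) >= a
    assert a - 1 < p.column_mismatch_fraction * n_aligned
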