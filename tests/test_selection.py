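import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karstpop import _codon
from karstpop import selection as sel
from karstpop.datatypes import Gene, GeneModel, SweepCall


def _block(rows, positions=None):
    haps = np.asarray(rows, dtype=np.int8)
    if positions is None:
        positions = 1000 * np.arange(1, haps.shape[1] + 1)
    return sel.HaplotypeBlock(haplotypes=haps, positions=np.asarray(positions))


class TestEHH:
    def test_all_identical(self):
        block = _block([[0, 1, 0, 1]] * 4)
        curve = sel.ehh(block, 1)
        assert np.all(curve.values == 1.0)
        # full flank length: (4000-2000) right + (2000-1000) left
        assert sel.ihh(curve) == pytest.approx(3000.0)

    def test_two_identical_pairs_plateau(self):
        # beyond the core, haplotypes form two identical pairs
        block = _block([
            [0, 0, 0],
            [0, 0, 0],
            [0, 1, 1],
            [0, 1, 1],
        ])
        curve = sel.ehh(block, 0)
        assert curve.values[0] == 1.0
        assert curve.values[1] == pytest.approx(2 / 6)
        assert curve.values[2] == pytest.approx(2 / 6)

    def test_all_distinct_drops_to_zero(self):
        block = _block([
            [0, 0],
            [0, 1],
            [1, 2],
            [1, 3],
        ])
        curve = sel.ehh(block, 0)
        assert curve.values[1] == 0.0

    def test_core_is_one_regardless_of_core_alleles(self):
        block = _block([[0], [1]])
        curve = sel.ehh(block, 0)
        assert curve.values[0] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(8, 40)).astype(np.int8)
        block = _block(haps)
        core = int(rng.integers(0, 40))
        curve = sel.ehh(block, core)
        right = curve.values[core:]
        left = curve.values[: core + 1][::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)

    def test_single_haplotype_pair_needed(self):
        with pytest.raises(ValueError):
            sel.ehh(_block([[0, 1]][:1] * 1), 0)


class TestIhhProfile:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_core_reference(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(10, 60)).astype(np.int8)
        pos = np.sort(rng.choice(100_000, size=60, replace=False)) + 1
        block = _block(haps, pos)
        prof = sel.ihh_profile(block)
        ref = np.array(
            [sel.ihh(sel.ehh(block, i)) for i in range(60)]
        )
        np.testing.assert_allclose(prof, ref, rtol=1e-10)


class TestXPEHH:
    def test_identical_populations_zero(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(6, 30)).astype(np.int8)
        a = _block(haps)
        b = _block(haps.copy())
        for core in (0, 10, 29):
            assert sel.xpehh(a, b, core) == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a = _block(rng.integers(0, 2, size=(6, 30)).astype(np.int8))
        b = _block(rng.integers(0, 2, size=(6, 30)).astype(np.int8))
        for core in (5, 15):
            ab = sel.xpehh(a, b, core)
            ba = sel.xpehh(b, a, core)
            assert ab == pytest.approx(-ba)

    def test_extended_homozygosity_positive_score(self):
        rng = np.random.default_rng(5)
        swept = np.tile(rng.integers(0, 2, size=30).astype(np.int8), (6, 1))
        neutral = rng.integers(0, 2, size=(6, 30)).astype(np.int8)
        score = sel.xpehh(_block(swept), _block(neutral), 15)
        assert score is not None and score > 0

    def test_mismatched_grids_rejected(self):
        a = _block(np.zeros((4, 5), dtype=np.int8))
        b = _block(np.zeros((4, 6), dtype=np.int8))
        with pytest.raises(ValueError):
            sel.xpehh(a, b, 0)


class TestStandardize:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=500)
        z, outliers = sel.standardize_scores(scores)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_nan_excluded_never_outlier(self):
        scores = np.array([1.0, 2.0, np.nan, 3.0, 100.0])
        z, outliers = sel.standardize_scores(scores)
        assert np.isnan(z[2])
        assert not outliers[2]
        assert outliers[4]

    def test_outlier_ties_inclusive(self):
        scores = np.array([0.0] * 18 + [5.0, 5.0])
        z, outliers = sel.standardize_scores(scores, outlier_quantile=0.05)
        assert outliers.sum() == 2  # both tied maxima included


@pytest.fixture(scope="module")
def sweep_bundle():
    from karstpop.simulate import SimConfig, simulate_dataset

    return simulate_dataset(
        SimConfig(seed=17, genome=[("chr1", 1_000_000)],
                  mutation_density=4.0, n_genes=0,
                  sweep_regions=[("chr1", 480_000, 560_000, 0.1)],
                  compute_truth=False)
    )


class TestPiRatioWindows:
    def test_min_variable_exclusion(self, sweep_bundle):
        b = sweep_bundle
        windows, _ = sel.pi_ratio_windows(
            b.table, b.matrix, b.popmap, "backgroundA", "target",
            min_variable=20,
        )
        assert all(w.n_variable_sites >= 20 for w in windows)

    def test_planted_sweep_in_top_5_percent(self, sweep_bundle):
        b = sweep_bundle
        windows, outliers = sel.pi_ratio_windows(
            b.table, b.matrix, b.popmap, "backgroundA", "target",
        )
        flagged = [(windows[i].start, windows[i].end) for i in outliers]
        assert any(s < 560_000 and 480_000 < e for s, e in flagged)

    def test_equal_diversity_zero_value(self):
        from karstpop.simulate import SimConfig, simulate_dataset

        b = simulate_dataset(
            SimConfig(seed=18, genome=[("chr1", 300_000)],
                      mutation_density=4.0, n_genes=0, compute_truth=False)
        )
        windows, _ = sel.pi_ratio_windows(
            b.table, b.matrix, b.popmap, "backgroundA", "backgroundA",
        )
        assert all(w.value == pytest.approx(0.0) for w in windows)


class TestKaKs:
    def test_identical_sequences(self):
        ka, ks, ratio = sel.kaks_ng86("ATGGCTTTTGGG", "ATGGCTTTTGGG")
        assert ka == 0.0 and ks == 0.0
        assert ratio is None

    def test_worked_example(self):
        """One synonymous GCT->GCA change: S = 7/3 sites per sequence,
        ps = 3/7, Ks = -3/4 ln(1 - 4/7) ~ 0.6355, Ka = 0."""
        ka, ks, ratio = sel.kaks_ng86("ATGGCTTTTGGG", "ATGGCATTTGGG")
        assert ka == 0.0
        assert ks == pytest.approx(-0.75 * math.log(3 / 7), abs=1e-12)
        assert ks == pytest.approx(0.6354734, abs=1e-6)
        assert ratio == 0.0

    def test_nonsyn_only_ratio_undefined(self):
        # ATG GCT -> ATG TCT: Ala->Ser, non-synonymous
        ka, ks, ratio = sel.kaks_ng86("ATGGCT", "ATGTCT")
        assert ka > 0 and ks == 0.0
        assert ratio is None

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            sel.kaks_ng86("ATGTAAGGG", "ATGTAAGGG")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sel.kaks_ng86("ATGGCT", "ATGGCTAAA")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        codons = _codon.SENSE_CODONS
        n = int(rng.integers(2, 12))
        a = "".join(codons[i] for i in rng.integers(0, len(codons), n))
        b = "".join(codons[i] for i in rng.integers(0, len(codons), n))
        assert sel.kaks_ng86(a, b) == sel.kaks_ng86(b, a)


class TestConsensus:
    def _model(self):
        return GeneModel(genes=[
            Gene("g1", "chr1", 0, 10_000, 0, 9_000),
            Gene("g2", "chr1", 50_000, 60_000, 50_000, 59_000),
        ])

    def test_two_methods_consensus_true(self):
        calls = sel.consensus_sweep(
            {"pi_ratio": [("chr1", 0, 5_000)], "xpehh": [("chr1", 8_000, 9_000)],
             "kaks": []},
            self._model(),
        )
        by_id = {c.gene_id: c for c in calls}
        assert by_id["g1"].consensus
        assert not by_id["g2"].consensus

    def test_single_method_consensus_false(self):
        calls = sel.consensus_sweep(
            {"pi_ratio": [], "xpehh": [("chr1", 0, 5_000)], "kaks": []},
            self._model(),
        )
        assert not any(c.consensus for c in calls)

    def test_three_methods_consensus_true(self):
        calls = sel.consensus_sweep(
            {"pi_ratio": ["g1"], "xpehh": ["g1"], "kaks": ["g1"]},
            self._model(),
        )
        assert {c.gene_id: c.consensus for c in calls}["g1"]

    def test_sweepcall_invariant(self):
        call = SweepCall("g", {"a": True, "b": False, "c": True})
        assert call.consensus
        call2 = SweepCall("g", {"a": True, "b": False})
        assert not call2.consensus


class TestScreens:
    def test_planted_private_set_recovered(self, base_bundle):
        b = base_bundle
        hits = sel.private_nonsyn_screen(b.table, b.matrix, b.popmap,
                                         "target", "private")
        got = sorted([h.chrom, h.pos, h.gene_id] for h in hits)
        assert got == sorted(b.truth.private_hits)
        assert all(h.background_max_freq == 0.0 for h in hits)
        assert all(h.tier == "private" for h in hits)

    def test_fixed_mode_superset_of_private(self, base_bundle):
        b = base_bundle
        private = sel.private_nonsyn_screen(b.table, b.matrix, b.popmap,
                                            "target", "private")
        fixed = sel.private_nonsyn_screen(b.table, b.matrix, b.popmap,
                                          "target", "fixed")
        private_keys = {(h.chrom, h.pos) for h in private}
        fixed_keys = {(h.chrom, h.pos) for h in fixed}
        assert private_keys <= fixed_keys
        got = sorted([h.chrom, h.pos, h.gene_id] for h in fixed)
        assert got == sorted(b.truth.fixed_hits)

    def test_het_target_not_a_hit(self, base_bundle):
        b = base_bundle
        hits = sel.private_nonsyn_screen(b.table, b.matrix, b.popmap,
                                         "target", "private")
        tgt_idx = b.popmap.indices(b.matrix.samples, "target")
        for h in hits:
            i = int(np.nonzero((b.table.chrom == h.chrom)
                               & (b.table.pos == h.pos))[0][0])
            assert np.all(b.matrix.codes[i, tgt_idx] == 2)

    def test_stop_gained_screen_matches_truth(self, base_bundle):
        b = base_bundle
        hits = sel.stop_gained_screen(b.table, b.matrix, b.popmap, "target")
        got = sorted([h.chrom, h.pos, h.gene_id] for h in hits)
        assert got == sorted(b.truth.stop_hits)
        assert all(h.stop_gained for h in hits)

    def test_candidate_gene_restriction(self, base_bundle):
        b = base_bundle
        all_hits = sel.stop_gained_screen(b.table, b.matrix, b.popmap,
                                          "target")
        if not all_hits:
            pytest.skip("bundle planted no stop hits")
        keep_gene = all_hits[0].gene_id
        restricted = sel.stop_gained_screen(
            b.table, b.matrix, b.popmap, "target",
            candidate_genes=[keep_gene],
        )
        assert restricted
        assert all(h.gene_id == keep_gene for h in restricted)
        excluded = sel.stop_gained_screen(
            b.table, b.matrix, b.popmap, "target",
            candidate_genes=["NOT_A_GENE"],
        )
        assert excluded == []

    def test_fixed_tier_boundary_inclusive(self):
        """Background frequency 11/38 (= 28.947%) must pass the 28.95%
        cutoff; 12/38 must not."""
        from karstpop.datatypes import (
            EffectAnnotation, GenotypeMatrix, PopulationMap, VariantTable,
        )

        def build(n_bg_alt_carriers):
            # 4 targets hom-alt; 19 background individuals; carriers are
            # het so the alt-allele count equals n_bg_alt_carriers
            n_bg = 19
            codes = np.zeros((1, 4 + n_bg), dtype=np.int8)
            codes[0, :4] = 2
            codes[0, 4 : 4 + n_bg_alt_carriers] = 1
            samples = [f"t{i}" for i in range(4)] + [
                f"b{i}" for i in range(n_bg)
            ]
            matrix = GenotypeMatrix(
                codes=codes, samples=samples,
                callable_length=np.full(4 + n_bg, 1),
            )
            popmap = PopulationMap(
                assignments={s: ("target" if s.startswith("t") else "bg")
                             for s in samples},
                roles={"target": "target", "bg": "background"},
            )
            table = VariantTable(
                chrom=np.array(["chr1"], dtype=object),
                pos=np.array([100]),
                ref=np.array(["A"], dtype=object),
                alt=np.array(["G"], dtype=object),
                ancestral=np.array([None], dtype=object),
                gerp=np.array([np.nan]),
                effects=[[EffectAnnotation("G1", "missense_variant",
                                           "MODERATE")]],
                ann_raw=[None],
            )
            return table, matrix, popmap

        table, matrix, popmap = build(11)  # 11/38 = 0.28947 <= 0.2895
        hits = sel.private_nonsyn_screen(table, matrix, popmap, "target",
                                         "fixed", max_background_freq=0.2895)
        assert len(hits) == 1
        assert hits[0].tier == "fixed_with_background"
        # exact boundary equality is inclusive
        hits_eq = sel.private_nonsyn_screen(
            table, matrix, popmap, "target", "fixed",
            max_background_freq=11 / 38,
        )
        assert len(hits_eq) == 1

        table, matrix, popmap = build(12)  # 12/38 = 0.3158 > 0.2895
        hits = sel.private_nonsyn_screen(table, matrix, popmap, "target",
                                         "fixed", max_background_freq=0.2895)
        assert hits == []
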