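import numpy as np
import pytest

from karstpop import load as load_mod
from karstpop.datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    EffectAnnotation,
    GenotypeMatrix,
    PopulationMap,
    VariantTable,
)


def _table(n, gerp=None, effects=None):
    return VariantTable(
        chrom=np.full(n, "chr1", dtype=object),
        pos=np.arange(1, n + 1, dtype=np.int64),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        ancestral=np.full(n, None, dtype=object),
        gerp=np.asarray(gerp if gerp is not None else [np.nan] * n, float),
        effects=effects if effects is not None else [[] for _ in range(n)],
        ann_raw=[None] * n,
    )


def _popmap(samples, pops, roles=None):
    return PopulationMap(
        assignments=dict(zip(samples, pops)),
        roles=roles or {},
    )


class TestPolarizeDerived:
    def _setup(self, out_codes):
        n = len(out_codes)
        codes = np.column_stack([
            np.full(n, HET, dtype=np.int8),
            np.asarray(out_codes, dtype=np.int8),
        ])
        matrix = GenotypeMatrix(codes=codes, samples=["a", "out"],
                                callable_length=np.full(2, n))
        popmap = _popmap(["a", "out"], ["pop", "og"],
                         {"pop": "target", "og": "outgroup"})
        return _table(n), matrix, popmap

    def test_outgroup_hom_ref_derived_alt(self):
        table, matrix, pm = self._setup([HOM_REF])
        assert load_mod.polarize_derived(table, matrix, pm)[0] == "alt"

    def test_outgroup_hom_alt_derived_ref(self):
        table, matrix, pm = self._setup([HOM_ALT])
        assert load_mod.polarize_derived(table, matrix, pm)[0] == "ref"

    def test_outgroup_het_excluded(self):
        table, matrix, pm = self._setup([HET])
        assert load_mod.polarize_derived(table, matrix, pm)[0] is None

    def test_outgroup_missing_excluded(self):
        table, matrix, pm = self._setup([MISSING])
        assert load_mod.polarize_derived(table, matrix, pm)[0] is None

    def test_polymorphic_outgroup_excluded(self):
        n = 1
        codes = np.array([[HET, HOM_REF, HOM_ALT]], dtype=np.int8)
        matrix = GenotypeMatrix(codes=codes, samples=["a", "o1", "o2"],
                                callable_length=np.full(3, n))
        pm = _popmap(["a", "o1", "o2"], ["pop", "og", "og"],
                     {"pop": "target", "og": "outgroup"})
        assert load_mod.polarize_derived(_table(n), matrix, pm)[0] is None


class TestGeneticLoad:
    def test_worked_example(self):
        """Two het deleterious sites (4.5, 5.0), one hom-derived site (6.0),
        100 called genotypes -> masked 0.095, realized 0.060."""
        n = 100
        gerp = np.full(n, 0.0)
        gerp[:2] = [4.5, 5.0]
        gerp[2] = 6.0
        codes = np.zeros((n, 1), dtype=np.int8)
        codes[:2, 0] = HET
        codes[2, 0] = HOM_ALT
        matrix = GenotypeMatrix(codes=codes, samples=["x"],
                                callable_length=np.array([n]))
        derived = np.full(n, "alt", dtype=object)
        masked, realized, n_called = load_mod.genetic_load(
            "x", matrix, _table(n, gerp), derived
        )
        assert n_called == 100
        assert masked == pytest.approx(0.095)
        assert realized == pytest.approx(0.060)

    def test_below_threshold_contributes_nothing(self):
        n = 10
        gerp = np.full(n, 3.9)
        codes = np.full((n, 1), HET, dtype=np.int8)
        matrix = GenotypeMatrix(codes=codes, samples=["x"],
                                callable_length=np.array([n]))
        derived = np.full(n, "alt", dtype=object)
        masked, realized, _ = load_mod.genetic_load(
            "x", matrix, _table(n, gerp), derived
        )
        assert masked == 0.0 and realized == 0.0

    def test_no_deleterious_alleles(self):
        n = 10
        gerp = np.full(n, 7.0)
        codes = np.zeros((n, 1), dtype=np.int8)  # hom ancestral (ref)
        matrix = GenotypeMatrix(codes=codes, samples=["x"],
                                callable_length=np.array([n]))
        derived = np.full(n, "alt", dtype=object)
        masked, realized, _ = load_mod.genetic_load(
            "x", matrix, _table(n, gerp), derived
        )
        assert (masked, realized) == (0.0, 0.0)

    def test_derived_ref_homozygote_realizes(self):
        n = 4
        gerp = np.full(n, 5.0)
        codes = np.zeros((n, 1), dtype=np.int8)  # hom ref
        matrix = GenotypeMatrix(codes=codes, samples=["x"],
                                callable_length=np.array([n]))
        derived = np.full(n, "ref", dtype=object)
        masked, realized, _ = load_mod.genetic_load(
            "x", matrix, _table(n, gerp), derived
        )
        assert masked == 0.0
        assert realized == pytest.approx(5.0)

    def test_disjoint_accounting(self, base_bundle):
        """Each deleterious derived site contributes to exactly one of
        masked / realized / neither for a given individual."""
        b = base_bundle
        derived = load_mod.polarize_derived(b.table, b.matrix, b.popmap)
        eligible = derived != None  # noqa: E711
        with np.errstate(invalid="ignore"):
            deleterious = b.table.gerp >= 4.0
        for sample in ("target_1", "backgroundA_3"):
            j = b.matrix.samples.index(sample)
            codes = b.matrix.codes[:, j]
            hom_derived = np.where(derived == "alt", HOM_ALT, HOM_REF)
            in_masked = eligible & deleterious & (codes == HET)
            in_realized = eligible & deleterious & (codes == hom_derived)
            assert not np.any(in_masked & in_realized)

    def test_threshold_monotonicity(self, base_bundle):
        b = base_bundle
        derived = load_mod.polarize_derived(b.table, b.matrix, b.popmap)
        prev = (np.inf, np.inf)
        for threshold in (2.0, 4.0, 6.0):
            masked, realized, _ = load_mod.genetic_load(
                "target_1", b.matrix, b.table, derived, threshold
            )
            assert masked <= prev[0] and realized <= prev[1]
            prev = (masked, realized)

    def test_equals_truth_on_bundle(self, base_bundle):
        reports = load_mod.load_reports(
            base_bundle.table, base_bundle.matrix, base_bundle.popmap
        )
        for r in reports:
            assert r.masked_load == pytest.approx(
                base_bundle.truth.masked_load[r.individual_id], abs=1e-12
            )
            assert r.realized_load == pytest.approx(
                base_bundle.truth.realized_load[r.individual_id], abs=1e-12
            )
            assert r.n_called == base_bundle.truth.n_called[r.individual_id]


class TestSharedSiteFilter:
    def _setup(self, codes_rows):
        codes = np.asarray(codes_rows, dtype=np.int8)
        n, m = codes.shape
        samples = [f"s{i}" for i in range(m)]
        pops = ["A", "A", "B", "B", "C", "C"][:m]
        matrix = GenotypeMatrix(codes=codes, samples=samples,
                                callable_length=np.full(m, n))
        pm = _popmap(samples, pops, {"A": "target"})
        return _table(n), matrix, pm

    def test_all_hom_alt_removed(self):
        table, matrix, pm = self._setup([[HOM_ALT] * 6])
        keep = load_mod.shared_site_filter(table, matrix, pm,
                                           ["A", "B", "C"])
        assert len(keep) == 0

    def test_polymorphic_anywhere_retained(self):
        table, matrix, pm = self._setup([[HOM_ALT] * 5 + [HET]])
        keep = load_mod.shared_site_filter(table, matrix, pm,
                                           ["A", "B", "C"])
        assert list(keep) == [0]

    def test_monomorphic_two_species_polymorphic_third(self):
        table, matrix, pm = self._setup(
            [[HOM_REF, HOM_REF, HOM_REF, HOM_REF, HOM_REF, HOM_ALT]]
        )
        keep = load_mod.shared_site_filter(table, matrix, pm,
                                           ["A", "B", "C"])
        assert list(keep) == [0]


class TestEffectCategoryProportions:
    def _setup(self):
        n = 1000
        effects = [[] for _ in range(n)]
        effects[0] = [EffectAnnotation("g", "stop_gained", "HIGH")]
        effects[1] = [EffectAnnotation("g", "stop_lost", "HIGH")]
        codes = np.zeros((n, 1), dtype=np.int8)
        codes[0, 0] = HET
        codes[1, 0] = HOM_ALT
        matrix = GenotypeMatrix(codes=codes, samples=["x"],
                                callable_length=np.array([n]))
        return _table(n, effects=effects), matrix

    def test_all_mode(self):
        table, matrix = self._setup()
        props = load_mod.effect_category_proportions("x", matrix, table, "all")
        assert props["HIGH"] == pytest.approx(0.002)

    def test_hom_only_mode_subset(self):
        table, matrix = self._setup()
        all_p = load_mod.effect_category_proportions("x", matrix, table, "all")
        hom_p = load_mod.effect_category_proportions(
            "x", matrix, table, "homozygous_only"
        )
        for cat in all_p:
            assert hom_p[cat] <= all_p[cat]
        assert hom_p["HIGH"] == pytest.approx(0.001)

    def test_no_alt_alleles_all_zero(self):
        table, matrix = self._setup()
        matrix.codes[:] = HOM_REF
        props = load_mod.effect_category_proportions("x", matrix, table, "all")
        assert all(v == 0 for v in props.values())


class TestOneWayAnova:
    def test_identical_means_f_zero(self):
        res = load_mod.one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res["F"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        """{1,2} vs {5,6}: SSB = 16 (df 1), SSW = 1 (df 2) -> F = 32."""
        ssb = 2 * (1.5 - 3.5) ** 2 + 2 * (5.5 - 3.5) ** 2
        ssw = (1 - 1.5) ** 2 + (2 - 1.5) ** 2 + (5 - 5.5) ** 2 + (6 - 5.5) ** 2
        f_hand = (ssb / 1) / (ssw / 2)
        assert ssb == pytest.approx(16.0)
        res = load_mod.one_way_anova({"a": [1, 2], "b": [5, 6]})
        assert res["F"] == pytest.approx(f_hand)
        assert res["F"] == pytest.approx(32.0)

    def test_degenerate_variance_flagged(self):
        res = load_mod.one_way_anova({"a": [1, 1], "b": [2, 2]})
        assert res["degenerate"]
        assert res["p"] == 0.0

    def test_pairwise_contrasts_present(self):
        res = load_mod.one_way_anova(
            {"a": [1, 2], "b": [5, 6], "c": [1.5, 2.5]}
        )
        assert set(res["pairwise"]) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_benjamini_hochberg_monotone(self):
        res = load_mod.one_way_anova(
            {"a": [1, 2], "b": [5, 6], "c": [1.5, 2.5]},
            benjamini_hochberg=True,
        )
        raw = load_mod.one_way_anova(
            {"a": [1, 2], "b": [5, 6], "c": [1.5, 2.5]}
        )
        for key in raw["pairwise"]:
            assert res["pairwise"][key] >= raw["pairwise"][key] - 1e-15
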