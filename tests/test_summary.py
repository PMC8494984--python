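import numpy as np
import pandas as pd
import pytest

from conftest import make_two_parent_dataset
from triopattern.classify import CATEGORIES, PAV_MODELS
from triopattern.summary import (
    DegRule,
    PatternSummary,
    SummaryError,
    focal_contrast,
    format_percent,
    hybrid_specific_genes,
    parental_asymmetry,
    ratio_flags,
    summarize_patterns,
)


def make_summary(hybrid, tissue, pav_counts=None, phce_counts=None):
    model_counts = {m: 0 for m in ("PCE", "PSE", "HSE", "SPE", "PHCE")}
    category_counts = {c: 0 for c in CATEGORIES}
    if pav_counts:
        model_counts.update(pav_counts)
    if phce_counts:
        category_counts.update(phce_counts)
        model_counts["PHCE"] = sum(phce_counts.values())
    return PatternSummary(hybrid=hybrid, tissue=tissue,
                          model_counts=model_counts,
                          category_counts=category_counts)


class TestParentalAsymmetry:
    def test_toy_three_genes(self):
        # 2x fold rule with pseudocount 1: gene0 higher in A, gene1 in B, gene2 tied
        ds = make_two_parent_dataset([10.0, 1.0, 5.0], [1.0, 10.0, 5.0])
        asym = parental_asymmetry(ds, "Z", "C", "L", DegRule(min_abs_log2fc=1.0))
        assert (asym.n_gt, asym.n_lt, asym.n_eq) == (1, 1, 1)

    def test_identical_profiles_all_equal(self):
        vals = list(np.linspace(0, 50, 20))
        ds = make_two_parent_dataset(vals, vals)
        asym = parental_asymmetry(ds, "Z", "C", "L")
        assert (asym.n_gt, asym.n_lt, asym.n_eq) == (0, 0, 20)

    def test_antisymmetric_under_parent_swap(self):
        rng = np.random.default_rng(5)
        a = np.exp(rng.normal(1, 2, 100))
        b = np.exp(rng.normal(1, 2, 100))
        ds = make_two_parent_dataset(a, b)
        fwd = parental_asymmetry(ds, "Z", "C", "L")
        rev = parental_asymmetry(ds, "C", "Z", "L")
        assert (fwd.n_gt, fwd.n_lt) == (rev.n_lt, rev.n_gt)
        assert fwd.n_eq == rev.n_eq
        assert fwd.n_gt + fwd.n_lt + fwd.n_eq == 100

    def test_ratio_and_flags(self):
        ds = make_two_parent_dataset([10.0, 1.0, 5.0], [1.0, 10.0, 5.0])
        asym = parental_asymmetry(ds, "Z", "C", "L")
        assert asym.ratio == pytest.approx(1.0)


class TestRatioFlags:
    def test_examples(self):
        a = lambda gt, lt: type("A", (), {"n_gt": gt, "n_lt": lt})()
        assert ratio_flags(a(300, 100), 3, 0.1) is True
        assert ratio_flags(a(100, 300), 3, 0.1) is False
        assert ratio_flags(a(330, 100), 3, 0.1) is True
        assert ratio_flags(a(331, 100), 3, 0.1) is False

    def test_zero_denominator_errors(self):
        a = type("A", (), {"n_gt": 10, "n_lt": 0})()
        with pytest.raises(SummaryError):
            ratio_flags(a, 3, 0.1)


class TestSummarizePatterns:
    def make_calls(self, spec):
        rows = []
        i = 0
        for model, category, count in spec:
            for _ in range(count):
                rows.append((f"g{i}", "H1", "L", model,
                             "both" if model in ("PCE", "PHCE") else "parent1",
                             np.nan, category))
                i += 1
        return pd.DataFrame(rows, columns=["gene_id", "hybrid", "tissue", "model",
                                           "expressing_parent", "a_value", "category"])

    def test_pav_shares(self):
        calls = self.make_calls([("SPE", "", 4), ("PSE", "", 4),
                                 ("PCE", "", 1), ("HSE", "", 1)])
        s = summarize_patterns(calls, "H1", "L")
        assert s.n_pav == 10 and s.n_phce == 0
        assert s.pav_shares["SPE"] == pytest.approx(0.40)
        assert format_percent(s.pav_shares["SPE"]) == "40.00"
        assert s.pav_proportion == pytest.approx(1.0)

    def test_all_phce_means_zero_pav(self):
        calls = self.make_calls([("PHCE", "MP", 10)])
        s = summarize_patterns(calls, "H1", "L")
        assert s.pav_proportion == 0.0
        assert s.phce_shares["MP"] == pytest.approx(1.0)

    def test_category_share(self):
        calls = self.make_calls([("PHCE", "NSD", 31), ("PHCE", "MP", 69)])
        s = summarize_patterns(calls, "H1", "L")
        assert s.phce_shares["NSD"] == pytest.approx(0.31)
        assert format_percent(s.phce_shares["NSD"]) == "31.00"

    def test_within_group_shares_sum_to_one(self):
        calls = self.make_calls([("SPE", "", 3), ("PSE", "", 2), ("HSE", "", 1),
                                 ("PCE", "", 1), ("PHCE", "NSD", 5),
                                 ("PHCE", "PD", 2), ("PHCE", "MP", 3)])
        s = summarize_patterns(calls, "H1", "L")
        assert sum(s.pav_shares.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(s.phce_shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_slice_errors(self):
        calls = self.make_calls([("SPE", "", 1)])
        with pytest.raises(SummaryError):
            summarize_patterns(calls, "H2", "L")


class TestFocalContrast:
    def test_derived_excess(self):
        # focal SPE share 0.4136 vs rest (0.30, 0.28, 0.27, 0.29, 0.28):
        # rest mean 0.284, excess 0.4136/0.284 - 1 = 0.45634 (hand arithmetic)
        denom = 10000
        summaries = [make_summary("ZC", "S", {"SPE": 4136, "PSE": denom - 4136})]
        for hybrid, share in [("ZM", 0.30), ("ZQ", 0.28), ("CM", 0.27),
                              ("CQ", 0.29), ("MQ", 0.28)]:
            n = int(round(share * denom))
            summaries.append(make_summary(hybrid, "S", {"SPE": n, "PSE": denom - n}))
        c = focal_contrast(summaries, "ZC", "S", "SPE")
        assert c.focal_proportion == pytest.approx(0.4136)
        assert c.rest_mean_proportion == pytest.approx(0.284)
        assert c.relative_excess == pytest.approx(0.4563380281690141, rel=1e-12)

    def test_focal_equal_to_rest_gives_zero(self):
        summaries = [make_summary(h, "L", {"SPE": 30, "PSE": 70})
                     for h in ("A", "B", "C")]
        c = focal_contrast(summaries, "A", "L", "SPE")
        assert c.relative_excess == pytest.approx(0.0)

    def test_single_other_hybrid(self):
        summaries = [make_summary("A", "L", {"SPE": 10, "PSE": 90}),
                     make_summary("B", "L", {"SPE": 40, "PSE": 60})]
        c = focal_contrast(summaries, "A", "L", "SPE")
        assert c.rest_mean_proportion == pytest.approx(0.40)

    def test_zero_rest_mean_flagged(self):
        summaries = [make_summary("A", "L", {"SPE": 10, "PSE": 90}),
                     make_summary("B", "L", {"PSE": 100})]
        c = focal_contrast(summaries, "A", "L", "SPE")
        assert c.relative_excess is None

    def test_missing_focal_errors(self):
        with pytest.raises(SummaryError):
            focal_contrast([make_summary("B", "L", {"SPE": 1})], "A", "L", "SPE")

    def test_recovers_planted_excess_on_synthetic_data(self):
        # plant SPE share 0.45 in the focal hybrid and 0.30 elsewhere; the
        # estimated relative excess should approach 0.45/0.30 - 1 = 0.5
        # within multinomial sampling error of the planting draws
        from triopattern.classify import classify_trios
        from triopattern.io import build_trios
        from triopattern.simulate import SimulationConfig, default_pattern_mix, simulate

        def with_spe_share(share):
            mix = default_pattern_mix()
            pav = sum(mix[m] for m in PAV_MODELS)
            scale = (1 - share) / (1 - mix["SPE"] / pav)
            out = dict(mix)
            out["SPE"] = pav * share
            for m in ("PCE", "PSE", "HSE"):
                out[m] = mix[m] * scale
            return out

        overrides = {("ZC", "L"): with_spe_share(0.45)}
        for h in ("ZM", "ZQ", "CM", "CQ", "MQ"):
            overrides[(h, "L")] = with_spe_share(0.30)
        cfg = SimulationConfig(n_genes=4000, noise_cv=0.0, tissues=["L"],
                               pattern_mix_overrides=overrides, seed=21)
        ds, _ = simulate(cfg)
        calls = classify_trios(build_trios(ds, "L"))
        summaries = [summarize_patterns(calls, c.hybrid, "L") for c in ds.design]
        c = focal_contrast(summaries, "ZC", "L", "SPE")
        # ~770 PAV draws per hybrid -> SE of the excess estimate ~0.07
        assert c.relative_excess == pytest.approx(0.5, abs=0.21)


class TestHybridSpecificGenes:
    def test_exclusive_regions(self):
        out = hybrid_specific_genes({"H1": {"a", "b", "c"}, "H2": {"b", "c", "d"}}, "L")
        by_hybrid = {s.hybrid: s.gene_ids for s in out}
        assert by_hybrid == {"H1": frozenset({"a"}), "H2": frozenset({"d"})}

    def test_identical_sets_give_empty_exclusives(self):
        out = hybrid_specific_genes({"H1": {"a", "b"}, "H2": {"a", "b"}}, "L")
        assert all(not s.gene_ids for s in out)

    def test_gene_shared_by_all_in_no_exclusive(self):
        sets = {f"H{i}": {"shared", f"own{i}"} for i in range(6)}
        out = hybrid_specific_genes(sets, "L")
        assert all("shared" not in s.gene_ids for s in out)
        assert {g for s in out for g in s.gene_ids} == {f"own{i}" for i in range(6)}

    def test_pairwise_disjoint_and_disjoint_from_other_inputs(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(200)]
        sets = {f"H{i}": set(rng.choice(genes, size=60, replace=False)) for i in range(5)}
        out = hybrid_specific_genes(sets, "L")
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                assert not (a.gene_ids & b.gene_ids)
            for other, members in sets.items():
                if other != a.hybrid:
                    assert not (a.gene_ids & members)

    def test_requires_two_hybrids(self):
        with pytest.raises(SummaryError):
            hybrid_specific_genes({"H1": {"a"}}, "L")


class TestFormatting:
    @pytest.mark.parametrize(
        "x, expected", [(0.43725, "43.73"), (0.4107, "41.07"), (0.005, "0.50"),
                        (0.0, "0.00"), (1.0, "100.00")]
    )
    def test_half_up_two_decimals(self, x, expected):
        assert format_percent(x) == expected
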