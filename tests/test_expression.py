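"""TNM staging, cohort assembly, fold change, KW testing and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rabnet import expression, synthgen


class TestClassifyTnm:
    @pytest.mark.parametrize(
        "t,n,m,expected",
        [
            ("T2", "N0", "M0", "primary"),
            ("T3", "N2", "M1", "metastasized"),
            ("T1", "N1", "M0", "metastasized"),
            ("T4", "N3", "M1", "metastasized"),
            ("T1", "NX", "M0", "excluded"),
            ("TX", "N0", "M0", "excluded"),
            ("T1", "N0", "MX", "excluded"),
        ],
    )
    def test_staging_rules(self, t, n, m, expected):
        assert expression.classify_tnm(t, n, m) == expected

    def test_n0_m1_excluded_strict_metastatic_inclusive(self):
        assert expression.classify_tnm("T2", "N0", "M1", mode="strict") == "excluded"
        assert expression.classify_tnm("T2", "N0", "M1", mode="inclusive") == "metastasized"

    def test_substage_codes_accepted(self):
        assert expression.classify_tnm("T2a", "N1b", "M0") == "metastasized"

    @pytest.mark.parametrize("t,n,m", [("Q2", "N0", "M0"), ("T", "N0", "M0"), ("T1", "N?", "M0")])
    def test_malformed_codes_rejected(self, t, n, m):
        with pytest.raises(ValueError, match="malformed"):
            expression.classify_tnm(t, n, m)


class TestBuildCohorts:
    def toy_study(self):
        samples = ["n1", "n2", "p1", "p2", "m1", "m2", "x1"]
        matrix = pd.DataFrame(
            np.arange(14, dtype=float).reshape(2, 7),
            index=pd.Index(["g1", "g2"], name="gene"),
            columns=samples,
        )
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "cancer_type": ["CT"] * 7,
                "source": ["normal", "normal"] + ["tumour"] * 5,
                "T": ["", "", "T1", "T2", "T3", "T2", "T1"],
                "N": ["", "", "N0", "N0", "N1", "N2", "NX"],
                "M": ["", "", "M0", "M0", "M0", "M1", "M0"],
            }
        ).set_index("sample_id")
        return matrix, meta

    def test_partition_into_three_cohorts(self):
        matrix, meta = self.toy_study()
        study = expression.build_cohorts(matrix, meta)
        assert study.cohort("CT", "normal") == ["n1", "n2"]
        assert study.cohort("CT", "primary") == ["p1", "p2"]
        assert study.cohort("CT", "metastatic") == ["m1", "m2"]

    def test_nx_sample_in_no_cohort(self):
        matrix, meta = self.toy_study()
        study = expression.build_cohorts(matrix, meta)
        all_ids = sum(study.cohorts["CT"].values(), [])
        assert "x1" not in all_ids

    def test_missing_metadata_rejected(self):
        matrix, meta = self.toy_study()
        with pytest.raises(ValueError, match="metadata"):
            expression.build_cohorts(matrix, meta.drop("p1"))

    def test_malformed_code_names_sample(self):
        matrix, meta = self.toy_study()
        meta.loc["p1", "N"] = "banana"
        with pytest.raises(ValueError, match="p1"):
            expression.build_cohorts(matrix, meta)

    def test_missing_normals_skips_transition(self, caplog):
        matrix, meta = self.toy_study()
        meta = meta.drop(["n1", "n2"])
        matrix = matrix.drop(columns=["n1", "n2"])
        study = expression.build_cohorts(matrix, meta)
        cands = pd.DataFrame(
            {"symbol": ["g1"], "status": ["final"]}
        )
        hits = expression.call_hits(cands, study)
        assert set(hits.transition) == {"primary_metastatic"}


class TestFoldChange:
    def test_exact_ratio(self):
        fc, l2 = expression.fold_change([2, 2], [8, 8])
        assert fc == pytest.approx(4.0, rel=1e-3)
        assert l2 == pytest.approx(2.0, abs=1e-3)

    def test_identity(self):
        fc, l2 = expression.fold_change([3, 3], [3, 3])
        assert fc == 1.0 and l2 == 0.0

    def test_zero_mean_guarded_by_pseudocount(self):
        fc, _ = expression.fold_change([0.0, 0.0], [1.0, 1.0])
        assert fc == pytest.approx((1 + 1e-3) / 1e-3)

    def test_antisymmetry_when_eps_negligible(self):
        a, b = [5.0, 7.0], [20.0, 30.0]
        _, l2ab = expression.fold_change(a, b)
        _, l2ba = expression.fold_change(b, a)
        assert l2ab == pytest.approx(-l2ba, abs=1e-3)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = expression.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_identical_groups_convention(self):
        h, p = expression.kruskal_wallis([2.0, 2.0], [2.0, 2.0])
        assert (h, p) == (0.0, 1.0)

    def test_rank_invariance_under_permutation(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        h1, p1 = expression.kruskal_wallis(a, b)
        h2, p2 = expression.kruskal_wallis(rng.permutation(a), rng.permutation(b))
        assert (h1, p1) == (h2, p2)

    def test_null_calibration_small(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.lognormal(2, 1, 20)
            b = rng.lognormal(2, 1, 20)
            _, p = expression.kruskal_wallis(a, b)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09


class TestStratify:
    @pytest.mark.parametrize(
        "l2,p,tier",
        [
            (2.5, 0.0005, "high"),
            (-2.5, 0.0005, "high"),
            (1.5, 0.005, "medium"),
            (1.5, 0.03, "low"),
            (0.2, 0.5, "non_significant"),
            (2.5, 0.005, "unclassified"),  # strong FC but P in the medium band
            (0.5, 0.01, "unclassified"),
            (1.5, 0.0005, "unclassified"),  # medium FC but high-significance P
        ],
    )
    def test_printed_bands(self, l2, p, tier):
        assert expression.stratify(l2, p) == tier

    @given(
        st.floats(min_value=-5, max_value=5, allow_nan=False),
        st.floats(min_value=0, max_value=1, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=300)
    def test_exactly_one_tier(self, l2, p):
        tier = expression.stratify(l2, p)
        assert tier in {"high", "medium", "low", "non_significant", "unclassified"}


class TestCallHits:
    def test_planted_gene_is_high_tier_hit(self):
        bundle = synthgen.generate_all(synthgen.SynthConfig(seed=3))
        study = expression.build_cohorts(bundle.matrix, bundle.meta)
        cands = pd.DataFrame(
            {"symbol": bundle.planted_hits, "status": "final"}
        )
        hits = expression.call_hits(cands, study)
        met = hits[(hits.transition == "primary_metastatic")]
        assert met.is_hit.sum() >= 9
        assert (met.loc[met.is_hit, "tier"].isin(["high", "medium"])).all()

    def test_hits_are_transition_specific(self):
        cfg = synthgen.SynthConfig(seed=4)
        bundle = synthgen.generate_all(cfg)
        gene = bundle.planted_hits[0]
        # re-plant the same gene on the normal->primary transition instead
        cfg2 = synthgen.SynthConfig(seed=4, planted=((gene, "normal_primary", 3.0),))
        matrix, meta = synthgen.synth_expression(sorted(bundle.net.nodes), cfg2)
        study = expression.build_cohorts(matrix, meta)
        cands = pd.DataFrame({"symbol": [gene], "status": ["final"]})
        hits = expression.call_hits(cands, study)
        by_t = hits.set_index("transition")
        assert by_t.loc["normal_primary", "tier"] in ("high", "medium")
        # the effect persists into the metastatic cohort, so the
        # primary->metastatic contrast is null and the gene is not a hit
        assert not by_t.loc["primary_metastatic", "is_hit"]
        assert not hits.is_hit.any()

    def test_candidate_absent_from_matrix_skipped(self):
        bundle = synthgen.generate_all(synthgen.SynthConfig(seed=5))
        study = expression.build_cohorts(bundle.matrix, bundle.meta)
        cands = pd.DataFrame({"symbol": ["NOT_A_GENE"], "status": ["final"]})
        hits = expression.call_hits(cands, study)
        assert len(hits) == 0

    def test_bh_column_informational(self):
        bundle = synthgen.generate_all(synthgen.SynthConfig(seed=6))
        study = expression.build_cohorts(bundle.matrix, bundle.meta)
        cands = pd.DataFrame({"symbol": bundle.planted_hits, "status": "final"})
        hits = expression.call_hits(cands, study)
        assert "p_bh" in hits.columns
        assert (hits.p_bh >= hits.p_value - 1e-12).all()
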