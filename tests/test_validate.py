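import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from gpsval.mme import EvaluationResult
from gpsval.validate import (
    compare_estimates,
    compute_pyd,
    pyd_reliability,
    pyd_reliability_full_sib,
    rescale_to_base,
    select_validation_animals,
    weighted_metrics,
)

from conftest import tiny_dataset


def _ebv_result(frame):
    return EvaluationResult(frame, {}, {}, pd.DataFrame(), {})


class TestValidationAnimalSelection:
    def test_both_requirements(self, small_dataset):
        val = set(select_validation_animals(small_dataset).tolist())
        # 8 and 9 have phenotyped progeny and pre-cutoff parents
        assert val == {8, 9}

    def test_animal_with_validation_parent_excluded(self, small_dataset):
        # progeny 11/12 have parents in the validation population
        val = select_validation_animals(small_dataset)
        assert 11 not in val and 12 not in val

    def test_unphenotyped_progeny_do_not_count(self):
        data = tiny_dataset()
        phen = data.phenotypes[~data.phenotypes["animal"].isin([11, 12])]
        with pytest.raises(ValueError, match="empty validation"):
            select_validation_animals(data.replace(phenotypes=phen))


class TestComputePyd:
    def test_single_progeny_substitution(self, small_dataset):
        phen = small_dataset.phenotypes.copy()
        phen.loc[phen["animal"] == 11, "value"] = 1.5
        phen = phen[phen["animal"] != 12]
        data = small_dataset.replace(phenotypes=phen)
        ebv = pd.DataFrame({"t": np.zeros(12)}, index=np.arange(1, 13))
        ebv.loc[9, "t"] = 1.0  # the mate of sire 8
        pyd = compute_pyd(data, _ebv_result(ebv), validation_animals=[8])
        assert pyd.loc[pyd["animal"] == 8, "pyd"].item() == pytest.approx(1.5 - 0.5)
        assert pyd.loc[pyd["animal"] == 8, "n_progeny"].item() == 1

    def test_mean_over_identical_terms(self, small_dataset):
        phen = small_dataset.phenotypes.copy()
        phen.loc[phen["animal"].isin([11, 12]), "value"] = 0.7
        data = small_dataset.replace(phenotypes=phen)
        ebv = pd.DataFrame({"t": np.zeros(12)}, index=np.arange(1, 13))
        pyd = compute_pyd(data, _ebv_result(ebv), validation_animals=[8])
        row = pyd[pyd["animal"] == 8]
        assert row["pyd"].item() == pytest.approx(0.7)
        assert row["n_progeny"].item() == 2

    def test_regression_on_parent_tbv_approaches_half(self):
        """With many progeny the PYD regresses on the parent's breeding
        value with slope 1/2."""
        rng = np.random.default_rng(0)
        n_sires, n_prog = 40, 60
        rows = [(i, 0, 0, "M", 0, "g0") for i in range(1, n_sires + 1)]
        rows += [(n_sires + i, 0, 0, "F", 0, "g0") for i in range(1, n_sires + 1)]
        u_s = rng.normal(scale=0.7, size=n_sires)
        u_d = rng.normal(scale=0.7, size=n_sires)
        aid = 2 * n_sires + 1
        phen_rows = []
        for k in range(n_sires):
            for _ in range(n_prog):
                rows.append((aid, k + 1, n_sires + k + 1, "M", 1, None))
                y = 0.5 * u_s[k] + 0.5 * u_d[k] + rng.normal(scale=0.8)
                phen_rows.append((aid, "t", y, "b", "l"))
                aid += 1
        from gpsval.datatypes import StudyDataset
        from gpsval.genotypes import GenotypeMatrix
        from gpsval.pedigree import Pedigree

        ped = Pedigree(
            pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "cohort", "group"])
        )
        ids = ped.ids
        tbv = pd.DataFrame({"t": np.zeros(len(ids))}, index=ids)
        tbv.loc[np.arange(1, n_sires + 1), "t"] = u_s
        tbv.loc[np.arange(n_sires + 1, 2 * n_sires + 1), "t"] = u_d
        data = StudyDataset(
            ped,
            GenotypeMatrix(ids[:0], np.array(["s"]), np.zeros((0, 1))),
            pd.DataFrame(phen_rows, columns=["animal", "trait", "value", "batch", "litter"]),
            tbv,
            training_cutoff=-1,
        )
        pyd = compute_pyd(data, _ebv_result(tbv), validation_animals=np.arange(1, n_sires + 1))
        slope = np.polyfit(u_s, pyd.set_index("animal").loc[np.arange(1, n_sires + 1), "pyd"], 1)[0]
        assert slope == pytest.approx(0.5, abs=0.06)

    def test_unknown_mate_skipped_and_counted(self, small_dataset):
        frame = small_dataset.pedigree.frame.copy()
        frame.loc[frame["animal"] == 12, "dam"] = 0
        frame.loc[frame["animal"] == 12, "group"] = "g0"
        from gpsval.pedigree import Pedigree

        data = small_dataset.replace(pedigree=Pedigree(frame))
        ebv = pd.DataFrame({"t": np.zeros(12)}, index=np.arange(1, 13))
        pyd = compute_pyd(data, _ebv_result(ebv), validation_animals=[8])
        row = pyd[pyd["animal"] == 8]
        assert row["n_progeny"].item() == 1
        assert row["n_skipped"].item() == 1


class TestReliability:
    def test_half_sib_substitution(self):
        assert pyd_reliability(1, 0.25) == pytest.approx(0.0625)

    def test_zero_heritability(self):
        assert (pyd_reliability(np.arange(1, 50), 0.0) == 0).all()

    def test_strictly_increasing_with_limit_one(self):
        r = pyd_reliability(np.arange(1, 2000), 0.4)
        assert (np.diff(r) > 0).all()
        assert r[-1] == pytest.approx(1.0, abs=2e-2)
        assert (r < 1.0).all()

    def test_full_sib_variant_larger(self):
        n = np.arange(1, 30)
        assert (pyd_reliability_full_sib(n, 0.3) >= pyd_reliability(n, 0.3)).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pyd_reliability(0, 0.3)
        with pytest.raises(ValueError):
            pyd_reliability(3, 1.5)


class TestRescaleToBase:
    def _setup(self):
        pyd = pd.DataFrame(
            {"animal": [8, 9], "trait": "t", "pyd": [0.4, -0.2], "n_progeny": [2, 2]}
        )
        ev = pd.DataFrame({"t": np.linspace(-1, 1, 12)}, index=np.arange(1, 13))
        pm = pd.DataFrame({"t": np.linspace(1, -1, 12)}, index=np.arange(1, 13))
        base = np.arange(1, 8)
        return pyd, _ebv_result(ev), _ebv_result(pm), base

    def test_zero_base_means_identity(self):
        pyd, ev, pm, base = self._setup()
        ev.ebv.loc[base, "t"] = 0.0
        pm.ebv.loc[base, "t"] = 0.0
        out = rescale_to_base(pyd, "t", ev, pm, base)
        assert np.allclose(out["pyd_rescaled"], out["pyd"])
        assert np.allclose(out["gebv_rescaled"], ev.ebv.loc[out["animal"], "t"])

    def test_constant_shift_of_evaluation_cancels(self):
        pyd, ev, pm, base = self._setup()
        out1 = rescale_to_base(pyd, "t", ev, pm, base)
        shifted = _ebv_result(ev.ebv + 5.0)
        out2 = rescale_to_base(pyd, "t", shifted, pm, base)
        assert np.allclose(out1["gebv_rescaled"], out2["gebv_rescaled"])

    def test_hand_computed_ten_animal_level_bias(self):
        """Frozen spreadsheet-style oracle on ten animals."""
        rng = np.random.default_rng(42)
        animals = np.arange(1, 11)
        pyd_vals = rng.normal(size=10)
        gebv = rng.normal(size=10)
        pm_ebv = pd.DataFrame({"t": rng.normal(size=10)}, index=animals)
        ev_ebv = pd.DataFrame({"t": gebv}, index=animals)
        base = animals[:4]
        pyd = pd.DataFrame(
            {"animal": animals, "trait": "t", "pyd": pyd_vals, "n_progeny": 3}
        )
        out = rescale_to_base(pyd, "t", _ebv_result(ev_ebv), _ebv_result(pm_ebv), base)
        w = np.ones(10)
        m = weighted_metrics(out["pyd_rescaled"], out["gebv_rescaled"], w, genetic_sd=0.6)
        # independent arithmetic
        p_adj = pyd_vals - 0.5 * pm_ebv.loc[base, "t"].mean()
        g_adj = gebv - gebv[:4].mean()
        expected = np.mean(p_adj - 0.5 * g_adj) / 0.6
        assert m.level_bias == pytest.approx(expected, rel=1e-9)

    def test_empty_base_rejected(self):
        pyd, ev, pm, _ = self._setup()
        with pytest.raises(ValueError, match="base"):
            rescale_to_base(pyd, "t", ev, pm, np.array([]))


class TestWeightedMetrics:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(1)
        gebv = rng.normal(size=30)
        w = rng.uniform(0.1, 1.0, size=30)
        m = weighted_metrics(0.5 * gebv, gebv, w, genetic_sd=1.0)
        assert m.accuracy == pytest.approx(1.0)
        assert m.level_bias == pytest.approx(0.0, abs=1e-12)
        assert m.dispersion == pytest.approx(0.5)

    def test_equal_weights_collapse_to_ordinary_statistics(self):
        rng = np.random.default_rng(2)
        pyd = rng.normal(size=50)
        gebv = rng.normal(size=50)
        m = weighted_metrics(pyd, gebv, np.full(50, 0.37), genetic_sd=1.0)
        assert m.accuracy == pytest.approx(pearsonr(gebv, pyd)[0])
        assert m.dispersion == pytest.approx(np.polyfit(gebv, pyd, 1)[0])
        assert m.level_bias == pytest.approx(np.mean(pyd - 0.5 * gebv))

    def test_unit_scale_invariances(self):
        rng = np.random.default_rng(3)
        pyd = rng.normal(size=40)
        gebv = pyd + rng.normal(size=40)
        w = rng.uniform(0.2, 1.0, 40)
        m1 = weighted_metrics(pyd, gebv, w, genetic_sd=0.5)
        k = 7.3
        m2 = weighted_metrics(k * pyd, k * gebv, w, genetic_sd=0.5 * k)
        assert m2.accuracy == pytest.approx(m1.accuracy)
        assert m2.level_bias == pytest.approx(m1.level_bias)
        assert m2.dispersion == pytest.approx(m1.dispersion)
        # adding the same constant to both series leaves dispersion alone
        m3 = weighted_metrics(pyd + 2.0, gebv + 2.0, w, genetic_sd=0.5)
        assert m3.dispersion == pytest.approx(m1.dispersion)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            weighted_metrics([1.0, 2.0], [1.0, 2.0], [1.0, 1.0], 1.0)
        with pytest.raises(ValueError, match="zero-variance"):
            weighted_metrics([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], np.ones(3), 1.0)


class TestCompareEstimates:
    def test_identical_not_different(self):
        assert not compare_estimates(0.5, 0.02, 0.5, 0.02).different

    def test_three_sigma_different(self):
        se = 0.02
        gap = 3.0 * np.hypot(se, se)
        assert compare_estimates(0.5 + gap, se, 0.5, se).different

    def test_hand_computed_pair(self):
        cmp = compare_estimates(0.51, 0.02, 0.44, 0.02)
        assert cmp.z == pytest.approx(0.07 / np.hypot(0.02, 0.02), rel=1e-9)
        assert cmp.different
        assert cmp.p_value == pytest.approx(0.00667, abs=2e-4)

    def test_zero_ses_rejected(self):
        with pytest.raises(ValueError):
            compare_estimates(1.0, 0.0, 2.0, 0.0)
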