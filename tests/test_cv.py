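import numpy as np
import pandas as pd
import pytest

from sparsegblup.cv import (
    CVPartition,
    EnrichmentSpec,
    ScenarioPlan,
    assemble_training,
    make_partitions,
    mask_target,
    run_scenario,
    standard_enrichment,
)
from sparsegblup.genotypes import compute_grm, filter_markers, impute_mean
from sparsegblup.model import MCMCSettings
from sparsegblup.simulate import (
    GenerativeParams,
    TrialDesign,
    simulate_design_pair,
    simulate_markers,
)


class TestMakePartitions:
    def test_rounding_rule(self):
        lines = [f"L{i}" for i in range(166)]
        parts = make_partitions(lines, (0.15,), 1, seed=0)
        assert len(parts[0].test_lines) == 25  # round(24.9)
        parts = make_partitions(lines, (0.50,), 1, seed=0)
        assert len(parts[0].test_lines) == 83

    def test_disjoint_and_exhaustive(self):
        lines = [f"L{i}" for i in range(30)]
        for p in make_partitions(lines, (0.3, 0.7), 4, seed=1):
            assert not p.test_lines & p.train_lines
            assert p.test_lines | p.train_lines == set(lines)

    def test_deterministic_under_seed(self):
        lines = [f"L{i}" for i in range(50)]
        a = make_partitions(lines, (0.3,), 5, seed=7)
        b = make_partitions(lines, (0.3,), 5, seed=7)
        assert [p.test_lines for p in a] == [p.test_lines for p in b]

    def test_partitions_differ_across_repeats(self):
        lines = [f"L{i}" for i in range(50)]
        parts = make_partitions(lines, (0.5,), 5, seed=7)
        assert len({p.test_lines for p in parts}) > 1

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError, match="test size"):
            make_partitions(["a", "b", "c", "d"], (0.05,), 1)  # k = 0
        with pytest.raises(ValueError, match="test size"):
            make_partitions(["a", "b", "c"], (0.9,), 1)  # k = n

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CVPartition(1, 0.5, frozenset("ab"), frozenset("bc"))


def _toy_library():
    """Two tiny seasons with target (IND) and auxiliary (MEX) envs."""
    def tab(label, year, lines, ind_envs, mex_envs):
        rows = []
        for env in ind_envs:
            for ln in lines:
                rows.append((ln, env, year, "target", 1.0))
        for env in mex_envs:
            for ln in lines:
                rows.append((ln, env, year, "auxiliary", 2.0))
        return pd.DataFrame(
            rows, columns=["line", "env", "year", "site_group", "value"]
        )

    lines23 = [f"L{i}" for i in range(10)]
    lines22 = [f"L{i}" for i in range(7, 17)]  # 3 shared lines
    return {
        "TPE_3_2022_2023": tab(
            "TPE_3_2022_2023", "2022_2023", lines23, ["I23a", "I23b"], ["M23a", "M23b"]
        ),
        "TPE_3_2021_2022": tab(
            "TPE_3_2021_2022", "2021_2022", lines22, ["I22a"], ["M22a"]
        ),
    }


class TestMaskTarget:
    def test_empty_test_set_masks_nothing(self):
        lib = _toy_library()
        part = CVPartition(1, 0.5, frozenset(), frozenset(f"L{i}" for i in range(10)))
        out = mask_target(lib["TPE_3_2022_2023"], part, ["I23a", "I23b"])
        assert not out["masked"].any()
        assert len(out) == len(lib["TPE_3_2022_2023"])  # nothing deleted

    def test_per_cell_masking_count(self):
        lib = _toy_library()
        test = frozenset(["L0", "L1", "L2"])
        part = CVPartition(1, 0.3, test, frozenset(f"L{i}" for i in range(3, 10)))
        out = mask_target(lib["TPE_3_2022_2023"], part, ["I23a", "I23b"])
        # each test line appears in both target envs -> 2 masked cells each
        assert out["masked"].sum() == 6
        expected = sum(
            ((lib["TPE_3_2022_2023"].line == ln)
             & lib["TPE_3_2022_2023"].env.isin(["I23a", "I23b"])).sum()
            for ln in test
        )
        assert out["masked"].sum() == expected

    def test_auxiliary_records_never_masked(self):
        lib = _toy_library()
        part = CVPartition(
            1, 0.5, frozenset(f"L{i}" for i in range(5)),
            frozenset(f"L{i}" for i in range(5, 10)),
        )
        out = mask_target(lib["TPE_3_2022_2023"], part, ["I23a", "I23b"])
        assert not out.loc[out.site_group == "auxiliary", "masked"].any()


class TestAssembleTraining:
    def _masked(self, lib):
        target = lib["TPE_3_2022_2023"]
        tab = target[target.site_group == "target"].reset_index(drop=True)
        part = CVPartition(
            1, 0.3, frozenset(["L0", "L1", "L2"]),
            frozenset(f"L{i}" for i in range(3, 10)),
        )
        return mask_target(tab, part, ["I23a", "I23b"])

    def test_no_enrichment_is_identity(self):
        lib = _toy_library()
        masked = self._masked(lib)
        out = assemble_training(masked, None, lib)
        pd.testing.assert_frame_equal(out, masked)
        out2 = assemble_training(masked, EnrichmentSpec([]), lib)
        pd.testing.assert_frame_equal(out2, masked)

    def test_study_style_composition(self):
        # training = unmasked current-season target cells + all previous-season
        # cells + all auxiliary (off-site) cells of both seasons
        lib = _toy_library()
        masked = self._masked(lib)
        spec = standard_enrichment("TPE_3_2022_2023", ["TPE_3_2021_2022"])
        out = assemble_training(masked, spec, lib)
        n_target = len(masked)  # all target records retained (flagged)
        n_aux_23 = (lib["TPE_3_2022_2023"].site_group == "auxiliary").sum()
        n_22 = len(lib["TPE_3_2021_2022"])
        assert len(out) == n_target + n_aux_23 + n_22
        # test lines reappear as observed in auxiliary envs (tested lines,
        # untested environments)
        obs = out[~out.masked]
        assert {"L0", "L1", "L2"} <= set(obs.line)
        assert not obs.env.isin(["I23a", "I23b"]).pipe(
            lambda s: s & obs.line.isin(["L0", "L1", "L2"])
        ).any()

    def test_leakage_guard_excludes_masked_cells(self, caplog):
        lib = _toy_library()
        masked = self._masked(lib)
        # adversarial source that contains the target dataset's target envs
        spec = EnrichmentSpec([("TPE_3_2022_2023", "target", True)])
        out = assemble_training(masked, spec, lib)
        obs_cells = set(map(tuple, out.loc[~out.masked, ["line", "env"]]
                            .itertuples(index=False)))
        msk_cells = set(map(tuple, out.loc[out.masked, ["line", "env"]]
                            .itertuples(index=False)))
        assert not obs_cells & msk_cells

    def test_missing_source_errors(self):
        lib = _toy_library()
        masked = self._masked(lib)
        with pytest.raises(KeyError, match="nonexistent"):
            assemble_training(
                masked, EnrichmentSpec([("nonexistent", "both", True)]), lib
            )


@pytest.fixture(scope="module")
def scenario_inputs():
    d1 = TrialDesign(
        "T", "Y1", 30, [("Y1_I1", "target"), ("Y1_M1", "auxiliary")], 0.2
    )
    d2 = TrialDesign(
        "T", "Y2", 30,
        [("Y2_I1", "target"), ("Y2_I2", "target"), ("Y2_M1", "auxiliary")], 0.2,
    )
    params = GenerativeParams(n_markers=300, aux_genetic_correlation=0.9, seed=13)
    markers, phenos, _ = simulate_design_pair((d1, d2), params)
    grm = compute_grm(impute_mean(filter_markers(markers)))
    return phenos, grm


class TestRunScenario:
    def test_smoke_two_partitions(self, scenario_inputs):
        phenos, grm = scenario_inputs
        plan = ScenarioPlan(
            target_dataset="T_Y2", tst_props=(0.5,), n_partitions=2,
            enrichment=standard_enrichment("T_Y2", ["T_Y1"]),
            mcmc=MCMCSettings(n_iter=400, burn_in=100, thin=1), seed=3,
        )
        preds, metrics = run_scenario(plan, phenos, grm)
        per_env = metrics[~metrics.env_or_across.isin(["across_envs"])]
        for model in ("GBLUP", "GBLUP_Ad"):
            for env in ("Y2_I1", "Y2_I2"):
                sub = per_env[(per_env.model == model) & (per_env.env_or_across == env)]
                assert len(sub) == 2  # one COR per partition
        assert set(preds.model) == {"GBLUP", "GBLUP_Ad"}
        assert not metrics["failed"].any()

    def test_no_enrichment_only_gblup(self, scenario_inputs):
        phenos, grm = scenario_inputs
        plan = ScenarioPlan(
            target_dataset="T_Y2", tst_props=(0.5,), n_partitions=1,
            mcmc=MCMCSettings(n_iter=300, burn_in=100, thin=1), seed=3,
        )
        _, metrics = run_scenario(plan, phenos, grm)
        assert set(metrics.model) == {"GBLUP"}

    def test_predictions_cover_all_masked_cells(self, scenario_inputs):
        phenos, grm = scenario_inputs
        plan = ScenarioPlan(
            target_dataset="T_Y2", tst_props=(0.3,), n_partitions=1,
            mcmc=MCMCSettings(n_iter=300, burn_in=100, thin=1), seed=5,
        )
        preds, _ = run_scenario(plan, phenos, grm)
        n_target_lines = phenos["T_Y2"].query("site_group=='target'").line.nunique()
        k = round(0.3 * n_target_lines)
        assert preds.line.nunique() == k
        assert preds.groupby("line").size().eq(2).all()  # both target envs

    def test_pooled_scoring_mode(self, scenario_inputs):
        phenos, grm = scenario_inputs
        plan = ScenarioPlan(
            target_dataset="T_Y2", tst_props=(0.5,), n_partitions=1,
            mcmc=MCMCSettings(n_iter=300, burn_in=100, thin=1),
            pool_envs=True, seed=3,
        )
        _, metrics = run_scenario(plan, phenos, grm)
        assert set(metrics.env_or_across) == {"pooled"}
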