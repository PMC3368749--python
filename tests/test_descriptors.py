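import numpy as np
import pytest

from ecpred.descriptors import (
    build_descriptor_matrix,
    composite_bond_change_vector,
    default_feature_registry,
    human_designed_vector,
    overall_bond_change_vector,
    zscale_apply,
    zscale_fit,
)
from ecpred.reaction_model import Species
from ecpred.synthetic_data import GeneratorConfig, generate_dataset

from .conftest import make_entry


class TestOverallAndComposite:
    def test_amide_hydrolysis_counts(self, amide_entry):
        v = overall_bond_change_vector(amide_entry)
        assert v.to_strings() == {"C.N_1.0": 1, "C.O_0.1": 1, "H.N_0.1": 1}

    def test_duplicate_token_gives_count_two(self):
        e = make_entry(overall={"C.O_0.1": 2}, mechanism=[{"C.O_0.1": 2}])
        assert overall_bond_change_vector(e).get(
            next(t for t, _ in e.overall_changes.items())) == 2

    def test_transient_bond_appears_twice_in_composite(self):
        e = make_entry(overall={}, mechanism=[{"C.O_0.1": 1}, {"C.O_1.0": 1}])
        e.validate()
        comp = composite_bond_change_vector(e)
        assert comp.to_strings() == {"C.O_0.1": 1, "C.O_1.0": 1}
        assert not overall_bond_change_vector(e)

    def test_single_step_composite_equals_overall(self, amide_entry):
        assert composite_bond_change_vector(amide_entry) == amide_entry.overall_changes

    def test_composite_is_additive_over_steps(self):
        e = make_entry(overall={"C.H_1.0": 6},
                       mechanism=[{"C.H_1.0": 2}] * 3)
        e.validate()
        assert composite_bond_change_vector(e).to_strings() == {"C.H_1.0": 6}

    def test_composite_preserves_net_token_demand(self, dataset):
        # For every inverse token pair, composite and overall agree on the
        # difference (transients add to both sides of a pair equally).
        for e in dataset:
            comp = composite_bond_change_vector(e)
            overall = e.overall_changes
            tokens = {t for t, _ in comp.items()} | {t for t, _ in overall.items()}
            for t in tokens:
                assert (comp.get(t) - comp.get(t.inverse())
                        == overall.get(t) - overall.get(t.inverse()))


class TestHumanDesignedFeatures:
    @pytest.fixture
    def registry(self):
        return default_feature_registry()

    def test_registry_has_28_unique_features(self, registry):
        assert len(registry) == 28
        assert len(set(registry.names)) == 28
        for name in ("f:X-H", "dv:C", "water.OH-.su", "Mod_Diff"):
            assert name in registry.names

    def test_mod_diff_zero_for_isomerase(self, registry):
        e = make_entry(ec="5.3.1.1", overall={"H.O_1.0": 1, "H.O_0.1": 1},
                       species=[Species("substrate_1", "C6H12O6", "substrate"),
                                Species("product_1", "C6H12O6", "product")])
        values = dict(zip(registry.names, human_designed_vector(e, registry)))
        assert values["Mod_Diff"] == pytest.approx(0.0)
        assert values["isomer"] == 1.0

    def test_water_substrate_flag(self, amide_entry, registry):
        values = dict(zip(registry.names, human_designed_vector(amide_entry, registry)))
        assert values["water.OH-.su"] == 1.0

    def test_formed_to_hydrogen_total(self, registry):
        e = make_entry(overall={"O.H_0.1": 2, "C.H_1.0": 1},
                       mechanism=[{"O.H_0.1": 2, "C.H_1.0": 1}])
        values = dict(zip(registry.names, human_designed_vector(e, registry)))
        assert values["f:X-H"] == 2.0
        assert values["c:X-H"] == 1.0

    def test_dv_counts_carbon_carbon_twice(self, registry):
        e = make_entry(overall={"C.C_1.2": 1, "C.O_0.1": 1},
                       mechanism=[{"C.C_1.2": 1, "C.O_0.1": 1}])
        values = dict(zip(registry.names, human_designed_vector(e, registry)))
        assert values["dv:C"] == 3.0  # 2 from C.C order +1, 1 from C.O formation
        assert values["dv:O"] == 1.0

    def test_mod_diff_requires_both_roles(self, registry):
        e = make_entry(species=[Species("substrate_1", "C2H6O", "substrate")])
        with pytest.raises(ValueError, match="Mod_Diff"):
            human_designed_vector(e, registry)

    def test_atp_hydrolysis_flag(self, registry):
        e = make_entry(ec="6.3.1.2", species=[
            Species("substrate_1", "C5H9NO4", "substrate"),
            Species("ATP", "C10H16N5O13P3", "substrate"),
            Species("product_1", "C5H10N2O3", "product"),
            Species("ADP", "C10H15N5O10P2", "product")])
        values = dict(zip(registry.names, human_designed_vector(e, registry)))
        assert values["ATP.hydrolysis"] == 1.0

    def test_every_synthetic_hydrolase_flags_water(self, dataset):
        registry = default_feature_registry()
        idx = registry.names.index("water.OH-.su")
        for e in dataset:
            if e.ec_class == 3:
                assert human_designed_vector(e, registry)[idx] == 1.0


class TestMatrixConstruction:
    def test_disjoint_token_sets_concatenate(self):
        e1 = make_entry(entry_id="E1", overall={"C.O_0.1": 1}, mechanism=[{"C.O_0.1": 1}])
        e2 = make_entry(entry_id="E2", overall={"H.N_0.1": 1}, mechanism=[{"H.N_0.1": 1}])
        m = build_descriptor_matrix([e1, e2], "overall")
        assert m.feature_names == ["C.O_0.1", "H.N_0.1"]
        assert m.df.loc["E1", "H.N_0.1"] == 0

    def test_row_order_does_not_change_content(self, dataset):
        fwd = build_descriptor_matrix(dataset[:10], "composite")
        rev = build_descriptor_matrix(dataset[:10][::-1], "composite")
        assert fwd.df.equals(rev.df.loc[fwd.entry_ids])

    def test_human_matrix_width_is_registry_size(self, dataset):
        m = build_descriptor_matrix(dataset[:5], "human")
        assert len(m.feature_names) == len(default_feature_registry())

    def test_fixed_feature_list_controls_columns(self, dataset):
        train = build_descriptor_matrix(dataset[:30], "overall")
        test = build_descriptor_matrix(dataset[30:40], "overall",
                                       feature_names=train.feature_names)
        assert test.feature_names == train.feature_names


class TestScaling:
    def test_hand_zscore_with_population_sd(self):
        m = build_descriptor_matrix(
            [make_entry(entry_id=f"E{i}", overall={"C.O_0.1": i + 1},
                        mechanism=[{"C.O_0.1": i + 1}]) for i in range(3)],
            "overall")
        scaled = zscale_apply(m, zscale_fit(m))
        assert scaled.df["C.O_0.1"].tolist() == pytest.approx(
            [-1.2247, 0.0, 1.2247], abs=1e-3)

    def test_fit_apply_centres_training_columns(self, dataset):
        m = build_descriptor_matrix(dataset, "overall")
        scaled = zscale_apply(m, zscale_fit(m))
        x = scaled.values
        nonconst = m.values.std(axis=0) > 0
        assert np.allclose(x[:, nonconst].mean(axis=0), 0, atol=1e-9)
        assert np.allclose(x[:, nonconst].std(axis=0), 1, atol=1e-9)
        assert np.allclose(x[:, ~nonconst], 0)

    def test_training_params_do_not_centre_test_data(self, dataset):
        m = build_descriptor_matrix(dataset, "overall")
        params = zscale_fit(m.rows(m.entry_ids[:60]))
        test = zscale_apply(m.rows(m.entry_ids[60:]), params)
        assert abs(test.values.mean()) > 1e-6

    def test_scaling_invertible_for_nonconstant_columns(self, dataset):
        m = build_descriptor_matrix(dataset[:40], "overall")
        params = zscale_fit(m)
        scaled = zscale_apply(m, params)
        std = np.asarray(params.std)
        nonconst = std > 0
        back = scaled.values[:, nonconst] * std[nonconst] + np.asarray(params.mean)[nonconst]
        assert np.allclose(back, m.values[:, nonconst])

    def test_feature_mismatch_rejected(self, dataset):
        m1 = build_descriptor_matrix(dataset[:10], "overall")
        m2 = build_descriptor_matrix(dataset[:10], "human")
        with pytest.raises(ValueError, match="mismatch"):
            zscale_apply(m2, zscale_fit(m1))
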