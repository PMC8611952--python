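"""Replicate averaging, feature filtering and profile-network linking."""

import numpy as np
import pandas as pd
import pytest

from chemogenlib.config import ConfigError, PipelineConfig
from chemogenlib.morphology import (
    aggregate_replicates,
    compartment_of,
    link_profiles,
    select_features,
)

CFG = PipelineConfig()


class TestAggregate:
    def test_replicates_average(self):
        t = pd.DataFrame(
            {
                "compound_id": ["A", "A", "B"],
                "replicate": [1, 2, 1],
                "Cells_Intensity_X": [1.0, 3.0, 5.0],
            }
        )
        out = aggregate_replicates(t)
        assert out.loc["A", "Cells_Intensity_X"] == 2.0
        assert out.loc["B", "Cells_Intensity_X"] == 5.0

    def test_single_replicate_is_identity(self):
        t = pd.DataFrame(
            {"compound_id": ["A"], "replicate": [1], "Nuclei_AreaShape_Y": [7.5]}
        )
        assert aggregate_replicates(t).loc["A", "Nuclei_AreaShape_Y"] == 7.5

    def test_missing_values_ignored_in_mean(self):
        t = pd.DataFrame(
            {
                "compound_id": ["A", "A", "A"],
                "replicate": [1, 2, 3],
                "Cells_I_X": [1.0, np.nan, 3.0],
                "Cells_I_Y": [np.nan, np.nan, np.nan],
            }
        )
        out = aggregate_replicates(t)
        assert out.loc["A", "Cells_I_X"] == 2.0
        assert np.isnan(out.loc["A", "Cells_I_Y"])


class TestCompartments:
    @pytest.mark.parametrize(
        "name,comp",
        [
            ("Cells_Intensity_MeanIntensity", "cell"),
            ("Cytoplasm_AreaShape_MeanRadius", "cyto"),
            ("Nuclei_Texture_Entropy", "nucl"),
        ],
    )
    def test_prefix_maps_to_compartment(self, name, comp):
        assert compartment_of(name) == comp

    def test_unknown_prefix_raises(self):
        with pytest.raises(ValueError):
            compartment_of("Mitochondria_X_Y")


def _planted_matrix(n=30, seed=0):
    rng = np.random.default_rng(seed)
    cols = {}
    base = []
    for i in range(5):
        x = rng.normal(size=n)
        cols[f"Cells_Ind_F{i}"] = x
        base.append(x)
    cols["Cells_Const_A"] = np.full(n, 3.0)
    cols["Cells_Derived_D0"] = base[0] + rng.normal(0, 0.01, size=n)
    cols["Cells_Derived_D1"] = base[1] * 2.0 + rng.normal(0, 0.01, size=n)
    return pd.DataFrame(cols, index=[f"C{i}" for i in range(n)])


class TestSelectFeatures:
    def test_constant_column_dropped(self):
        survivors = select_features(_planted_matrix(), CFG)
        assert "Cells_Const_A" not in survivors["cell"]

    def test_duplicated_column_keeps_exactly_one_copy(self):
        m = _planted_matrix()
        m["Cells_Ind_F0_copy"] = m["Cells_Ind_F0"]
        survivors = select_features(m, CFG)
        assert "Cells_Ind_F0" in survivors["cell"]
        assert "Cells_Ind_F0_copy" not in survivors["cell"]

    def test_planted_structure_recovered(self):
        survivors = select_features(_planted_matrix(), CFG)
        assert survivors["cell"] == [f"Cells_Ind_F{i}" for i in range(5)]

    def test_survivors_satisfy_pairwise_threshold(self):
        m = _planted_matrix()
        survivors = select_features(m, CFG)
        kept = m[survivors["cell"]]
        corr = kept.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert (corr < CFG.corr_threshold).all()

    def test_row_order_invariance(self):
        m = _planted_matrix()
        shuffled = m.sample(frac=1.0, random_state=4)
        assert select_features(m, CFG) == select_features(shuffled, CFG)

    def test_compartments_filtered_independently(self):
        n = 20
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        m = pd.DataFrame(
            {
                "Cells_F_A": x,
                "Nuclei_F_B": x + rng.normal(0, 0.001, size=n),  # r~1 but other compartment
            }
        )
        survivors = select_features(m, CFG)
        assert survivors["cell"] == ["Cells_F_A"]
        assert survivors["nucl"] == ["Nuclei_F_B"]

    def test_fewer_than_two_compounds_is_config_error(self):
        with pytest.raises(ConfigError):
            select_features(_planted_matrix(n=1), CFG)


class TestLinkProfiles:
    KEY1 = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"
    KEY2 = "CCCCCCCCCCCCCC-DDDDDDDDDD-N"

    def test_identical_single_compound_sets_match(self):
        link = link_profiles({"P1": self.KEY1}, {"M1": self.KEY1})
        assert link.matched == {"P1": "M1"} and link.n_matched == 1

    def test_disjoint_sets_do_not_match(self):
        link = link_profiles({"P1": self.KEY1}, {"M1": self.KEY2})
        assert link.n_matched == 0
        assert link.unmatched_profiles == ["P1"]
        assert link.unmatched_molecules == ["M1"]

    def test_planted_shared_keys_all_match(self, bundle):
        profile_keys = (
            bundle.morphology.drop_duplicates("compound_id")
            .set_index("compound_id")["inchikey"]
            .to_dict()
        )
        link = link_profiles(profile_keys, bundle.truth.molecule_inchikey)
        matched_keys = {profile_keys[p] for p in link.matched}
        assert matched_keys == set(bundle.truth.shared_inchikeys)
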