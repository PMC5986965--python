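import numpy as np
import pytest

from fcstage.attribution import (
    ConnectionWeightTable,
    connection_weights,
    direction_partition,
    network_involvement,
    partition_table,
    seed_weights,
    write_edge_file,
)
from fcstage.classify import SvmHyperparams, SvmModel
from fcstage.connectivity import pair_to_index
from fcstage.features import FeatureChain, PcaBasis
from fcstage.synthetic import toy_atlas


def make_basis(loadings: np.ndarray, k: int) -> PcaBasis:
    p, m = loadings.shape
    return PcaBasis(
        mean_vector=np.zeros(p),
        loadings=loadings,
        variance_fractions=np.linspace(0.5, 0.1, m) / np.linspace(0.5, 0.1, m).sum(),
        n_components_kept=k,
    )


class TestConnectionWeights:
    def test_single_component_absolute_loadings(self):
        basis = make_basis(np.array([[0.6], [-0.8]]), k=1)
        tab = connection_weights(basis, np.array([0, 1]), s=4)
        assert np.allclose(tab.aggregate, [0.6, 0.8])

    def test_equal_magnitude_components_aggregate_to_magnitude(self):
        basis = make_basis(np.array([[0.3, -0.3], [-0.5, 0.5]]), k=2)
        tab = connection_weights(basis, np.array([0, 1]), s=4)
        assert np.allclose(tab.aggregate, [0.3, 0.5])

    def test_svm_backprojection_mode(self):
        basis = make_basis(np.array([[0.6, 0.1], [-0.8, 0.2]]), k=2)
        model = SvmModel(weights=np.array([1.0, 2.0]), bias=0.0, hyperparams=SvmHyperparams())
        tab = connection_weights(basis, np.array([0, 1]), s=4, model=model,
                                 mode="svm_backprojection")
        assert np.allclose(tab.aggregate, [abs(0.6 + 0.2), abs(-0.8 + 0.4)])
        with pytest.raises(ValueError, match="requires"):
            connection_weights(basis, np.array([0, 1]), s=4, mode="svm_backprojection")

    def test_planted_connections_carry_more_weight(self, planted_cohort):
        # ground-truth enrichment: among selected features, the planted
        # ones should outweigh the false positives
        xp, xq = planted_cohort["x_pre"], planted_cohort["x_post"]
        chain = FeatureChain().fit(xp, xq)
        sel = chain.selection.selected_indices
        tab = connection_weights(chain.basis, sel, s=30)
        planted = set(planted_cohort["truth"].planted_indices(30).tolist())
        mask = np.array([k in planted for k in sel])
        assert mask.any() and (~mask).any()
        assert tab.aggregate[mask].mean() > tab.aggregate[~mask].mean()


class TestSeedWeights:
    def test_half_split_single_connection(self):
        tab = ConnectionWeightTable(
            connection_indices=np.array([0]),
            seed_i=np.array([0]), seed_j=np.array([1]),
            component_weights=np.array([[0.4]]), aggregate=np.array([0.4]),
            weighting_mode="loading_magnitude",
        )
        sw = seed_weights(tab, toy_atlas(4))
        assert sw.cumulative_weight[0] == pytest.approx(0.2)
        assert sw.cumulative_weight[1] == pytest.approx(0.2)
        assert np.all(sw.cumulative_weight[2:] == 0)

    def test_conservation_of_total_weight(self, planted_cohort):
        xp, xq = planted_cohort["x_pre"], planted_cohort["x_post"]
        chain = FeatureChain().fit(xp, xq)
        for mode in ("loading_magnitude", "svm_backprojection"):
            from fcstage.classify import train_svm, PRE, POST

            scores = np.vstack([chain.transform(xp), chain.transform(xq)])
            model = train_svm(scores, [PRE] * 20 + [POST] * 20)
            tab = connection_weights(
                chain.basis, chain.selection.selected_indices, s=30,
                model=model, mode=mode,
            )
            sw = seed_weights(tab, planted_cohort["atlas"])
            assert sw.half_weight_sum.sum() == pytest.approx(tab.aggregate.sum(), rel=1e-12)

    def test_star_graph_hub_mean_half_weight(self):
        # hub seed 0 in three unit-weight connections: mean half-weight 0.5
        tab = ConnectionWeightTable(
            connection_indices=np.array([0, 1, 2]),
            seed_i=np.array([0, 0, 0]), seed_j=np.array([1, 2, 3]),
            component_weights=np.ones((3, 1)), aggregate=np.ones(3),
            weighting_mode="loading_magnitude",
        )
        sw = seed_weights(tab, toy_atlas(4))
        assert sw.cumulative_weight[0] == pytest.approx(0.5)
        assert sw.n_connections[0] == 3
        assert sw.rank[0] == 1

    def test_unknown_seed_rejected(self):
        tab = ConnectionWeightTable(
            connection_indices=np.array([0]),
            seed_i=np.array([0]), seed_j=np.array([9]),
            component_weights=np.ones((1, 1)), aggregate=np.ones(1),
            weighting_mode="loading_magnitude",
        )
        with pytest.raises(ValueError):
            seed_weights(tab, toy_atlas(4))

    def test_equivariance_under_seed_relabeling(self):
        rng = np.random.default_rng(0)
        atlas = toy_atlas(8, n_networks=2)
        pairs = [(0, 3), (1, 2), (2, 5), (4, 7)]
        w = rng.uniform(0.1, 1, size=4)
        perm = rng.permutation(8)

        def table(pair_list):
            i = np.array([min(a, b) for a, b in pair_list])
            j = np.array([max(a, b) for a, b in pair_list])
            return ConnectionWeightTable(
                connection_indices=np.asarray(pair_to_index(i, j, 8)),
                seed_i=i, seed_j=j,
                component_weights=w[:, None], aggregate=w.copy(),
                weighting_mode="loading_magnitude",
            )

        sw = seed_weights(table(pairs), atlas)
        sw_p = seed_weights(table([(perm[a], perm[b]) for a, b in pairs]), atlas)
        assert np.allclose(sw_p.cumulative_weight[perm], sw.cumulative_weight)


class TestDirectionPartition:
    def test_mean_increase_is_strengthened(self):
        atlas = toy_atlas(4)
        x_pre = np.tile([0.1, 0.5, 0.0, 0.0, 0.0, 0.0], (6, 1))
        x_post = np.tile([0.3, 0.2, 0.0, 0.0, 0.0, 0.0], (6, 1))
        part = direction_partition(x_pre, x_post, np.array([0, 1]), atlas)
        assert part.direction.tolist() == ["strengthened", "weakened"]

    def test_counts_and_margins_reconcile(self, planted_cohort):
        xp, xq = planted_cohort["x_pre"], planted_cohort["x_post"]
        chain = FeatureChain().fit(xp, xq)
        part = direction_partition(
            xp, xq, chain.selection.selected_indices, planted_cohort["atlas"]
        )
        s = part.summary()
        assert part.counts.sum() == chain.selection.selected_indices.size
        assert s.loc["Overall", "Total"] == part.counts.sum()
        assert s.loc["Strengthened", "Total"] == s.loc["Strengthened", ["Motor", "Non-motor"]].sum()
        assert (s.loc["Overall", ["Motor", "Non-motor"]].sum() == s.loc["Overall", "Total"])

    def test_planted_positive_effects_labeled_strengthened(self, planted_cohort):
        xp, xq = planted_cohort["x_pre"], planted_cohort["x_post"]
        truth = planted_cohort["truth"]
        planted = truth.planted_indices(30)
        part = direction_partition(xp, xq, planted, planted_cohort["atlas"])
        frac = np.mean(part.direction == "strengthened")
        assert frac >= 0.95

    def test_motor_endpoint_rule(self):
        # restrict the motor set to the hand network: seeds 0-2 motor, 3-5 not
        atlas = toy_atlas(6, n_networks=2)
        x_pre = np.zeros((4, 15))
        x_post = np.full((4, 15), 0.1)
        k_motor = pair_to_index(0, 4, 6)  # one motor endpoint
        k_non = pair_to_index(3, 5, 6)  # none
        part = direction_partition(
            x_pre, x_post, np.array([k_motor, k_non]), atlas,
            motor_networks={"Sensory/somatomotor hand"},
        )
        assert part.motor.tolist() == [True, False]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            direction_partition(np.zeros((3, 6)), np.zeros((3, 6)), np.array([]), toy_atlas(4))


class TestPartitionTable:
    def test_reported_breakdown_margins(self):
        # strengthened (105 motor, 336 non-motor), weakened (71, 167)
        t = partition_table([[105, 336], [71, 167]])
        assert t.loc["Strengthened", "Total"] == 441
        assert t.loc["Weakened", "Total"] == 238
        assert t.loc["Overall", "Motor"] == 176
        assert t.loc["Overall", "Non-motor"] == 503
        assert t.loc["Overall", "Total"] == 679


class TestNetworkInvolvement:
    def test_cross_network_connection_counts_once_per_network(self):
        atlas = toy_atlas(6, n_networks=2)
        k = pair_to_index(0, 5, 6)
        counts = network_involvement(np.array([k]), atlas)
        assert list(counts.values()) == [1, 1]

    def test_handshake_sum(self, planted_cohort):
        chain = FeatureChain().fit(planted_cohort["x_pre"], planted_cohort["x_post"])
        sel = chain.selection.selected_indices
        counts = network_involvement(sel, planted_cohort["atlas"])
        assert sum(counts.values()) == 2 * sel.size

    def test_normalization_by_network_size(self):
        atlas = toy_atlas(6, n_networks=2)  # networks of size 3 and 3
        # four connections touching each network
        ks = [pair_to_index(i, j, 6) for i, j in [(0, 3), (1, 4), (2, 5), (0, 4)]]
        raw = network_involvement(np.array(ks), atlas)
        norm = network_involvement(np.array(ks), atlas, normalize=True)
        for name in raw:
            assert norm[name] == pytest.approx(raw[name] / 3)


def test_edge_file_symmetric_and_signed(tmp_path, planted_cohort):
    chain = FeatureChain().fit(planted_cohort["x_pre"], planted_cohort["x_post"])
    sel = chain.selection.selected_indices
    tab = connection_weights(chain.basis, sel, s=30)
    part = direction_partition(
        planted_cohort["x_pre"], planted_cohort["x_post"], sel, planted_cohort["atlas"]
    )
    path = tmp_path / "conn.edge"
    write_edge_file(tab, part.direction, 30, path)
    m = np.loadtxt(path)
    assert m.shape == (30, 30)
    assert np.allclose(m, m.T)
    assert np.all(np.diag(m) == 0)
    assert (m > 0).any() and (m < 0).any()
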