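"""Generator checks against closed-form properties of the generating MRFs."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import chain_network, gaussian_roster, partial_corr_of
from prevnet.roster import NodeSpec
from prevnet.synthetic import (
    PanelData,
    TrueNetwork,
    default_visit_distribution,
    make_default_study_networks,
    plant_edge_change,
    sample_panel,
    simulate_correlated_binary_panel,
    split_composites,
)


def one_wave_sample(net, roster, n, seed=0, **kw):
    return sample_panel([net], n_participants=n, visit_distribution=np.array([1.0]),
                        within_person_sd=0.0, seed=seed, roster=roster, **kw)


class TestSamplerDistribution:
    def test_empty_network_gives_independence(self):
        roster = gaussian_roster(4)
        net = chain_network(4, weight=0.0)
        panel = one_wave_sample(net, roster, 5000, seed=1)
        x = panel.df[[n.code for n in roster]].to_numpy()
        r = np.corrcoef(x, rowvar=False)
        off = r[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_chain_partial_correlations_match_oracle(self):
        # A-B 0.3, B-C 0.3, A-C 0: oracle from inverting the implied precision
        roster = gaussian_roster(3)
        net = chain_network(3, weight=0.3)
        oracle = partial_corr_of(net)
        panel = one_wave_sample(net, roster, 5000, seed=2)
        x = panel.df[[n.code for n in roster]].to_numpy()
        prec = np.linalg.inv(np.cov(x, rowvar=False))
        d = np.sqrt(np.diag(prec))
        pc = -prec / np.outer(d, d)
        np.fill_diagonal(pc, 0.0)
        assert np.max(np.abs(pc - oracle)) < 0.03

    def test_single_binary_node_marginal(self):
        # empirical P(x=1) matches logistic(threshold) within 3 SE at n=10000
        roster = [NodeSpec("y", "binary")]
        for thresh in (-1.0, 0.5):
            net = TrueNetwork(1, np.zeros((1, 1)), np.array([thresh]), np.ones(1))
            panel = one_wave_sample(net, roster, 10000, seed=3, burn_in=20)
            p_true = expit(thresh)
            se = np.sqrt(p_true * (1 - p_true) / 10000)
            assert abs(panel.df["y"].mean() - p_true) < 3 * se

    def test_planted_edge_sign_symmetric(self):
        # conditional association sign agrees whichever node is conditioned
        roster = gaussian_roster(3)
        net = chain_network(3, weight=0.35)
        panel = one_wave_sample(net, roster, 2000, seed=4)
        x = panel.df[["g0", "g1", "g2"]].to_numpy()
        b01 = np.linalg.lstsq(
            np.column_stack([np.ones(2000), x[:, [1, 2]]]), x[:, 0], rcond=None
        )[0][1]
        b10 = np.linalg.lstsq(
            np.column_stack([np.ones(2000), x[:, [0, 2]]]), x[:, 1], rcond=None
        )[0][1]
        assert np.sign(b01) == np.sign(b10) == 1.0

    def test_truncation_respects_scale_range(self, mixed_roster8, mixed_panel):
        for node in mixed_roster8:
            if node.scale_range is not None:
                vals = mixed_panel.df[node.code]
                assert vals.min() >= node.scale_range[0]
                assert vals.max() <= node.scale_range[1]


class TestAttendance:
    def test_visit_distribution_and_total_rows(self):
        # printed distribution (54,130,189,259)/632 gives 1917 expected rows
        dist = default_visit_distribution()
        expected = 632 * np.sum(dist * np.arange(1, 5))
        assert round(float(expected)) == 1917

        roster = gaussian_roster(3)
        nets = [chain_network(3, wave=w) for w in (1, 2, 3, 4)]
        panel = sample_panel(nets, n_participants=632, visit_distribution=dist,
                             seed=5, roster=roster)
        # multinomial sampling error on the total: sd ~ 24 rows
        assert abs(len(panel.df) - 1917) < 100
        counts = panel.df.groupby("participant_id").size().value_counts()
        observed = np.array([counts.get(k, 0) for k in (1, 2, 3, 4)])
        expected_counts = 632 * dist
        se = np.sqrt(632 * dist * (1 - dist))
        assert np.all(np.abs(observed - expected_counts) < 4 * se)

    def test_attendance_non_monotone(self):
        roster = gaussian_roster(2)
        nets = [chain_network(2, wave=w) for w in (1, 2, 3, 4)]
        panel = sample_panel(nets, 400, np.array([0, 0.5, 0.5, 0]), seed=6,
                             roster=roster)
        # some 2-visit participant attends non-adjacent waves
        gaps = panel.df.groupby("participant_id")["wave"].agg(lambda w: np.max(np.diff(sorted(w))) if len(w) > 1 else 0)
        assert (gaps > 1).any()

    def test_unique_participant_wave(self, mixed_panel):
        assert not mixed_panel.df.duplicated(["participant_id", "wave"]).any()


class TestWithinPersonCorrelation:
    @staticmethod
    def _icc(panel, code):
        wide = panel.df.pivot(index="participant_id", columns="wave", values=code).dropna()
        r = np.corrcoef(wide.to_numpy(), rowvar=False)
        return np.mean(r[np.triu_indices_from(r, 1)])

    def test_icc_positive_with_random_intercepts(self):
        roster = gaussian_roster(2)
        nets = [chain_network(2, wave=w) for w in (1, 2)]
        common = dict(visit_distribution=np.array([0.0, 1.0]), roster=roster)
        corr = sample_panel(nets, 800, within_person_sd=0.8, seed=7, **common)
        indep = sample_panel(nets, 800, within_person_sd=0.0, seed=7, **common)
        assert self._icc(corr, "g0") > 0.2
        assert abs(self._icc(indep, "g0")) < 0.1


class TestValidation:
    def test_asymmetric_weights_rejected(self):
        w = np.zeros((2, 2))
        w[0, 1] = 0.3
        with pytest.raises(ValueError, match="symmetric"):
            TrueNetwork(1, w, np.zeros(2), np.ones(2))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            TrueNetwork(1, np.eye(2), np.zeros(2), np.ones(2))

    def test_non_positive_burn_in_rejected(self):
        roster = gaussian_roster(2)
        with pytest.raises(ValueError, match="burn_in"):
            one_wave_sample(chain_network(2), roster, 10, burn_in=0)

    def test_bad_visit_distribution_rejected(self):
        roster = gaussian_roster(2)
        with pytest.raises(ValueError, match="sum to 1"):
            sample_panel([chain_network(2)], 10, np.array([0.5]), roster=roster)


class TestPlantEdgeChange:
    def test_zero_delta_is_identity(self):
        roster = gaussian_roster(3)
        nets = [chain_network(3, wave=w) for w in (1, 2)]
        out = plant_edge_change(nets, ("g0", "g2"), 0.0, [2], roster=roster)
        for a, b in zip(nets, out):
            assert np.array_equal(a.weights, b.weights)

    def test_delta_applies_to_listed_waves_only(self):
        roster = gaussian_roster(3)
        nets = [chain_network(3, wave=w) for w in (1, 2, 3, 4)]
        out = plant_edge_change(nets, ("g0", "g2"), 0.4, [4], roster=roster)
        assert out[3].weights[0, 2] - out[0].weights[0, 2] == pytest.approx(0.4)
        assert out[3].weights[2, 0] == out[3].weights[0, 2]
        assert out[0].weights[0, 2] == 0.0

    def test_self_loop_rejected(self):
        roster = gaussian_roster(3)
        with pytest.raises(ValueError, match="self-loop"):
            plant_edge_change([chain_network(3)], ("g1", "g1"), 0.1, [1], roster=roster)

    def test_unknown_edge_rejected(self):
        roster = gaussian_roster(3)
        with pytest.raises(KeyError):
            plant_edge_change([chain_network(3)], ("g0", "g9"), 0.1, [1], roster=roster)


class TestDefaultStudy:
    def test_wave1_structure_change_planted(self):
        nets = make_default_study_networks()
        assert [n.wave for n in nets] == [1, 2, 3, 4]
        from prevnet.roster import make_default_roster

        idx = {n.code: i for i, n in enumerate(make_default_roster())}
        i, j = idx["prep4"], idx["prep7"]
        assert nets[0].weights[i, j] > 0
        assert nets[1].weights[i, j] == 0
        a, b = idx["PrEP"], idx["VLS"]
        assert nets[3].weights[a, b] > nets[1].weights[a, b]

    def test_csv_round_trip(self, mixed_panel, tmp_path):
        path = tmp_path / "panel.csv"
        mixed_panel.to_csv(path)
        back = PanelData.from_csv(path, mixed_panel.roster)
        pd.testing.assert_frame_equal(
            back.df, mixed_panel.df[back.df.columns], check_dtype=False
        )

    def test_seed_determinism(self, mixed_roster8):
        nets = [chain_network(8, wave=1)]
        kw = dict(visit_distribution=np.array([1.0]), roster=gaussian_roster(8))
        a = sample_panel(nets, 100, seed=11, **kw)
        b = sample_panel(nets, 100, seed=11, **kw)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestHelpers:
    def test_split_composites_high_alpha(self, mixed_panel):
        from prevnet.scales import internal_consistency

        bank = {"b1": ["b1_1", "b1_2", "b1_3"]}
        items = split_composites(mixed_panel, bank, item_sd=0.4, seed=8)
        assert "b1" not in items.df.columns
        alpha = internal_consistency(items.df[bank["b1"]])
        assert alpha > 0.7

    def test_correlated_binary_marginals(self):
        df = simulate_correlated_binary_panel(4000, 4, intercept=-1.0,
                                              slope=0.3, icc=0.4, seed=9)
        p_hat = df.groupby("wave")["y"].mean()
        p_true = expit(-1.0 + 0.3 * np.arange(1, 5))
        se = np.sqrt(p_true * (1 - p_true) / 4000)
        assert np.all(np.abs(p_hat.to_numpy() - p_true) < 3.5 * se)
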