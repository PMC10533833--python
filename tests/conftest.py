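"""Shared fixtures: small rosters and generating networks with known truth."""

from __future__ import annotations

import numpy as np
import pytest

from prevnet.roster import NodeSpec
from prevnet.synthetic import TrueNetwork, sample_panel


def gaussian_roster(p: int, prefix: str = "g") -> list[NodeSpec]:
    return [NodeSpec(f"{prefix}{i}", "gaussian") for i in range(p)]


def chain_network(p: int, weight: float = 0.3, wave: int = 1,
                  thresholds: np.ndarray | None = None) -> TrueNetwork:
    w = np.zeros((p, p))
    for i in range(p - 1):
        w[i, i + 1] = w[i + 1, i] = weight
    tau = thresholds if thresholds is not None else np.zeros(p)
    return TrueNetwork(wave, w, tau, np.ones(p))


def partial_corr_of(net: TrueNetwork) -> np.ndarray:
    """Closed-form partial correlations of a gaussian MRF with unit
    conditional SDs: precision theta_jj = 1, theta_jk = -w_jk."""
    theta = np.eye(net.weights.shape[0]) - net.weights
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


@pytest.fixture(scope="session")
def mixed_roster8() -> list[NodeSpec]:
    return [
        NodeSpec("PrEP", "binary"),
        NodeSpec("VLS", "binary"),
        NodeSpec("b1", "gaussian", (1.0, 7.0)),
        NodeSpec("b2", "gaussian", (1.0, 7.0)),
        NodeSpec("b3", "gaussian", (1.0, 7.0)),
        NodeSpec("b4", "gaussian", (1.0, 7.0)),
        NodeSpec("b5", "gaussian", (1.0, 7.0)),
        NodeSpec("b6", "gaussian", (1.0, 7.0)),
    ]


def mixed_network8(wave: int = 1, extra: float = 0.0) -> TrueNetwork:
    """Two-block structure: PrEP-b1-b2-b3 and VLS-b5-b6 plus b3-b4."""
    p = 8
    w = np.zeros((p, p))
    for i, j, v in [(0, 2, 0.3), (2, 3, 0.3), (3, 4, 0.25), (4, 5, 0.25),
                    (1, 6, 0.3), (6, 7, 0.3)]:
        w[i, j] = w[j, i] = v
    w[2, 4] += extra
    w[4, 2] += extra
    mu = np.array([0.15, 0.10, 4, 4, 4, 4, 4, 4], dtype=float)
    from scipy.special import logit

    tau = np.where(
        np.arange(p) < 2, logit(mu) - w @ mu, mu - w @ mu
    )
    return TrueNetwork(wave, w, tau, np.ones(p))


@pytest.fixture(scope="session")
def mixed_panel(mixed_roster8):
    """Four-wave mixed panel (n=400) with a planted wave-1 structure change."""
    nets = [mixed_network8(1, extra=0.3), mixed_network8(2),
            mixed_network8(3), mixed_network8(4)]
    return sample_panel(nets, n_participants=400, within_person_sd=0.4,
                        seed=42, roster=mixed_roster8)
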