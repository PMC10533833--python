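"""Synthetic multi-wave panel generation from known pairwise Markov random fields.

The generator emulates an open prospective cohort interviewed at four
6-monthly waves: each participant attends a random subset of waves
(non-monotone attendance), and at each attended wave their node values
are drawn from that wave's mixed MRF (gaussian belief nodes, binary
behaviour nodes) by Gibbs sampling.  Participant-level random intercepts
induce within-person correlation across waves.  Because the generating
networks are known, every downstream estimate (edge weights, communities,
trend ORs, comparison-test rejections) can be checked against ground truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .roster import NodeSpec, make_default_roster, codes as roster_codes

__all__ = [
    "TrueNetwork",
    "PanelData",
    "sample_panel",
    "plant_edge_change",
    "make_default_study_networks",
    "default_visit_distribution",
    "split_composites",
    "simulate_correlated_binary_panel",
]

#: printed visit-count distribution of the cohort: 54/130/189/259 participants
#: with 1/2/3/4 visits out of 632 (1917 visits in total).
DEFAULT_VISIT_COUNTS = np.array([54, 130, 189, 259], dtype=float)


def default_visit_distribution() -> np.ndarray:
    return DEFAULT_VISIT_COUNTS / DEFAULT_VISIT_COUNTS.sum()


@dataclass
class TrueNetwork:
    """Generating pairwise MRF for one wave.

    ``weights`` is the symmetric zero-diagonal interaction matrix over the
    roster; ``thresholds`` are per-node intercepts (logit scale for binary
    nodes); ``gaussian_sd`` are conditional standard deviations of the
    gaussian nodes.  With unit conditional SDs the gaussian-gaussian
    weights equal the partial correlations of the implied joint gaussian.
    """

    wave: int
    weights: np.ndarray
    thresholds: np.ndarray
    gaussian_sd: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 0.0):
            raise ValueError("weights must have zero diagonal")
        self.weights = w
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.gaussian_sd = np.asarray(self.gaussian_sd, dtype=float)
        p = w.shape[0]
        if self.thresholds.shape != (p,) or self.gaussian_sd.shape != (p,):
            raise ValueError("thresholds and gaussian_sd must match matrix dimension")

    def copy(self) -> "TrueNetwork":
        return TrueNetwork(
            self.wave, self.weights.copy(), self.thresholds.copy(), self.gaussian_sd.copy()
        )


@dataclass
class PanelData:
    """Long-format panel: one row per (participant, attended wave)."""

    df: pd.DataFrame
    roster: list[NodeSpec] = field(default_factory=make_default_roster)

    def __post_init__(self) -> None:
        required = {"participant_id", "wave"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"panel missing columns {sorted(missing)}")
        if self.df.duplicated(["participant_id", "wave"]).any():
            raise ValueError("duplicate (participant_id, wave) rows")

    @property
    def node_codes(self) -> list[str]:
        return [n.code for n in self.roster if n.code in self.df.columns]

    def waves(self) -> list[int]:
        return sorted(self.df["wave"].unique())

    def wave_data(self, wave: int, columns: list[str] | None = None) -> pd.DataFrame:
        sub = self.df[self.df["wave"] == wave]
        return sub[columns] if columns is not None else sub

    def to_csv(self, path: str | Path) -> None:
        cols = ["participant_id", "wave"] + [c for c in self.df.columns if c not in ("participant_id", "wave")]
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, roster: list[NodeSpec] | None = None) -> "PanelData":
        df = pd.read_csv(path)
        return cls(df, roster if roster is not None else make_default_roster())


def _validate_networks(networks: list[TrueNetwork], p: int) -> None:
    for net in networks:
        if net.weights.shape != (p, p):
            raise ValueError("network dimension does not match roster size")


def _gibbs_wave(
    net: TrueNetwork,
    intercepts: np.ndarray,
    is_binary: np.ndarray,
    burn_in: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one sample per row of ``intercepts`` from the wave's MRF.

    Fixed scan order (roster order); all rows advance in lockstep, which is
    valid because rows are independent chains.
    """
    if burn_in <= 0:
        raise ValueError("burn_in must be positive")
    n, p = intercepts.shape
    x = np.empty((n, p))
    # initialize at the conditional means given zeros / random binaries
    x[:, ~is_binary] = net.thresholds[~is_binary] + intercepts[:, ~is_binary]
    x[:, is_binary] = rng.binomial(1, 0.5, size=(n, int(is_binary.sum())))
    w = net.weights
    for _ in range(burn_in):
        for j in range(p):
            eta = net.thresholds[j] + intercepts[:, j] + x @ w[:, j]
            if is_binary[j]:
                x[:, j] = rng.binomial(1, expit(eta))
            else:
                x[:, j] = eta + net.gaussian_sd[j] * rng.standard_normal(n)
    return x


def sample_panel(
    networks: list[TrueNetwork],
    n_participants: int = 632,
    visit_distribution: np.ndarray | None = None,
    within_person_sd: float = 0.5,
    burn_in: int = 200,
    seed: int = 0,
    roster: list[NodeSpec] | None = None,
    cas_coefs: tuple[float, float, float] = (-0.5, 1.0, 1.0),
    condom_coefs: tuple[float, float, float] = (0.6, -0.8, -0.5),
) -> PanelData:
    """Simulate a long-format mixed panel from per-wave generating networks.

    Per participant a visit count is drawn from ``visit_distribution`` and
    that many waves are chosen uniformly without replacement (attendance is
    non-monotone).  Node values at each attended wave are Gibbs-sampled from
    the wave's MRF with participant random intercepts ~ N(0, within_person_sd²)
    added to every node's threshold, inducing within-person correlation.
    Gaussian belief values are truncated to their scale range afterwards.
    ``cas`` (condomless anal sex with casual partners) and ``condom`` use are
    drawn per wave from logistic models on the PrEP and VLS values.
    """
    roster = roster if roster is not None else make_default_roster()
    p = len(roster)
    _validate_networks(networks, p)
    n_waves = len(networks)
    if visit_distribution is None:
        visit_distribution = default_visit_distribution()
    visit_distribution = np.asarray(visit_distribution, dtype=float)
    if visit_distribution.shape != (n_waves,):
        raise ValueError("visit_distribution must have one probability per wave count")
    if not np.isclose(visit_distribution.sum(), 1.0):
        raise ValueError("visit_distribution must sum to 1")

    rng = np.random.default_rng(seed)
    is_binary = np.array([n.is_binary for n in roster])
    node_cols = roster_codes(roster)

    intercepts = rng.normal(0.0, within_person_sd, size=(n_participants, p))
    n_visits = rng.choice(n_waves, size=n_participants, p=visit_distribution) + 1
    wave_ids = [net.wave for net in networks]
    attendance = np.zeros((n_participants, n_waves), dtype=bool)
    for i in range(n_participants):
        attendance[i, rng.choice(n_waves, size=n_visits[i], replace=False)] = True

    frames = []
    for k, net in enumerate(networks):
        active = np.flatnonzero(attendance[:, k])
        if active.size == 0:
            continue
        x = _gibbs_wave(net, intercepts[active], is_binary, burn_in, rng)
        for j, node in enumerate(roster):
            if node.scale_range is not None:
                lo, hi = node.scale_range
                x[:, j] = np.clip(x[:, j], lo, hi)
        df = pd.DataFrame(x, columns=node_cols)
        df.insert(0, "participant_id", active)
        df.insert(1, "wave", wave_ids[k])
        prep = df["PrEP"].to_numpy() if "PrEP" in df else np.zeros(len(df))
        vls = df["VLS"].to_numpy() if "VLS" in df else np.zeros(len(df))
        b0, b1, b2 = cas_coefs
        df["cas"] = rng.binomial(1, expit(b0 + b1 * prep + b2 * vls))
        g0, g1, g2 = condom_coefs
        df["condom"] = rng.binomial(1, expit(g0 + g1 * prep + g2 * vls))
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    for col in [n.code for n in roster if n.is_binary] + ["cas", "condom"]:
        out[col] = out[col].astype(int)
    return PanelData(out.sort_values(["participant_id", "wave"]).reset_index(drop=True), roster)


def plant_edge_change(
    networks: list[TrueNetwork],
    edge: tuple[str, str],
    delta: float,
    waves: list[int],
    roster: list[NodeSpec] | None = None,
) -> list[TrueNetwork]:
    """Return copies of the networks with ``delta`` added to one edge on the
    listed waves only.  Used to plant temporal structure changes."""
    roster = roster if roster is not None else make_default_roster()
    code_index = {n.code: i for i, n in enumerate(roster)}
    a, b = edge
    if a not in code_index or b not in code_index:
        raise KeyError(f"edge {edge} not in roster")
    i, j = code_index[a], code_index[b]
    if i == j:
        raise ValueError("self-loop edges are not allowed")
    out = []
    for net in networks:
        net2 = net.copy()
        if net.wave in waves:
            net2.weights[i, j] += delta
            net2.weights[j, i] += delta
        out.append(net2)
    return out


# ---------------------------------------------------------------------------
# Default study conditions: four waves, planted structure change T1 -> T2
# ---------------------------------------------------------------------------

#: edges present at every wave (code_a, code_b, weight); sparse attitude
#: structure with belief chains, a self-efficacy pair, social-norm links and
#: behaviour-belief edges in the magnitude range of reported edge weights.
#: behaviour-belief couplings are raw conditional log-odds per scale unit;
#: they are set so the *estimated* standardized mixed-model edge weights land
#: in the 0.2-0.4 range of the reported direct correlates (a raw cross-family
#: weight w yields an estimated weight near √(w·sd_belief · w·sd_binary),
#: roughly 0.4·w at these prevalences)
_BASE_EDGES = [
    ("PrEP", "prep13", 0.60),
    ("PrEP", "prep9", 0.60),
    ("PrEP", "prep1", 0.45),
    ("PrEP", "prep11", 0.45),
    ("PrEP", "age", 0.40),
    ("VLS", "vls8", 0.55),
    ("VLS", "vls5", 0.45),
    ("VLS", "age", 0.35),
    ("VLS", "sp", -0.35),
    ("riskHIV", "prep5", 0.20),
    ("prep13", "prep14", 0.25),
    ("prep15", "prep16", 0.25),
    ("prep20", "prep21", 0.35),
    ("sp", "prep1", -0.25),
]


def _chain(codes_list: list[str], weight: float) -> list[tuple[str, str, float]]:
    return [(a, b, weight) for a, b in zip(codes_list[:-1], codes_list[1:])]


def make_default_study_networks(
    roster: list[NodeSpec] | None = None,
    gaussian_sd: float = 1.0,
    within_person_sd: float = 0.5,
) -> list[TrueNetwork]:
    """Build the four generating networks of the default synthetic study.

    Structure: belief chains within the PrEP- and VLS-belief blocks plus the
    behaviour-belief edges above, constant across waves except for a planted
    change between waves 1 and 2 (the PrEP-affordability edge present at wave
    1 disappears; the PrEP-VLS coupling strengthens at wave 4).  Binary-node
    thresholds are set so that marginal PrEP uptake rises across waves
    (≈10% → ≈31%) while VLS stays near 8% and steady partner near 65%;
    gaussian thresholds are solved so that stationary belief means sit near
    the middle of the 1-7 scale (risk perception lower, near 1.9).
    """
    roster = roster if roster is not None else make_default_roster()
    p = len(roster)
    idx = {n.code: i for i, n in enumerate(roster)}
    prep_chain = _chain([f"prep{i}" for i in range(1, 22)], 0.22)
    vls_chain = _chain([f"vls{i}" for i in range(1, 10)], 0.22)

    def build_weights(extra: list[tuple[str, str, float]]) -> np.ndarray:
        w = np.zeros((p, p))
        for a, b, wt in _BASE_EDGES + prep_chain + vls_chain + extra:
            i, j = idx[a], idx[b]
            w[i, j] += wt
            w[j, i] += wt
        return w

    # planted temporal structure: wave 1 has an extra PrEP-prep7
    # (affordability) and PrEP-prep4 (efficacy) edge; wave 4 strengthens
    # the PrEP-VLS coupling.
    # the prep4-prep7 (efficacy-affordability) edge is continuous-continuous
    # so the comparison test, which only sees continuous nodes, can detect
    # the wave-1 structure difference.
    wave_extras = {
        1: [("PrEP", "prep7", 0.50), ("PrEP", "prep4", 0.35),
            ("prep4", "prep7", 0.30), ("PrEP", "VLS", 0.30)],
        2: [("PrEP", "VLS", 0.30)],
        3: [("PrEP", "VLS", 0.30)],
        4: [("PrEP", "VLS", 1.00)],
    }
    prep_uptake = {1: 0.10, 2: 0.22, 3: 0.25, 4: 0.31}

    target_mean = np.full(p, 4.0)
    target_mean[idx["age"]] = 0.0
    target_mean[idx["riskHIV"]] = 1.9
    target_mean[idx["VLS"]] = 0.08
    target_mean[idx["sp"]] = 0.65

    is_binary = np.array([n.is_binary for n in roster])
    nets = []
    for wave in (1, 2, 3, 4):
        w = build_weights(wave_extras[wave])
        mu = target_mean.copy()
        mu[idx["PrEP"]] = prep_uptake[wave]
        # gaussian stationary mean satisfies mu = tau + W mu (exact given the
        # neighbour means); binary thresholds solve the logit-normal moment
        # approximation E[sigmoid(eta)] ≈ sigmoid(m/√(1+π s²/8)) for the mean
        # m of the linear predictor, with s² the predictor variance from
        # gaussian/binary neighbours and the participant random intercept.
        neigh_var = np.where(is_binary, mu * (1 - mu), gaussian_sd**2 * 1.3)
        s2 = (w**2) @ neigh_var + within_person_sd**2
        kappa = np.sqrt(1.0 + np.pi * s2 / 8.0)
        tau = np.where(
            is_binary,
            kappa * logit(np.clip(mu, 1e-6, 1 - 1e-6)) - w @ mu,
            mu - w @ mu,
        )
        nets.append(TrueNetwork(wave, w, tau, np.full(p, gaussian_sd)))
    return nets


# ---------------------------------------------------------------------------
# Item-level expansion and correlated-binary helper
# ---------------------------------------------------------------------------

def split_composites(
    panel: PanelData,
    bank: dict[str, list[str]],
    item_sd: float = 0.6,
    seed: int = 0,
) -> PanelData:
    """Replace composite columns by noisy item replicates (common-factor style).

    Each item equals the composite value plus independent N(0, item_sd²)
    noise, clipped to the composite's scale range; the composite column is
    dropped.  The inverse of scale construction's item combination, used to
    exercise the internal-consistency gate end-to-end.
    """
    rng = np.random.default_rng(seed)
    df = panel.df.copy()
    ranges = {n.code: n.scale_range for n in panel.roster}
    for composite, items in bank.items():
        if composite not in df.columns:
            raise KeyError(f"composite {composite!r} not in panel")
        base = df[composite].to_numpy(dtype=float)
        for item in items:
            vals = base + rng.normal(0.0, item_sd, size=len(df))
            rng_pair = ranges.get(composite)
            if rng_pair is not None:
                vals = np.clip(vals, *rng_pair)
            df[item] = vals
        df = df.drop(columns=[composite])
    return PanelData(df, panel.roster)


def simulate_correlated_binary_panel(
    n_participants: int,
    n_waves: int,
    intercept: float,
    slope: float,
    icc: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary repeated-measures panel with exact marginal logits.

    A gaussian-copula construction: latent z_it = √icc·u_i + √(1−icc)·ε_it
    with u, ε standard normal; y_it = 1{z_it < Φ⁻¹(p_t)} where
    logit(p_t) = intercept + slope·t.  Marginal means are exactly p_t, so a
    marginal (GEE) logistic trend model targets ``slope`` regardless of the
    within-person correlation.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must be in [0, 1)")
    rng = np.random.default_rng(seed)
    t = np.arange(1, n_waves + 1)
    p_t = expit(intercept + slope * t)
    u = rng.standard_normal((n_participants, 1))
    eps = rng.standard_normal((n_participants, n_waves))
    z = np.sqrt(icc) * u + np.sqrt(1.0 - icc) * eps
    y = (z < norm.ppf(p_t)[None, :]).astype(int)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_participants), n_waves),
            "wave": np.tile(t, n_participants),
            "y": y.ravel(),
        }
    )
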