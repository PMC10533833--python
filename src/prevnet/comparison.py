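"""Permutation network comparison test (NCT) between two waves.

Compares two groups' EBIC-graphical-lasso networks over the continuous
nodes on three levels: global strength invariance (|difference of summed
absolute edge weights|), structure invariance (maximum absolute edge
difference), and edge-wise differences (Holm-corrected).  The null
distribution is built by pooling the rows of both groups and repeatedly
re-splitting them at random into the original group sizes, re-estimating
both networks per permutation.  Waves share participants in the cohort;
the permutation scheme nevertheless treats groups as independent — the
scheme the test supports — and this caveat is documented.

A hybrid report annotates the significant NCT edges with the edge-weight
difference taken from the mixed (all-node) networks, mirroring how
significance and magnitude come from different model families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimation import EBICGraphLasso, MGMNetwork

__all__ = ["NCTResult", "nct", "nct_pairwise_schedule", "hybrid_difference_report"]

log = logging.getLogger(__name__)

NCT_PAIRS = [(1, 4), (1, 2), (2, 3), (3, 4)]


@dataclass
class NCTResult:
    nodes: list[str]
    global_strength_a: float
    global_strength_b: float
    gs_statistic: float
    gs_p: float
    m_statistic: float
    structure_p: float
    edge_table: pd.DataFrame
    permutations: int
    seed: int
    label: str = ""
    weights_a: np.ndarray | None = None
    weights_b: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "global_strength_a": self.global_strength_a,
            "global_strength_b": self.global_strength_b,
            "gs_statistic": self.gs_statistic,
            "gs_p": self.gs_p,
            "m_statistic": self.m_statistic,
            "structure_p": self.structure_p,
            "permutations": self.permutations,
            "seed": self.seed,
            "edges": self.edge_table.to_dict(orient="records"),
        }


def _drop_id(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray | None]:
    if "participant_id" in df.columns:
        ids = df["participant_id"].to_numpy()
        return df.drop(columns=[c for c in ("participant_id", "wave") if c in df.columns]), ids
    return df, None


def nct(
    wave_data_a: pd.DataFrame,
    wave_data_b: pd.DataFrame,
    permutations: int = 1000,
    gamma: float = 0.5,
    seed: int = 0,
    n_lambda: int = 30,
    label: str = "",
) -> NCTResult:
    """Permutation network comparison test on two groups of continuous rows.

    Inputs are DataFrames whose columns are the continuous node codes (a
    ``participant_id`` column, if present, is used only for an overlap
    warning and then dropped).  P-values use the +1 continuity convention
    p = (1 + #{perm ≥ obs}) / (permutations + 1), hence lie in (0, 1].
    The lambda grid is derived once from the pooled correlation matrix, so
    every permutation is scored against the same path, and rows are pooled
    in a canonical sort order so results are invariant to swapping the
    group labels.
    """
    if permutations < 200:
        raise ValueError("permutations must be >= 200")
    a, ids_a = _drop_id(wave_data_a)
    b, ids_b = _drop_id(wave_data_b)
    if list(a.columns) != list(b.columns):
        raise ValueError("groups must share the same node columns")
    if ids_a is not None and ids_b is not None:
        overlap = np.intersect1d(ids_a, ids_b).size
        if overlap:
            warnings.warn(
                f"{overlap} participants appear in both groups; the permutation "
                "scheme treats groups as independent",
                stacklevel=2,
            )
    nodes = list(a.columns)
    p = len(nodes)
    n_a, n_b = len(a), len(b)
    n_small = min(n_a, n_b)

    pooled = np.vstack([a.to_numpy(dtype=float), b.to_numpy(dtype=float)])
    # canonical row order -> label-swap invariance of the permutation draws
    order = np.lexsort(pooled.T[::-1])
    pooled_sorted = pooled[order]

    s = np.corrcoef(pooled_sorted, rowvar=False)
    lam_max = max(np.max(np.abs(s - np.eye(p))), 1e-4)
    grid = np.logspace(np.log10(lam_max), np.log10(lam_max * 0.01), n_lambda)

    def fit_weights(x: np.ndarray) -> np.ndarray:
        return EBICGraphLasso(gamma=gamma, lambdas=grid).fit(x).partial_corr_

    iu = np.triu_indices(p, 1)

    w_a = fit_weights(a.to_numpy(dtype=float))
    w_b = fit_weights(b.to_numpy(dtype=float))
    gs_a = float(np.abs(w_a[iu]).sum())
    gs_b = float(np.abs(w_b[iu]).sum())
    obs_edge_diff = np.abs((w_a - w_b)[iu])
    gs_obs = abs(gs_a - gs_b)
    m_obs = float(obs_edge_diff.max()) if obs_edge_diff.size else 0.0

    rng = np.random.default_rng(seed)
    n_tot = n_a + n_b
    ge_gs = 0
    ge_m = 0
    ge_edge = np.zeros(len(obs_edge_diff))
    for _ in range(permutations):
        perm = rng.permutation(n_tot)
        g1 = pooled_sorted[perm[:n_small]]
        g2 = pooled_sorted[perm[n_small:]]
        w1 = fit_weights(g1)
        w2 = fit_weights(g2)
        d = np.abs((w1 - w2)[iu])
        gs_perm = abs(np.abs(w1[iu]).sum() - np.abs(w2[iu]).sum())
        if gs_perm >= gs_obs:
            ge_gs += 1
        if d.max() >= m_obs:
            ge_m += 1
        ge_edge += d >= obs_edge_diff

    denom = permutations + 1
    gs_p = (1 + ge_gs) / denom
    structure_p = (1 + ge_m) / denom
    edge_p = (1 + ge_edge) / denom
    _, edge_p_holm, _, _ = multipletests(edge_p, method="holm")

    edge_table = pd.DataFrame(
        {
            "node_i": [nodes[i] for i in iu[0]],
            "node_j": [nodes[j] for j in iu[1]],
            "diff": (w_a - w_b)[iu],
            "abs_diff": obs_edge_diff,
            "p": edge_p,
            "p_holm": edge_p_holm,
        }
    )
    return NCTResult(
        nodes=nodes,
        global_strength_a=gs_a,
        global_strength_b=gs_b,
        gs_statistic=gs_obs,
        gs_p=gs_p,
        m_statistic=m_obs,
        structure_p=structure_p,
        edge_table=edge_table,
        permutations=permutations,
        seed=seed,
        label=label,
        weights_a=w_a,
        weights_b=w_b,
    )


def nct_pairwise_schedule(
    wave_frames: dict[int, pd.DataFrame],
    permutations: int = 1000,
    gamma: float = 0.5,
    seed: int = 0,
    n_lambda: int = 30,
    pairs: list[tuple[int, int]] | None = None,
) -> list[NCTResult]:
    """Run the NCT on the study's four wave pairs: (1,4), (1,2), (2,3), (3,4)."""
    pairs = pairs if pairs is not None else NCT_PAIRS
    for wave in sorted({w for pair in pairs for w in pair}):
        if wave not in wave_frames:
            raise KeyError(f"wave {wave} missing from input")
    results = []
    for k, (wa, wb) in enumerate(pairs):
        results.append(
            nct(
                wave_frames[wa],
                wave_frames[wb],
                permutations=permutations,
                gamma=gamma,
                seed=seed + k,
                n_lambda=n_lambda,
                label=f"T{wa}-T{wb}",
            )
        )
    return results


def hybrid_difference_report(
    nct_result: NCTResult,
    mgm_a: MGMNetwork,
    mgm_b: MGMNetwork,
    display_cut: float = 0.15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Annotate significant NCT edges with mixed-network weight differences.

    Edges with Holm-adjusted NCT p < alpha get the difference (w_b − w_a)
    of the mixed networks' weights; an edge significant in the NCT but
    absent from both mixed networks is annotated 0 and flagged.  Rows with
    |difference| below ``display_cut`` stay in the machine output with
    ``in_display=False``.
    """
    idx_a = {c: i for i, c in enumerate(mgm_a.nodes)}
    idx_b = {c: i for i, c in enumerate(mgm_b.nodes)}
    missing = [c for c in nct_result.nodes if c not in idx_a or c not in idx_b]
    if missing:
        raise ValueError(f"NCT nodes {missing} absent from the mixed networks")
    sig = nct_result.edge_table[nct_result.edge_table["p_holm"] < alpha]
    rows = []
    for _, row in sig.iterrows():
        ci, cj = row["node_i"], row["node_j"]
        wa = mgm_a.weights[idx_a[ci], idx_a[cj]]
        wb = mgm_b.weights[idx_b[ci], idx_b[cj]]
        diff = wb - wa
        absent = wa == 0.0 and wb == 0.0
        rows.append(
            {
                "node_i": ci,
                "node_j": cj,
                "nct_p_holm": row["p_holm"],
                "mgm_diff": 0.0 if absent else diff,
                "absent_in_mgm": absent,
                "in_display": (not absent) and abs(diff) >= display_cut,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["node_i", "node_j", "nct_p_holm", "mgm_diff", "absent_in_mgm", "in_display"],
    )
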