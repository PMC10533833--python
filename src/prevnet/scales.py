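"""Composite-scale construction and per-wave descriptive tables.

Multi-item measures (HIV risk perception, PrEP/VLS self-efficacy) are
combined into their row-mean composite only when internal consistency
exceeds a threshold: Pearson's correlation for two items, Cronbach's
alpha for more.  Descriptives cover prevention-strategy uptake counts
per wave and belief means/SDs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import PanelData

__all__ = [
    "DEFAULT_ITEM_BANK",
    "internal_consistency",
    "combine_items",
    "describe_uptake",
    "describe_beliefs",
    "round_half_away",
]

log = logging.getLogger(__name__)

#: default composite -> item columns mapping (the questionnaire's multi-item
#: measures: 4 risk-perception items, 2 items each for the self-efficacy pairs)
DEFAULT_ITEM_BANK: dict[str, list[str]] = {
    "riskHIV": ["riskHIV_1", "riskHIV_2", "riskHIV_3", "riskHIV_4"],
    "prep20": ["prep20_1", "prep20_2"],
    "prep21": ["prep21_1", "prep21_2"],
    "vls9": ["vls9_1", "vls9_2"],
}


def internal_consistency(items: np.ndarray | pd.DataFrame) -> float:
    """Pearson correlation (2 items) or Cronbach's alpha (>2 items).

    Cronbach's alpha = k/(k-1) · (1 − Σ item variances / variance of row
    sums), with sample (n−1) variances.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2:
        raise ValueError("items must be an n x k matrix")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any():
        raise ValueError("missing values not supported")
    variances = x.var(axis=0, ddof=1)
    zero = np.flatnonzero(variances == 0.0)
    if zero.size:
        names = (
            [items.columns[i] for i in zero] if isinstance(items, pd.DataFrame) else list(zero)
        )
        raise ValueError(f"zero-variance item(s): {names}")
    if k == 2:
        return float(np.corrcoef(x[:, 0], x[:, 1])[0, 1])
    total_var = x.sum(axis=1).var(ddof=1)
    return float(k / (k - 1) * (1.0 - variances.sum() / total_var))


@dataclass
class CombineReport:
    combined: list[str] = field(default_factory=list)
    not_combined: dict[str, float] = field(default_factory=dict)
    consistency: dict[str, float] = field(default_factory=dict)


def combine_items(
    panel: PanelData,
    bank: dict[str, list[str]],
    threshold: float = 0.7,
) -> tuple[PanelData, CombineReport]:
    """Add row-mean composites for item sets passing the consistency gate.

    Composites above ``threshold`` replace their items; failing composites
    keep the raw items and are flagged in the returned report.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    df = panel.df.copy()
    report = CombineReport()
    for composite, item_cols in bank.items():
        missing = [c for c in item_cols if c not in df.columns]
        if missing:
            raise KeyError(f"items {missing} for composite {composite!r} not in panel")
        stat = internal_consistency(df[item_cols])
        report.consistency[composite] = stat
        if stat > threshold:
            df[composite] = df[item_cols].mean(axis=1)
            df = df.drop(columns=item_cols)
            report.combined.append(composite)
        else:
            report.not_combined[composite] = stat
            log.warning(
                "composite %s not combined: internal consistency %.3f <= %.2f",
                composite, stat, threshold,
            )
    return PanelData(df, panel.roster), report


def round_half_away(x: float) -> int:
    """Round half away from zero (display convention for percentages)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


#: uptake-table row label -> indicator function of (prep, vls, condom)
_UPTAKE_CATEGORIES = {
    "any_strategy": lambda p, v, c: (p | v | c),
    "condom": lambda p, v, c: c,
    "prep": lambda p, v, c: p,
    "vls": lambda p, v, c: v,
    "no_prevention": lambda p, v, c: ~(p | v | c),
    "any_biomedical": lambda p, v, c: (p | v),
    "only_prep": lambda p, v, c: p & ~v,
    "only_vls": lambda p, v, c: v & ~p,
    "both_prep_vls": lambda p, v, c: p & v,
    "no_biomedical": lambda p, v, c: ~(p | v),
}


def describe_uptake(panel: PanelData) -> pd.DataFrame:
    """Per-wave uptake table: counts and percentages of the ten strategy
    categories (any strategy, condom, PrEP, VLS, no prevention, any/only/
    both/no biomedical).  Percentages are stored unrounded with a separate
    half-away-from-zero display column."""
    for col in ("PrEP", "VLS", "condom"):
        if col not in panel.df.columns:
            raise KeyError(f"required column {col!r} missing")
    rows = []
    for wave, sub in panel.df.groupby("wave"):
        n_wave = len(sub)
        p = sub["PrEP"].astype(bool).to_numpy()
        v = sub["VLS"].astype(bool).to_numpy()
        c = sub["condom"].astype(bool).to_numpy()
        for label, fn in _UPTAKE_CATEGORIES.items():
            n = int(fn(p, v, c).sum()) if n_wave else 0
            pct = 100.0 * n / n_wave if n_wave else np.nan
            rows.append(
                {
                    "wave": wave,
                    "category": label,
                    "n": n,
                    "N": n_wave,
                    "pct": pct,
                    "pct_display": round_half_away(pct) if n_wave else None,
                }
            )
    return pd.DataFrame(rows)


def describe_beliefs(panel: PanelData, belief_codes: list[str] | None = None) -> pd.DataFrame:
    """Per-wave mean and sample SD (n−1) of each belief node, with 1-decimal
    display columns."""
    if belief_codes is None:
        belief_codes = [
            n.code for n in panel.roster
            if not n.is_binary and n.code != "age" and n.code in panel.df.columns
        ]
    rows = []
    for wave, sub in panel.df.groupby("wave"):
        for code in belief_codes:
            vals = sub[code].astype(float)
            rows.append(
                {
                    "wave": wave,
                    "node": code,
                    "n": int(vals.notna().sum()),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    out = pd.DataFrame(rows)
    out["mean_display"] = out["mean"].round(1)
    out["sd_display"] = out["sd"].round(1)
    return out
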