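"""End-to-end study orchestration.

Runs the full analysis analogue in the study's order — simulate or load
the panel, combine scales, descriptive tables, GEE trends, per-wave
networks, bootstrap accuracy, strength centrality, consensus communities,
the network-comparison schedule, and the condomless-anal-sex (CAS)
sensitivity analysis — writing each stage's outputs before the next
begins, with a manifest of seeds, versions and timings.

Stage seeds are derived from the master seed by stable hashing of stage
names, so adding a stage never shifts the randomness of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy import bootstrap_edges, casedrop_strength_stability
from .comparison import NCT_PAIRS, nct, nct_pairwise_schedule
from .descriptives import consensus_communities, global_strength, strength
from .estimation import estimate_mgm, threshold_for_display, MGMNetwork
from .roster import make_default_roster, roster_to_json, NodeSpec, gaussian_codes
from .scales import DEFAULT_ITEM_BANK, combine_items, describe_beliefs, describe_uptake
from .synthetic import (
    PanelData,
    default_visit_distribution,
    make_default_study_networks,
    sample_panel,
)
from .trends import fit_gee_trend

__all__ = ["StudyConfig", "StudyResults", "run_full_study", "filter_cas",
           "run_cas_sensitivity", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class StudyConfig:
    """Configuration of a full study run (YAML-serializable)."""

    # input
    input_mode: str = "simulate"          # "simulate" or "load"
    panel_path: str | None = None         # CSV path in load mode
    # simulation block
    n_participants: int = 632
    within_person_sd: float = 0.5
    burn_in: int = 200
    # estimation block
    gamma_mgm: float = 0.25
    gamma_glasso: float = 0.5
    rule: str = "and"
    n_lambda: int = 50
    # bootstrap block
    bootstrap_B: int = 100
    stability_B: int = 50
    drop_fractions: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7)
    # communities block
    communities_iterations: int = 100
    communities_threshold: float = 0.9
    # nct block
    nct_permutations: int = 200
    nct_n_lambda: int = 20
    nct_nodes: list[str] | None = None    # continuous subset; None = all gaussian
    # sensitivity
    cas_wave: int = 4
    # output
    display_cut: float = 0.15
    seed: int = 0
    outdir: str = "study_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drop_fractions" in payload:
            payload["drop_fractions"] = tuple(payload["drop_fractions"])
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["drop_fractions"] = list(self.drop_fractions)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    def validate(self) -> None:
        if self.input_mode not in ("simulate", "load"):
            raise ValueError("input_mode must be 'simulate' or 'load'")
        if self.input_mode == "load":
            if not self.panel_path or not Path(self.panel_path).exists():
                raise ValueError(f"panel_path {self.panel_path!r} does not exist")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")


@dataclass
class StudyResults:
    panel: PanelData
    uptake: pd.DataFrame | None = None
    beliefs: pd.DataFrame | None = None
    trends: pd.DataFrame | None = None
    networks: dict[int, MGMNetwork] = field(default_factory=dict)
    centrality: dict[int, pd.DataFrame] = field(default_factory=dict)
    bootstrap: dict[int, pd.DataFrame] = field(default_factory=dict)
    communities: dict[int, object] = field(default_factory=dict)
    stability: dict[int, object] = field(default_factory=dict)
    nct_results: list = field(default_factory=list)
    sensitivity: dict | None = None
    manifest: dict = field(default_factory=dict)


def filter_cas(panel: PanelData) -> PanelData:
    """Rows reporting condomless anal sex with casual partners (cas = 1)."""
    if "cas" not in panel.df.columns:
        raise KeyError("cas column missing")
    return PanelData(panel.df[panel.df["cas"] == 1].reset_index(drop=True), panel.roster)


def run_cas_sensitivity(
    panel: PanelData,
    wave: int = 4,
    gamma: float = 0.25,
    rule: str = "and",
    permutations: int = 200,
    nct_nodes: list[str] | None = None,
    nct_n_lambda: int = 20,
    seed: int = 0,
) -> dict:
    """Re-estimate the wave's network on the CAS subset and test structure
    invariance between the full wave and the subset with the NCT."""
    if wave not in panel.waves():
        raise KeyError(f"wave {wave} not present")
    full_wave = panel.wave_data(wave)
    cas_wave = filter_cas(panel).wave_data(wave)
    if len(cas_wave) < 50:
        raise ValueError(f"CAS subset has {len(cas_wave)} rows (< 50): aborting")
    net_full = estimate_mgm(full_wave, panel.roster, gamma=gamma, rule=rule)
    net_cas = estimate_mgm(cas_wave, panel.roster, gamma=gamma, rule=rule)
    cont = nct_nodes if nct_nodes is not None else gaussian_codes(panel.roster)
    cont = [c for c in cont if c in full_wave.columns]
    result = nct(
        full_wave[["participant_id"] + cont],
        cas_wave[["participant_id"] + cont],
        permutations=permutations,
        seed=seed,
        n_lambda=nct_n_lambda,
        label=f"T{wave}-full-vs-CAS",
    )
    return {"network_full": net_full, "network_cas": net_cas, "nct": result,
            "n_full": len(full_wave), "n_cas": len(cas_wave)}


def _write(df: pd.DataFrame, path: Path, manifest_files: list[str]) -> None:
    df.to_csv(path, index=False)
    manifest_files.append(path.name)


def run_full_study(
    config: StudyConfig,
    roster: list[NodeSpec] | None = None,
    networks=None,
) -> StudyResults:
    """Execute every stage in order, writing outputs per stage.

    ``roster``/``networks`` default to the study's 35-node roster and the
    four default generating networks; tests may pass smaller ones.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    roster = roster if roster is not None else make_default_roster()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
        "timings_s": {},
        "files": [],
    }
    files = manifest["files"]
    results = StudyResults(panel=None)  # type: ignore[arg-type]

    def timed(stage: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            manifest["failed_stage"] = stage
            _dump_manifest(manifest, outdir)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        _dump_manifest(manifest, outdir)
        return out

    # --- stage 1: panel -----------------------------------------------------
    def _panel():
        if config.input_mode == "load":
            return PanelData.from_csv(config.panel_path, roster)
        nets = networks if networks is not None else make_default_study_networks(roster)
        s = stage_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = s
        return sample_panel(
            nets,
            n_participants=config.n_participants,
            visit_distribution=default_visit_distribution() if len(nets) == 4 else np.full(len(nets), 1 / len(nets)),
            within_person_sd=config.within_person_sd,
            burn_in=config.burn_in,
            seed=s,
            roster=roster,
        )

    panel = timed("panel", _panel)
    results.panel = panel
    panel.to_csv(outdir / "panel.csv")
    roster_to_json(roster, outdir / "roster.json")
    files += ["panel.csv", "roster.json"]
    waves = panel.waves()

    # --- stage 2: scales & descriptives ------------------------------------
    def _scales():
        p = panel
        bank = {c: items for c, items in DEFAULT_ITEM_BANK.items()
                if all(i in p.df.columns for i in items)}
        if bank:
            p, report = combine_items(p, bank)
            log.info("combined composites: %s", report.combined)
        has_uptake_cols = {"PrEP", "VLS", "condom"} <= set(p.df.columns)
        uptake = describe_uptake(p) if has_uptake_cols else None
        beliefs = describe_beliefs(p)
        return p, uptake, beliefs

    panel, results.uptake, results.beliefs = timed("scales", _scales)
    if results.uptake is not None:
        _write(results.uptake, outdir / "uptake.csv", files)
    _write(results.beliefs, outdir / "beliefs.csv", files)

    # --- stage 3: GEE trends ------------------------------------------------
    def _trends():
        rows = []
        for outcome in ("PrEP", "VLS", "condom"):
            if outcome in panel.df.columns and panel.df[outcome].nunique() > 1:
                rows.append(fit_gee_trend(panel, outcome, family="binomial").as_row())
        for node in panel.node_codes:
            spec = next(n for n in panel.roster if n.code == node)
            if not spec.is_binary and node != "age":
                rows.append(fit_gee_trend(panel, node, family="gaussian").as_row())
        return pd.DataFrame(rows)

    results.trends = timed("trends", _trends)
    _write(results.trends, outdir / "trends.csv", files)

    # --- stage 4: per-wave networks ----------------------------------------
    def _networks():
        nets = {}
        for w in waves:
            nets[w] = estimate_mgm(
                panel.wave_data(w), panel.roster,
                gamma=config.gamma_mgm, rule=config.rule, n_lambda=config.n_lambda,
            )
        return nets

    results.networks = timed("networks", _networks)
    for w, net in results.networks.items():
        net.to_csv(outdir / f"edges_wave{w}.csv")
        net.to_graphml(outdir / f"network_wave{w}.graphml")
        mat = pd.DataFrame(net.weights, index=net.nodes, columns=net.nodes)
        mat.to_csv(outdir / f"matrix_wave{w}.csv")
        _write(threshold_for_display(net, config.display_cut),
               outdir / f"display_edges_wave{w}.csv", files)
        files += [f"edges_wave{w}.csv", f"network_wave{w}.graphml", f"matrix_wave{w}.csv"]

    # --- stage 5: bootstrap accuracy ---------------------------------------
    def _bootstrap():
        out = {}
        for w in waves:
            s = stage_seed(config.seed, f"bootstrap:{w}")
            manifest["stage_seeds"][f"bootstrap:{w}"] = s
            boot = bootstrap_edges(
                panel.wave_data(w), panel.roster, B=config.bootstrap_B, seed=s,
                gamma=config.gamma_mgm, rule=config.rule, n_lambda=config.n_lambda,
            )
            out[w] = boot.summary()
        return out

    results.bootstrap = timed("bootstrap", _bootstrap)
    for w, summ in results.bootstrap.items():
        _write(summ, outdir / f"bootstrap_wave{w}.csv", files)

    # --- stage 6: centrality & stability -----------------------------------
    def _centrality():
        cents, stabs = {}, {}
        for w in waves:
            cents[w] = strength(results.networks[w])
            s = stage_seed(config.seed, f"stability:{w}")
            manifest["stage_seeds"][f"stability:{w}"] = s
            stabs[w] = casedrop_strength_stability(
                panel.wave_data(w), panel.roster,
                drop_fractions=config.drop_fractions, B=config.stability_B, seed=s,
            )
        return cents, stabs

    results.centrality, results.stability = timed("centrality", _centrality)
    for w in waves:
        _write(results.centrality[w], outdir / f"centrality_wave{w}.csv", files)
        _write(results.stability[w].summary(), outdir / f"stability_wave{w}.csv", files)

    # --- stage 7: communities ----------------------------------------------
    def _communities():
        out = {}
        for w in waves:
            s = stage_seed(config.seed, f"communities:{w}")
            manifest["stage_seeds"][f"communities:{w}"] = s
            est = lambda df: estimate_mgm(df, panel.roster, gamma=config.gamma_mgm,
                                          rule=config.rule, n_lambda=config.n_lambda)
            out[w] = consensus_communities(
                panel.wave_data(w), panel.roster,
                iterations=config.communities_iterations,
                threshold=config.communities_threshold,
                seed=s, estimator=est,
            )
        return out

    results.communities = timed("communities", _communities)
    for w, cc in results.communities.items():
        path = outdir / f"communities_wave{w}.json"
        path.write_text(json.dumps({
            "iterations": cc.iterations,
            "threshold": cc.threshold,
            "clusters": cc.consensus_clusters,
            "co_membership": cc.co_membership.round(4).tolist(),
            "nodes": cc.nodes,
        }, indent=1))
        files.append(path.name)

    # --- stage 8: network comparison schedule ------------------------------
    def _nct():
        cont = config.nct_nodes if config.nct_nodes is not None else gaussian_codes(panel.roster)
        cont = [c for c in cont if c in panel.df.columns]
        frames = {w: panel.wave_data(w)[["participant_id"] + cont] for w in waves}
        s = stage_seed(config.seed, "nct")
        manifest["stage_seeds"]["nct"] = s
        pairs = [p for p in NCT_PAIRS if p[0] in waves and p[1] in waves]
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # waves share participants by design
            return nct_pairwise_schedule(
                frames, permutations=config.nct_permutations, gamma=config.gamma_glasso,
                seed=s, n_lambda=config.nct_n_lambda, pairs=pairs,
            )

    results.nct_results = timed("nct", _nct)
    (outdir / "nct.json").write_text(
        json.dumps([r.to_dict() for r in results.nct_results], indent=1, default=float)
    )
    files.append("nct.json")

    # --- stage 9: CAS sensitivity ------------------------------------------
    if config.cas_wave in waves and "cas" in panel.df.columns:
        def _cas():
            s = stage_seed(config.seed, "cas")
            manifest["stage_seeds"]["cas"] = s
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                return run_cas_sensitivity(
                    panel, wave=config.cas_wave, gamma=config.gamma_mgm, rule=config.rule,
                    permutations=config.nct_permutations, nct_nodes=config.nct_nodes,
                    nct_n_lambda=config.nct_n_lambda, seed=s,
                )

        results.sensitivity = timed("cas_sensitivity", _cas)
        (outdir / "cas_sensitivity.json").write_text(json.dumps({
            "n_full": results.sensitivity["n_full"],
            "n_cas": results.sensitivity["n_cas"],
            "structure_p": results.sensitivity["nct"].structure_p,
            "gs_p": results.sensitivity["nct"].gs_p,
        }, indent=1))
        files.append("cas_sensitivity.json")

    results.manifest = manifest
    _dump_manifest(manifest, outdir)
    return results


def _dump_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
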