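"""Config-driven orchestration of the analysis stages.

A single YAML config declares synthetic variants and the analysis settings;
:func:`run_pipeline` executes the requested stages in dependency order
(simulate -> states -> rmsf-diff / network-diff -> evb / lra), writes every
table as TSV into the output directory, and emits a JSON run report echoing
the effective config.  All randomness derives from one integer seed, so a
(config, seed) pair reproduces every numeric table bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble_io import Topology, write_per_residue_scores, write_structure
from .errors import ConfigError, LoopshiftError
from .evb import EvbParams, fep_ladder, lra_group_contribution, umbrella_profile
from .flexibility import (delta_rmsf, per_residue_ttest, rmsf_per_replica,
                          significance_report, write_projection)
from .geometry import rmsd_series
from .interactions import (DetectorConfig, interaction_occupancy,
                           network_difference, residue_projection)
from .states import (STATE_NAMES, fraction_below, label_states, rmsd_histogram,
                     state_populations)
from .synthetic import (DiabatSpec, LoopSystemSpec, PlantRule, analytic_barrier,
                        make_reference_states, plant_interactions,
                        simulate_group_energies, simulate_loop_ensemble,
                        simulate_mapping_series, sticky_transition_matrix)

log = logging.getLogger("loopshift")

PRESETS = {
    "paper_scale": {"n_replicas": 15, "n_frames": 5000},
    "quick": {"n_replicas": 3, "n_frames": 500},
}

DEFAULT_CUTOFFS = {"closed": 1.5, "open": 1.5, "wide_open": 1.5}


def _sub_seed(seed: int, stream: int) -> int:
    """Derive a stable 31-bit stream seed from the run seed."""
    ss = np.random.SeedSequence([seed, stream])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class VariantResult:
    """Everything computed for one simulated variant."""

    name: str
    spec: LoopSystemSpec
    topology: Topology
    refs: dict
    ensemble: object
    true_labels: object
    rmsd: dict = field(default_factory=dict)
    labels: object = None
    populations: object = None
    occupancy: object = None
    rmsf: object = None


def build_variant_spec(cfg: Mapping, preset: str = "quick",
                       seed: int = 0) -> LoopSystemSpec:
    """Translate a config-variant block into a :class:`LoopSystemSpec`."""
    cfg = dict(cfg or {})
    kwargs = dict(PRESETS.get(preset) or {})
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; use one of {sorted(PRESETS)}")
    if "stationary" in cfg:
        kwargs["transition_matrix"] = sticky_transition_matrix(
            cfg.pop("stationary"), mobility=cfg.pop("mobility", 0.05))
    for key in ("n_residues", "loop_span", "displacement_scale", "noise_sigma",
                "n_replicas", "n_frames", "frame_interval_ps", "start_state",
                "transition_matrix", "interaction_sites", "residue_names"):
        if key in cfg:
            kwargs[key] = cfg.pop(key)
    if "sigma_overrides" in cfg:
        kwargs["sigma_overrides"] = {int(k): float(v)
                                     for k, v in cfg.pop("sigma_overrides").items()}
    plant = cfg.pop("plant_interactions", None)
    if cfg:
        raise ConfigError(f"unknown variant keys: {sorted(cfg)}")
    if "loop_span" in kwargs:
        kwargs["loop_span"] = tuple(kwargs["loop_span"])
    if "interaction_sites" in kwargs:
        kwargs["interaction_sites"] = tuple(tuple(s) for s in kwargs["interaction_sites"])
    spec = LoopSystemSpec(seed=seed, **kwargs)
    spec._plant_rules = list(plant or [])
    return spec


def _resolve_atom(top: Topology, residue_index: int, atom_name: str) -> int:
    hits = np.nonzero((top.residue_indices == residue_index)
                      & (top.atom_names == atom_name))[0]
    if len(hits) != 1:
        raise ConfigError(f"cannot resolve atom {atom_name!r} of residue "
                          f"{residue_index} uniquely")
    return int(top.atom_ids[hits[0]])


def _make_rule(top: Topology, cfg) -> PlantRule:
    """Accept either atom ids or (residue_index, atom_name) references."""
    if isinstance(cfg, PlantRule):
        return cfg
    cfg = dict(cfg)
    for side, key in (("donor", "donor_atom_id"), ("acceptor", "acceptor_atom_id")):
        if side in cfg:
            res_idx, name = cfg.pop(side)
            cfg[key] = _resolve_atom(top, int(res_idx), str(name))
    return PlantRule(**cfg)


def run_variant(spec: LoopSystemSpec, name: str = "variant",
                cutoffs: Mapping[str, float] = DEFAULT_CUTOFFS,
                detector: DetectorConfig | None = None,
                compute_occupancy: bool = False,
                rmsf_state: str | None = None) -> VariantResult:
    """Simulate one variant and run the state/flexibility analyses on it."""
    refs, top = make_reference_states(spec)
    ensemble, truth = simulate_loop_ensemble(spec, refs, top)
    rules = [_make_rule(top, r) for r in getattr(spec, "_plant_rules", [])]
    if rules:
        ensemble = plant_interactions(ensemble, truth, rules,
                                      seed=_sub_seed(spec.seed, 7))
    fit = refs["closed"].fit_selection
    loop = refs["closed"].loop_selection
    res = VariantResult(name=name, spec=spec, topology=top, refs=refs,
                        ensemble=ensemble, true_labels=truth)
    res.rmsd = {s: rmsd_series(ensemble, refs[s], fit, loop)
                for s in ("closed", "open", "wide_open")}
    res.labels = label_states(res.rmsd["closed"], res.rmsd["open"],
                              res.rmsd["wide_open"], cutoffs)
    res.populations = state_populations(res.labels)
    ca = top.select(atom_names=["CA"], label="all-CA")
    state_filter = (res.labels, rmsf_state) if rmsf_state else None
    res.rmsf = rmsf_per_replica(ensemble, ca, fit=fit, state_filter=state_filter)
    if compute_occupancy:
        res.occupancy = interaction_occupancy(
            ensemble, res.labels, detector or DetectorConfig(hbond_mode="heavy_only"),
            variant=name)
    return res


@dataclass
class ComparisonReport:
    """Cross-variant population / flexibility / network comparison."""

    populations: pd.DataFrame
    rmsf_report: object
    network_diff: pd.DataFrame | None


def compare_variants(res_a: VariantResult, res_b: VariantResult,
                     fdr: float = 0.05, test: str = "welch",
                     network_state: str | None = None) -> ComparisonReport:
    """Join two variants' populations, test ΔRMSF, and difference networks.

    Population rows carry 3-SE intervals; residue axes must agree (network
    keys join by position even when residue names differ)."""
    rows = []
    for res in (res_a, res_b):
        for s in STATE_NAMES:
            f = res.populations.pooled[s]
            se = res.populations.se[s]
            rows.append({"variant": res.name, "state": s, "fraction": f,
                         "se": se, "lo3se": f - 3 * se, "hi3se": f + 3 * se})
    pops = pd.DataFrame(rows)
    delta = delta_rmsf(res_a.rmsf, res_b.rmsf)
    p = per_residue_ttest(res_a.rmsf, res_b.rmsf, variant=test)
    report = significance_report(delta, p, fdr=fdr, test_variant=test,
                                 topology=res_a.topology,
                                 alignment_spec=res_a.rmsf.alignment_spec)
    net = None
    if network_state is not None:
        if res_a.occupancy is None or res_b.occupancy is None:
            raise ConfigError("occupancy tables missing; enable compute_occupancy")
        net = network_difference(res_a.occupancy, res_b.occupancy, network_state)
    return ComparisonReport(populations=pops, rmsf_report=report,
                            network_diff=net)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

ALL_STAGES = ("simulate", "states", "rmsf_diff", "network_diff", "evb", "lra")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - {"seed", "outdir", "preset", *ALL_STAGES}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    for pair_stage in ("rmsf_diff", "network_diff"):
        block = cfg.get(pair_stage)
        if block and "pair" in block:
            variants = (cfg.get("simulate") or {}).get("variants", {})
            missing = set(block["pair"]) - set(variants)
            if missing:
                raise ConfigError(f"{pair_stage}.pair references unknown "
                                  f"variants: {sorted(missing)}")


def run_pipeline(config: dict, outdir, seed: int | None = None,
                 stages: tuple = ALL_STAGES) -> dict:
    """Execute the configured stages; returns the run report (also written
    as ``run_report.json`` next to the TSV tables)."""
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    preset = config.get("preset", "quick")
    report = {"version": __version__, "seed": seed, "config": config,
              "stages": {}, "warnings": []}

    def _stage(name):
        return name in stages and name in config

    variants: dict[str, VariantResult] = {}
    cutoffs = dict(DEFAULT_CUTOFFS)
    states_cfg = config.get("states") or {}
    cutoffs.update(states_cfg.get("cutoffs") or {})
    need_network = _stage("network_diff")
    net_cfg = config.get("network_diff") or {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if _stage("simulate") or _stage("states") or _stage("rmsf_diff") or need_network:
            t0 = time.perf_counter()
            sim_cfg = config.get("simulate") or {}
            rmsf_state = (config.get("rmsf_diff") or {}).get("state")
            for i, (name, vcfg) in enumerate(sorted((sim_cfg.get("variants") or {}).items())):
                spec = build_variant_spec(vcfg, preset=sim_cfg.get("preset", preset),
                                          seed=_sub_seed(seed, i))
                log.info("simulating variant %s (%d x %d frames)", name,
                         spec.n_replicas, spec.n_frames)
                detector = DetectorConfig(
                    hbond_mode=net_cfg.get("mode", "heavy_only"),
                    hbond_d_max=net_cfg.get("d_max", 3.5),
                    detect_contact=net_cfg.get("contacts", False))
                variants[name] = run_variant(
                    spec, name=name, cutoffs=cutoffs, detector=detector,
                    compute_occupancy=need_network, rmsf_state=rmsf_state)
            report["stages"]["simulate"] = {
                "variants": sorted(variants),
                "seconds": round(time.perf_counter() - t0, 2)}

        if _stage("states"):
            t0 = time.perf_counter()
            bin_width = states_cfg.get("bin_width", 0.16)
            frac_cuts = states_cfg.get("fraction_cutoffs", [1.5, 2.0])
            summary = {}
            for name, res in variants.items():
                res.labels.to_frame().to_csv(outdir / f"labels_{name}.tsv",
                                             sep="\t", index=False)
                hist = rmsd_histogram(res.rmsd["closed"], bin_width=bin_width)
                hist.to_frame().to_csv(outdir / f"histogram_closed_{name}.tsv",
                                       sep="\t", index=False)
                res.populations.to_frame().to_csv(
                    outdir / f"populations_{name}.tsv", sep="\t", index=False)
                fr_rows = []
                for cut in frac_cuts:
                    fb = fraction_below(res.rmsd["closed"], cut)
                    fr_rows.append({"cutoff": cut, "fraction": fb.pooled})
                pd.DataFrame(fr_rows).to_csv(
                    outdir / f"fraction_below_{name}.tsv", sep="\t", index=False)
                summary[name] = {
                    "populations": res.populations.pooled.to_dict(),
                    "fraction_below": {str(r["cutoff"]): r["fraction"] for r in fr_rows}}
            report["stages"]["states"] = {
                "cutoffs": cutoffs, "bin_width": bin_width, "summary": summary,
                "seconds": round(time.perf_counter() - t0, 2)}

        if _stage("rmsf_diff"):
            t0 = time.perf_counter()
            rcfg = config["rmsf_diff"] or {}
            a, b = rcfg.get("pair", sorted(variants)[:2])
            cmp_rep = compare_variants(variants[a], variants[b],
                                       fdr=rcfg.get("fdr", 0.05),
                                       test=rcfg.get("test", "welch"))
            cmp_rep.rmsf_report.to_tsv(outdir / f"rmsf_diff_{a}_vs_{b}.tsv")
            cmp_rep.populations.to_csv(outdir / f"population_compare_{a}_vs_{b}.tsv",
                                       sep="\t", index=False)
            write_projection(cmp_rep.rmsf_report, variants[a].topology,
                             variants[a].refs["closed"].coords,
                             outdir / f"rmsf_diff_{a}_vs_{b}.pdb")
            n_sig = int(cmp_rep.rmsf_report.table["significant"].sum())
            report["stages"]["rmsf_diff"] = {
                "pair": [a, b], "n_significant": n_sig,
                "fdr": rcfg.get("fdr", 0.05),
                "seconds": round(time.perf_counter() - t0, 2)}

        if _stage("network_diff"):
            t0 = time.perf_counter()
            a, b = net_cfg.get("pair", sorted(variants)[:2])
            state = net_cfg.get("state", "wide_open")
            diff = network_difference(variants[a].occupancy,
                                      variants[b].occupancy, state)
            diff.drop(columns=["key"]).to_csv(
                outdir / f"network_diff_{a}_vs_{b}_{state}.tsv",
                sep="\t", index=False)
            proj = residue_projection(diff)
            write_per_residue_scores(variants[a].topology,
                                     variants[a].refs["closed"].coords, proj,
                                     outdir / f"network_diff_{a}_vs_{b}_{state}.pdb")
            report["stages"]["network_diff"] = {
                "pair": [a, b], "state": state, "n_keys": len(diff),
                "top_delta": float(diff["delta"].iloc[0]) if len(diff) else 0.0,
                "seconds": round(time.perf_counter() - t0, 2)}

        if _stage("evb"):
            t0 = time.perf_counter()
            ecfg = dict(config["evb"] or {})
            n_bins = ecfg.pop("n_bins", 100)
            min_bin_count = ecfg.pop("min_bin_count", 10)
            dspec = DiabatSpec(seed=_sub_seed(seed, 100), **ecfg)
            series = simulate_mapping_series(dspec)
            ladder = fep_ladder(series, dspec.params())
            profile = umbrella_profile(series, dspec.params(), ladder,
                                       n_bins=n_bins, min_bin_count=min_bin_count)
            ladder.to_frame().to_csv(outdir / "evb_ladder.tsv", sep="\t", index=False)
            profile.to_frame().to_csv(outdir / "evb_profile.tsv", sep="\t", index=False)
            oracle = analytic_barrier(dspec)
            report["stages"]["evb"] = {
                "dg_activation": profile.dg_activation,
                "dg_reaction": profile.dg_reaction,
                "oracle_activation": oracle[0], "oracle_reaction": oracle[1],
                "temperature": dspec.temperature,
                "seconds": round(time.perf_counter() - t0, 2)}

        if _stage("lra"):
            t0 = time.perf_counter()
            lcfg = config["lra"] or {}
            effects = {int(k): float(v)
                       for k, v in (lcfg.get("effects") or {"1": 2.0}).items()}
            series = simulate_group_energies(
                n_frames=lcfg.get("n_frames", 10000), effects=effects,
                noise_sd=lcfg.get("noise_sd", 1.0), seed=_sub_seed(seed, 200))
            rep = lra_group_contribution(series,
                                         epsilon_in=lcfg.get("epsilon_in", 4.0))
            rep.to_tsv(outdir / "lra.tsv")
            report["stages"]["lra"] = {
                "epsilon_in": rep.epsilon_in,
                "ddg_elec": dict(zip(map(int, rep.table["residue_index"]),
                                     map(float, rep.table["ddg_elec"]))),
                "seconds": round(time.perf_counter() - t0, 2)}

        report["warnings"] = [str(w.message) for w in caught]

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
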