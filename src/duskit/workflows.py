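"""Scenario presets reproducing the study designs on synthetic data.

A scenario bundles strains, paraquat doses, oxygenation and replicate counts,
simulates every sample with seeded generators, runs the AlkAnilineSeq scoring
pipeline and the LC–MS quantification on each, and writes TSV tables plus a
deterministic manifest.  Available scenarios:

* ``pilot`` — wild type and triple knockout, 0/0.1/0.3 mM paraquat, aerobic.
* ``aerobic`` / ``anaerobic`` — wild type dose series under controlled
  oxygenation; only the aerobic series shows paraquat-dependent decreases.
* ``knockout_panel`` — WT plus single and triple knockouts (five biological
  replicates), with knockout decomposition of enzyme contributions.
* ``polysome`` — free (F0) versus polysomal (F3) tRNA fractions, identical
  occupancies by default (``f3_shift`` explores fraction-specific changes).

Every artefact is reproducible from (config, seed) alone: generators draw
from per-sample streams keyed by stable strings and outputs carry no
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aas, lcms
from .core import (
    DEFAULT_BASELINE_OCCUPANCY,
    DEFAULT_SENSITIVITY,
    ModificationProfile,
    effective_occupancy,
    strain_config,
)
from .simulate import (
    AASLibraryParams,
    LcmsSimParams,
    build_fixture_references,
    simulate_aas_library,
    simulate_lcms_replicates,
)

SCENARIOS = ("pilot", "aerobic", "anaerobic", "knockout_panel", "polysome")

_FLOAT_FORMAT = "%.6g"


def _scenario_defaults(name: str) -> dict:
    common = {"replicates": 3, "paraquat_mM": [0.0, 0.1, 0.3], "strains": ["WT"], "aerobic": True}
    presets = {
        "pilot": {**common, "strains": ["WT", "triple"]},
        "aerobic": dict(common),
        "anaerobic": {**common, "aerobic": False},
        "knockout_panel": {
            "replicates": 5,
            "paraquat_mM": [0.0],
            "strains": ["WT", "dusA", "dusB", "dusC", "triple"],
            "aerobic": True,
        },
        "polysome": {
            "replicates": 3,
            "paraquat_mM": [0.0, 0.3],
            "strains": ["WT", "dusA", "dusB", "dusC"],
            "aerobic": True,
        },
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    return presets[name]


@dataclass
class ScenarioConfig:
    """Full description of a synthetic experiment (see module docstring)."""

    scenario: str
    seed: int
    n_trnas: int = 20
    baseline_occupancy: float = DEFAULT_BASELINE_OCCUPANCY
    replicates: int = 3
    paraquat_mM: list[float] = field(default_factory=lambda: [0.0, 0.1, 0.3])
    strains: list[str] = field(default_factory=lambda: ["WT"])
    aerobic: bool = True
    sensitivity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    aas_params: dict = field(default_factory=dict)
    lcms_params: dict = field(default_factory=dict)
    f3_shift: float = 1.0
    run_aas: bool = True

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required (no silent nondeterminism)")

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        scenario = data.pop("scenario")
        if "seed" not in data:
            raise ValueError("config must set a seed")
        defaults = _scenario_defaults(scenario)
        merged = {**defaults, **data}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(merged) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(scenario=scenario, **{k: v for k, v in merged.items() if k != "scenario"})

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _derived_seed(seed: int, key: str) -> int:
    digest = hashlib.sha256(f"{seed}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _condition_name(strain: str, pq: float, fraction: str | None) -> str:
    name = f"{strain}_pq{pq:g}"
    return f"{name}_{fraction}" if fraction else name


def _scaled(profile: ModificationProfile, factor: float) -> ModificationProfile:
    return ModificationProfile(
        occupancy={site: min(1.0, occ * factor) for site, occ in profile.occupancy.items()},
        enzymes=dict(profile.enzymes),
    )


def run_scenario(config: ScenarioConfig, out_dir) -> dict[str, Path]:
    """Simulate and analyse a scenario; returns {artifact name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    bundle = build_fixture_references(config.n_trnas, seed=_derived_seed(config.seed, "bundle"))
    baseline = bundle.baseline_profile(config.baseline_occupancy)
    fractions = ["F0", "F3"] if config.scenario == "polysome" else [None]

    conditions: list[tuple[str, ModificationProfile]] = []
    for strain_name in config.strains:
        for pq in config.paraquat_mM:
            sc = strain_config(strain_name, paraquat_mM=pq, aerobic=config.aerobic,
                               sensitivity=config.sensitivity)
            profile = effective_occupancy(baseline, sc)
            for fraction in fractions:
                cond_profile = profile
                if fraction == "F3" and config.f3_shift != 1.0:
                    cond_profile = _scaled(profile, config.f3_shift)
                conditions.append((_condition_name(strain_name, pq, fraction), cond_profile))

    # ---- LC-MS quantification -------------------------------------------
    lcms_tables = {}
    for name, profile in conditions:
        params = LcmsSimParams(**{**config.lcms_params, "seed": _derived_seed(config.seed, f"lcms:{name}")})
        lcms_tables[name] = simulate_lcms_replicates(
            bundle, profile, name, config.replicates, params
        )
    nucleoside_table = pd.concat(lcms_tables.values(), ignore_index=True)
    path = out / "nucleoside_table.tsv"
    nucleoside_table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    written["nucleoside_table"] = path

    control_name = _condition_name(config.strains[0], config.paraquat_mM[0], fractions[0])
    levels = [
        lcms.relative_d_level(lcms_tables[name], lcms_tables[control_name], sample_name=name)
        for name, _ in conditions
    ]
    path = out / "relative_levels.tsv"
    lcms.relative_levels_table(levels).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    written["relative_levels"] = path

    if config.scenario == "knockout_panel":
        by_name = {lv.sample: lv.mean for lv in levels}
        wt = by_name[control_name]
        knockouts = {}
        for enzyme, strain_name in (("DusA", "dusA"), ("DusB", "dusB"), ("DusC", "dusC")):
            key = _condition_name(strain_name, config.paraquat_mM[0], fractions[0])
            if key in by_name:
                knockouts[enzyme] = by_name[key]
        if knockouts:
            decomposition = lcms.decompose_contributions(wt, knockouts)
            rows = [{"enzyme": e, "contribution_percent": c}
                    for e, c in sorted(decomposition.contributions.items())]
            rows.append({"enzyme": "residual", "contribution_percent": decomposition.residual})
            path = out / "contributions.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
            written["contributions"] = path

    # ---- AlkAnilineSeq ---------------------------------------------------
    if config.run_aas:
        profiles: dict[str, aas.StopProfile] = {}
        for name, profile in conditions:
            params = AASLibraryParams(
                **{**config.aas_params, "seed": _derived_seed(config.seed, f"aas:{name}")}
            )
            reads, _truth = simulate_aas_library(bundle, profile, params)
            aligned, _report = aas.map_reads(
                [(r.read_id, r.sequence) for r in reads], bundle
            )
            stop = aas.stop_ratio(aas.tally(aligned, bundle))
            profiles[name] = stop
            table = aas.stop_profile_table(stop, bundle)
            path = out / f"stop_ratios_{name}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
            written[f"stop_ratios_{name}"] = path
            calls = aas.infer_d_positions(stop, bundle, mode="annotated")
            path = out / f"calls_{name}.tsv"
            aas.calls_table(calls).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
            written[f"calls_{name}"] = path

        comparisons = []
        if config.scenario == "polysome":
            for strain_name in config.strains:
                for pq in config.paraquat_mM:
                    f3 = _condition_name(strain_name, pq, "F3")
                    f0 = _condition_name(strain_name, pq, "F0")
                    if f3 in profiles and f0 in profiles:
                        comparisons.append((f3, f0))
        else:
            for strain_name in config.strains:
                untreated = _condition_name(strain_name, config.paraquat_mM[0], None)
                for pq in config.paraquat_mM[1:]:
                    treated = _condition_name(strain_name, pq, None)
                    if treated in profiles and untreated in profiles:
                        comparisons.append((treated, untreated))
        for treated, control in comparisons:
            comparison = aas.compare_conditions(profiles[treated], profiles[control])
            path = out / f"comparison_{treated}_vs_{control}.tsv"
            comparison.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
            written[f"comparison_{treated}_vs_{control}"] = path
            summary = aas.enzyme_level_summary(comparison, bundle.annotations)
            path = out / f"enzyme_summary_{treated}_vs_{control}.tsv"
            summary.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
            written[f"enzyme_summary_{treated}_vs_{control}"] = path

    # ---- manifest and log ------------------------------------------------
    manifest_rows = []
    for name in sorted(written):
        digest = hashlib.sha256(written[name].read_bytes()).hexdigest()
        manifest_rows.append({"artifact": name, "file": written[name].name, "sha256": digest})
    manifest_path = out / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    written["manifest"] = manifest_path

    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        fh.write(f"scenario\t{config.scenario}\n")
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"config_hash\t{config.config_hash()}\n")
        fh.write(f"n_outputs\t{len(manifest_rows)}\n")
    written["log"] = log_path
    return written
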