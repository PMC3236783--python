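"""Scenario configuration and the end-to-end simulate -> call -> compare workflow.

A scenario YAML bundles the simulation settings, the three assay profiles
and the calling parameters; :func:`run_scenario` chains cohort generation,
both assay simulations, both callers and the agreement analysis, writing all
intermediates plus a manifest so a run is reproducible byte-for-byte from
its config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import agreement, io, prt, qpcr
from .simulate import (
    ROLE_PRT_PAIR,
    ROLE_QPCR_REFERENCE,
    ROLE_QPCR_TARGET,
    AssayProfile,
    ConfigurationError,
    SimulationConfig,
    cohort_to_frame,
    make_cohort,
    simulate_prt_run,
    simulate_qpcr_plate,
)

__all__ = ["CallingParams", "ScenarioConfig", "run_scenario", "bundled_scenario_path"]

logger = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclasses.dataclass(frozen=True)
class CallingParams:
    """Parameters of the shared maximum-likelihood integer-assignment engine."""

    sigma0: float = 0.1
    cv: float = 0.05
    k_max: int = 10


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """A complete study condition: simulation, assays, anchoring, calling."""

    simulation: SimulationConfig
    target_assay: AssayProfile
    reference_assay: AssayProfile
    prt_assay: AssayProfile
    modal_cn: int = 2
    calling: CallingParams = dataclasses.field(default_factory=CallingParams)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        assays = d.pop("assays", None)
        if not assays:
            raise ConfigurationError("scenario config requires an 'assays' section")
        try:
            target = AssayProfile(role=ROLE_QPCR_TARGET, **assays["qpcr_target"])
            reference = AssayProfile(role=ROLE_QPCR_REFERENCE, **assays["qpcr_reference"])
            prt_assay = AssayProfile(role=ROLE_PRT_PAIR, **assays["prt"])
        except KeyError as exc:
            raise ConfigurationError(f"assays section missing {exc}") from None
        modal_cn = int(d.pop("modal_cn", 2))
        calling = CallingParams(**d.pop("calling", {}))
        unknown = set(d) - _SIM_KEYS
        if unknown:
            raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
        sim = SimulationConfig.from_dict(d)
        return cls(
            simulation=sim,
            target_assay=target,
            reference_assay=reference,
            prt_assay=prt_assay,
            modal_cn=modal_cn,
            calling=calling,
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: scenario config must be a mapping")
        return cls.from_dict(data)


def bundled_scenario_path(name: str) -> Path:
    """Path of a scenario config shipped with the package.

    Bundled scenarios: ``normalized_intact``, ``nonnormalized``, ``degraded``,
    ``defb4_modal4``.
    """
    from importlib.resources import files

    path = files("cnvassay").joinpath("scenarios", f"{name}.yaml")
    if not path.is_file():
        raise FileNotFoundError(f"no bundled scenario named {name!r}")
    return Path(str(path))


def run_scenario(config_path, out_dir, seed: int | None = None) -> io.RunManifest:
    """Execute simulate -> call-qpcr -> call-prt -> concord for one scenario.

    Writes ``truth.csv``, ``ct_table.csv``, ``peak_table.csv``,
    ``calls_qpcr.csv``, ``calls_prt.csv`` and ``report.json`` under
    ``out_dir``, plus ``manifest.json``.  ``seed`` overrides the config's
    seed; all randomness flows from it.  Reruns with the same config and
    seed reproduce byte-identical tables.
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = ScenarioConfig.from_yaml(config_path)
    sim = scenario.simulation if seed is None else scenario.simulation.with_seed(seed)
    calling = scenario.calling

    rng = np.random.default_rng(sim.seed)
    outputs = []

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"scenario stage {name!r} failed: {exc}") from exc

    cohort = _stage("simulate", lambda: make_cohort(sim, rng))
    outputs.append(io.write_table(cohort_to_frame(cohort), out_dir / "truth.csv"))

    ct_table = _stage(
        "simulate",
        lambda: simulate_qpcr_plate(
            cohort, scenario.target_assay, scenario.reference_assay, sim, rng
        ),
    )
    outputs.append(io.write_table(ct_table, out_dir / "ct_table.csv"))

    peak_table = _stage(
        "simulate", lambda: simulate_prt_run(cohort, scenario.prt_assay, sim, rng)
    )
    outputs.append(io.write_table(peak_table, out_dir / "peak_table.csv"))

    calls_q = _stage(
        "call-qpcr",
        lambda: qpcr.call_qpcr(
            ct_table, scenario.modal_cn, sigma0=calling.sigma0, cv=calling.cv, k_max=calling.k_max
        ),
    )
    outputs.append(io.write_table(calls_q[io.CALLS_COLUMNS], out_dir / "calls_qpcr.csv"))

    calls_p = _stage(
        "call-prt",
        lambda: prt.call_prt(
            peak_table,
            scenario.modal_cn,
            scenario.prt_assay.reference_copies,
            sigma0=calling.sigma0,
            cv=calling.cv,
            k_max=calling.k_max,
        ),
    )
    outputs.append(io.write_table(calls_p[io.CALLS_COLUMNS], out_dir / "calls_prt.csv"))

    report = _stage("concord", lambda: _concordance_report(calls_p, calls_q))
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2) + "\n")
    outputs.append(report_path)

    manifest = io.RunManifest(
        command=f"run-scenario --config {config_path.name} --seed {sim.seed}",
        config_hash=io.file_sha256(config_path),
        seed=sim.seed,
        input_files=[str(config_path)],
        output_files=[p.name for p in outputs],
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def _concordance_report(calls_prt_, calls_qpcr_) -> dict:
    """Agreement statistics with PRT on rows and qPCR on columns."""
    matrix = agreement.concordance_matrix(
        calls_prt_, calls_qpcr_, method_a="prt", method_b="qpcr"
    )
    rates = agreement.concordance_rates(matrix)
    merged = calls_prt_.merge(
        calls_qpcr_, on="sample_id", suffixes=("_prt", "_qpcr")
    )
    ba = agreement.bland_altman(
        merged["continuous_cn_prt"], merged["continuous_cn_qpcr"]
    )
    try:
        chi2 = agreement.distribution_chi2(
            merged["predicted_cn_prt"], merged["predicted_cn_qpcr"]
        )._asdict()
    except ValueError:
        chi2 = None  # too few copy-number classes (e.g. an invariant-CN cohort)
    return {
        "n": matrix.n_total,
        "method_a": matrix.method_a,
        "method_b": matrix.method_b,
        "matrix": matrix.counts.tolist(),
        "frac_same": rates.frac_same,
        "frac_qpcr_higher": rates.frac_b_higher,
        "frac_qpcr_lower": rates.frac_b_lower,
        "bland_altman": ba.to_dict(),
        "distribution_chi2": chi2,
    }
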