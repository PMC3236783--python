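"""Generative model of qPCR and PRT copy-number assays.

Simulates cohorts of samples with known integer copy numbers, then the
threshold cycles (Ct) a duplex TaqMan-style qPCR would report and the peak
areas a paralog ratio test (PRT) would report for each sample, under
configurable amplification efficiencies, input-DNA amounts and template
degradation.

Two failure mechanisms of real assays are represented mechanistically:

* **Efficiency mismatch x input amount.** Each assay amplifies from ``N``
  template molecules as ``N * (1 + E)**c`` and crosses a fixed detection
  threshold ``T`` at ``Ct = log10(T / N) / log10(1 + E)``.  When target and
  reference efficiencies differ, their dilution slopes ``-1/log10(1+E)``
  differ, so dCt (and with it the called copy number) drifts with the amount
  of input DNA.
* **Degradation x amplicon length.** Random fragmentation of genomic DNA
  with mean fragment length ``lambda`` leaves a fraction ``exp(-L/lambda)``
  of templates intact across an ``L`` bp amplicon, so longer amplicons lose
  more amplifiable template.  The number of amplifiable molecules is then a
  Poisson draw, which adds spread (without bias) to ratio-based calls.

Peak areas are modelled at the ratio-relevant level only: no plateau
kinetics, heteroduplex formation, digestion efficiency or electrophoresis
physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HAPLOID_GENOMES_PER_NG",
    "MAX_CT",
    "ROLE_QPCR_TARGET",
    "ROLE_QPCR_REFERENCE",
    "ROLE_PRT_PAIR",
    "ConfigurationError",
    "AssayProfile",
    "SampleProfile",
    "InputModel",
    "DegradationModel",
    "SimulationConfig",
    "intact_fraction",
    "make_cohort",
    "simulate_ct",
    "simulate_qpcr_plate",
    "simulate_prt_run",
    "cohort_to_frame",
]

#: Haploid human genome equivalents per ng of genomic DNA (3.3 pg / haploid genome).
HAPLOID_GENOMES_PER_NG = 303.0

#: Reactions are cycled 40 times; a Ct beyond this is reported as missing.
MAX_CT = 40.0

ROLE_QPCR_TARGET = "qpcr_target"
ROLE_QPCR_REFERENCE = "qpcr_reference"
ROLE_PRT_PAIR = "prt_pair"

CT_TABLE_COLUMNS = ["sample_id", "replicate_index", "ct_target", "ct_reference", "input_mass"]
PEAK_TABLE_COLUMNS = ["sample_id", "replicate_index", "area_target", "area_paralog"]
TRUTH_COLUMNS = ["sample_id", "true_cn", "input_mass", "mean_fragment_length"]


class ConfigurationError(ValueError):
    """Invalid simulation configuration or assay/role mismatch."""


@dataclass(frozen=True)
class AssayProfile:
    """A PCR assay: efficiency, amplicon geometry and its role in the workflow.

    Parameters
    ----------
    name : str
        Assay label (e.g. the gene it targets).
    efficiency : float
        Per-cycle amplification efficiency E in (0, 1.2]; 1.0 means perfect
        doubling each cycle.
    amplicon_length : float
        Amplicon length in bp (>= 50).  For a PRT pair this is the length of
        the amplicon over the copy-variable (target) locus.
    role : str
        One of ``qpcr_target``, ``qpcr_reference``, ``prt_pair``.
    paralog_length : float, optional
        PRT only: amplicon length over the fixed-copy paralog locus, bp.
    reference_copies : int, optional
        PRT only: copy number of the paralog locus per diploid genome.
    intercept : float, optional
        Ct at one genome-copy equivalent of template; purely informational
        (simulation works from the detection threshold instead).
    """

    name: str
    efficiency: float
    amplicon_length: float
    role: str
    paralog_length: float | None = None
    reference_copies: int | None = None
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency <= 1.2:
            raise ConfigurationError(
                f"assay {self.name!r}: efficiency must be in (0, 1.2], got {self.efficiency}"
            )
        if self.amplicon_length < 50:
            raise ConfigurationError(
                f"assay {self.name!r}: amplicon_length must be >= 50 bp, got {self.amplicon_length}"
            )
        if self.role not in (ROLE_QPCR_TARGET, ROLE_QPCR_REFERENCE, ROLE_PRT_PAIR):
            raise ConfigurationError(f"assay {self.name!r}: unknown role {self.role!r}")
        if self.role == ROLE_PRT_PAIR:
            if self.paralog_length is None or self.reference_copies is None:
                raise ConfigurationError(
                    f"assay {self.name!r}: prt_pair requires paralog_length and reference_copies"
                )
            if self.paralog_length < 50:
                raise ConfigurationError(
                    f"assay {self.name!r}: paralog_length must be >= 50 bp"
                )
            if self.reference_copies < 1:
                raise ConfigurationError(
                    f"assay {self.name!r}: reference_copies must be >= 1"
                )


@dataclass(frozen=True)
class SampleProfile:
    """Ground truth for one simulated sample."""

    sample_id: str
    true_cn: int
    input_mass: float  # ng DNA per reaction
    mean_fragment_length: float = math.inf  # bp; inf = intact genomic DNA
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if self.true_cn < 0:
            raise ConfigurationError(f"{self.sample_id}: true_cn must be >= 0")
        if not self.input_mass > 0:
            raise ConfigurationError(f"{self.sample_id}: input_mass must be > 0")
        if not self.mean_fragment_length > 0:
            raise ConfigurationError(f"{self.sample_id}: mean_fragment_length must be > 0")


@dataclass(frozen=True)
class InputModel:
    """Per-reaction input DNA amount: fixed (normalized) or lognormal.

    ``normalized`` fixes every sample at ``ng`` (default 5 ng/reaction:
    2.5 ng/ul x 2 ul).  ``lognormal`` draws masses with arithmetic mean
    ``mean_ng`` and log-scale SD ``sigma_log``.
    """

    kind: str = "normalized"
    ng: float = 5.0
    mean_ng: float = 13.28
    sigma_log: float = 0.7

    def __post_init__(self) -> None:
        if self.kind not in ("normalized", "lognormal"):
            raise ConfigurationError(f"unknown input model kind {self.kind!r}")
        if self.kind == "normalized" and not self.ng > 0:
            raise ConfigurationError("normalized input requires ng > 0")
        if self.kind == "lognormal" and (not self.mean_ng > 0 or self.sigma_log < 0):
            raise ConfigurationError("lognormal input requires mean_ng > 0 and sigma_log >= 0")


@dataclass(frozen=True)
class DegradationModel:
    """Template integrity: intact DNA or degraded with per-sample fragment length.

    Degraded cohorts are heterogeneous: each sample's mean fragment length is
    drawn lognormally with median ``mean_fragment_length`` and log-scale SD
    ``sigma_log`` (0 = every sample identically degraded).
    """

    kind: str = "intact"
    mean_fragment_length: float = 300.0
    sigma_log: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("intact", "degraded"):
            raise ConfigurationError(f"unknown degradation model kind {self.kind!r}")
        if self.kind == "degraded" and (
            not self.mean_fragment_length > 0 or self.sigma_log < 0
        ):
            raise ConfigurationError(
                "degraded model requires mean_fragment_length > 0 and sigma_log >= 0"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the simulator needs besides the assay profiles.

    ``detection_threshold`` is the number of molecule-equivalents at which a
    qPCR reaction crosses threshold; only Ct differences matter downstream,
    so its absolute scale is arbitrary.  ``poisson_template`` switches the
    Poisson sampling of amplifiable molecules off for closed-form checks.
    """

    n_samples: int = 100
    cn_distribution: Mapping[int, float] = field(default_factory=lambda: {2: 1.0})
    input_model: InputModel = field(default_factory=InputModel)
    degradation_model: DegradationModel = field(default_factory=DegradationModel)
    ct_noise_sd: float = 0.08  # cycles, additive Gaussian on Ct
    area_noise_cv: float = 0.02  # multiplicative Gaussian on peak areas
    pcr_cycles: int = 26  # PRT cycle count (pre-plateau)
    detection_threshold: float = 1e10
    n_replicates_qpcr: int = 3
    n_replicates_prt: int = 1
    poisson_template: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if not self.cn_distribution:
            raise ConfigurationError("cn_distribution must be non-empty")
        probs = np.asarray(list(self.cn_distribution.values()), dtype=float)
        keys = list(self.cn_distribution.keys())
        if any((not float(k).is_integer()) or k < 0 for k in keys):
            raise ConfigurationError("cn_distribution keys must be integers >= 0")
        if (probs < 0).any():
            raise ConfigurationError("cn_distribution probabilities must be >= 0")
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ConfigurationError(
                f"cn_distribution must sum to 1, got {probs.sum():.8f}"
            )
        if self.ct_noise_sd < 0 or self.area_noise_cv < 0:
            raise ConfigurationError("noise magnitudes must be >= 0")
        if self.pcr_cycles < 1 or self.detection_threshold <= 0:
            raise ConfigurationError("pcr_cycles >= 1 and detection_threshold > 0 required")
        if self.n_replicates_qpcr < 1 or self.n_replicates_prt < 1:
            raise ConfigurationError("replicate counts must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "input_model" in d and isinstance(d["input_model"], Mapping):
            d["input_model"] = InputModel(**d["input_model"])
        if "degradation_model" in d and isinstance(d["degradation_model"], Mapping):
            d["degradation_model"] = DegradationModel(**d["degradation_model"])
        if "cn_distribution" in d:
            d["cn_distribution"] = {int(k): float(v) for k, v in d["cn_distribution"].items()}
        if "detection_threshold" in d:
            d["detection_threshold"] = float(d["detection_threshold"])
        return cls(**d)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def intact_fraction(amplicon_length: float, mean_fragment_length: float) -> float:
    """Fraction of templates intact across an amplicon under random breakage.

    With breakpoints falling uniformly at rate ``1/mean_fragment_length``, the
    probability that no break interrupts an ``L`` bp stretch is
    ``exp(-L / mean_fragment_length)``.  Monotonically decreasing in amplicon
    length and increasing in fragment length; 1.0 for intact DNA
    (``mean_fragment_length = inf``).
    """
    if not amplicon_length > 0:
        raise ValueError(f"amplicon_length must be > 0, got {amplicon_length}")
    if not mean_fragment_length > 0:
        raise ValueError(f"mean_fragment_length must be > 0, got {mean_fragment_length}")
    return float(np.exp(-amplicon_length / mean_fragment_length))


def _intact_fraction_vec(amplicon_length: float, mean_fragment_length: np.ndarray) -> np.ndarray:
    return np.exp(-amplicon_length / mean_fragment_length)


def make_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SampleProfile]:
    """Draw a cohort of samples with integer copy numbers, input masses and integrity.

    Deterministic under a fixed ``config.seed`` (when no external ``rng`` is
    supplied).  Copy numbers follow ``cn_distribution``; input masses follow
    the input model; degraded cohorts get per-sample fragment lengths.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    cns = sorted(config.cn_distribution)
    probs = np.asarray([config.cn_distribution[k] for k in cns], dtype=float)
    probs = probs / probs.sum()
    true_cn = rng.choice(np.asarray(cns, dtype=int), size=n, p=probs)

    im = config.input_model
    if im.kind == "normalized":
        mass = np.full(n, im.ng)
    else:
        mu = math.log(im.mean_ng) - 0.5 * im.sigma_log**2
        mass = rng.lognormal(mean=mu, sigma=im.sigma_log, size=n)

    dm = config.degradation_model
    if dm.kind == "intact":
        frag = np.full(n, math.inf)
    elif dm.sigma_log > 0:
        frag = rng.lognormal(mean=math.log(dm.mean_fragment_length), sigma=dm.sigma_log, size=n)
    else:
        frag = np.full(n, dm.mean_fragment_length)

    label = f"{im.kind}_{dm.kind}"
    return [
        SampleProfile(
            sample_id=f"S{i + 1:04d}",
            true_cn=int(true_cn[i]),
            input_mass=float(mass[i]),
            mean_fragment_length=float(frag[i]),
            cohort_label=label,
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: Sequence[SampleProfile]) -> pd.DataFrame:
    """Ground-truth table for a cohort (the ``truth.csv`` schema)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort],
            "true_cn": [s.true_cn for s in cohort],
            "input_mass": [s.input_mass for s in cohort],
            "mean_fragment_length": [s.mean_fragment_length for s in cohort],
        }
    )


def _locus_copies(sample: SampleProfile, role: str, reference_copies: int | None = None) -> float:
    """Template molecules carrying the assayed locus in one reaction."""
    genomes = sample.input_mass * HAPLOID_GENOMES_PER_NG
    if role == ROLE_QPCR_TARGET:
        return genomes * sample.true_cn / 2.0
    if role == ROLE_QPCR_REFERENCE:
        return genomes  # 2 copies per diploid genome = 1 per haploid equivalent
    raise ConfigurationError(f"unexpected role {role!r}")


def simulate_ct(
    sample: SampleProfile,
    assay: AssayProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """One qPCR threshold cycle; ``nan`` means no amplification (missing).

    ``Ct = (log10(T) - log10(N)) / log10(1 + E) + eps`` where ``N`` is the
    number of amplifiable template molecules (Poisson around
    copies x intact fraction unless ``poisson_template`` is off) and ``eps``
    is Gaussian with SD ``ct_noise_sd``.  Reactions with no amplifiable
    template, or crossing threshold beyond 40 cycles, return ``nan``.
    """
    if assay.role not in (ROLE_QPCR_TARGET, ROLE_QPCR_REFERENCE):
        raise ConfigurationError(
            f"simulate_ct requires a qPCR assay, got role {assay.role!r}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = _locus_copies(sample, assay.role) * intact_fraction(
        assay.amplicon_length, sample.mean_fragment_length
    )
    n_templates = float(rng.poisson(lam)) if config.poisson_template else lam
    if n_templates <= 0:
        return float("nan")
    ct = (math.log10(config.detection_threshold) - math.log10(n_templates)) / math.log10(
        1.0 + assay.efficiency
    )
    if config.ct_noise_sd > 0:
        ct += rng.normal(0.0, config.ct_noise_sd)
    return float("nan") if ct > MAX_CT else float(ct)


def simulate_qpcr_plate(
    cohort: Sequence[SampleProfile],
    target_assay: AssayProfile,
    reference_assay: AssayProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ct table for a duplex qPCR run: one row per sample x replicate.

    Target and reference are read out from the same template mass but with
    independent Poisson template sampling (distinct loci) and independent Ct
    noise.  Missing Cts (no template, or Ct > 40) are ``nan``.
    """
    if target_assay.role != ROLE_QPCR_TARGET:
        raise ConfigurationError(
            f"target assay must have role {ROLE_QPCR_TARGET!r}, got {target_assay.role!r}"
        )
    if reference_assay.role != ROLE_QPCR_REFERENCE:
        raise ConfigurationError(
            f"reference assay must have role {ROLE_QPCR_REFERENCE!r}, got {reference_assay.role!r}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = len(cohort)
    reps = config.n_replicates_qpcr
    mass = np.asarray([s.input_mass for s in cohort])
    cn = np.asarray([s.true_cn for s in cohort], dtype=float)
    frag = np.asarray([s.mean_fragment_length for s in cohort])
    genomes = mass * HAPLOID_GENOMES_PER_NG

    cts = {}
    for assay, copies in (
        (target_assay, genomes * cn / 2.0),
        (reference_assay, genomes),
    ):
        lam = copies * _intact_fraction_vec(assay.amplicon_length, frag)
        lam = np.broadcast_to(lam[:, None], (n, reps))
        templates = (
            rng.poisson(lam).astype(float) if config.poisson_template else np.array(lam)
        )
        with np.errstate(divide="ignore"):
            ct = (np.log10(config.detection_threshold) - np.log10(templates)) / np.log10(
                1.0 + assay.efficiency
            )
        if config.ct_noise_sd > 0:
            ct = ct + rng.normal(0.0, config.ct_noise_sd, size=(n, reps))
        ct[(templates <= 0) | (ct > MAX_CT)] = np.nan
        cts[assay.role] = ct

    return pd.DataFrame(
        {
            "sample_id": np.repeat([s.sample_id for s in cohort], reps),
            "replicate_index": np.tile(np.arange(1, reps + 1), n),
            "ct_target": cts[ROLE_QPCR_TARGET].ravel(),
            "ct_reference": cts[ROLE_QPCR_REFERENCE].ravel(),
            "input_mass": np.repeat(mass, reps),
        }
    )


def simulate_prt_run(
    cohort: Sequence[SampleProfile],
    prt_assay: AssayProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Peak-area table for a PRT run: one row per sample x replicate.

    A single primer pair amplifies the target and paralog loci with one
    shared efficiency, for a fixed pre-plateau cycle count.  Each peak area
    is ``N_intact * (1 + E)**cycles * (1 + eps)`` with ``N_intact`` Poisson
    around copies x intact fraction of the locus's full amplicon, and
    multiplicative Gaussian noise of CV ``area_noise_cv``.  The expected area
    ratio equals ``true_cn / reference_copies`` for any degradation level;
    degradation only adds template-sampling spread.
    """
    if prt_assay.role != ROLE_PRT_PAIR:
        raise ConfigurationError(
            f"PRT assay must have role {ROLE_PRT_PAIR!r}, got {prt_assay.role!r}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = len(cohort)
    reps = config.n_replicates_prt
    mass = np.asarray([s.input_mass for s in cohort])
    cn = np.asarray([s.true_cn for s in cohort], dtype=float)
    frag = np.asarray([s.mean_fragment_length for s in cohort])
    genomes = mass * HAPLOID_GENOMES_PER_NG
    gain = (1.0 + prt_assay.efficiency) ** config.pcr_cycles

    areas = {}
    for key, copies, length in (
        ("area_target", genomes * cn / 2.0, prt_assay.amplicon_length),
        ("area_paralog", genomes * prt_assay.reference_copies / 2.0, prt_assay.paralog_length),
    ):
        lam = copies * _intact_fraction_vec(length, frag)
        lam = np.broadcast_to(lam[:, None], (n, reps))
        templates = (
            rng.poisson(lam).astype(float) if config.poisson_template else np.array(lam)
        )
        area = templates * gain
        if config.area_noise_cv > 0:
            area = area * (1.0 + rng.normal(0.0, config.area_noise_cv, size=(n, reps)))
        areas[key] = np.maximum(area, 0.0)

    return pd.DataFrame(
        {
            "sample_id": np.repeat([s.sample_id for s in cohort], reps),
            "replicate_index": np.tile(np.arange(1, reps + 1), n),
            "area_target": areas["area_target"].ravel(),
            "area_paralog": areas["area_paralog"].ravel(),
        }
    )
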