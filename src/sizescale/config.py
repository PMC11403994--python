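"""Configuration objects for the synthetic single-cell feature generator.

The generator emulates per-cell feature tables exported by high-content
screening platforms: lognormal cell areas, intensity channels following a
power law in cell area (mean intensity = ``a * A**b``), bimodal integrated
DNA content, a nuclear-area/cell-area coupling, crowding (neighbour
fraction), and cell-cycle-stage-dependent PCNA/CCNA2 marker features.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

from .errors import ConfigurationError

#: Interphase cell-cycle stages, in cycle order. Mitosis ("M") is handled
#: separately through ``mitotic_fraction``.
STAGES = ("G0", "G1", "earlyS", "S", "G2")

COMPARTMENTS = ("whole_cell", "nucleus", "cytoplasm")

PRESETS = ("breast_default", "constant_nuclear", "flat_actin", "custom")


@dataclass(frozen=True)
class ChannelSpec:
    """One stained intensity channel measured over one compartment.

    The mean (per-pixel) intensity of the channel in a cell of area ``A``
    is generated as ``a * A**b``, multiplied by ``dna_bin_factor`` for
    cells in the upper half of the DNA-content distribution and by
    multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (median 1, so the power law is unbiased in log space).
    """

    name: str
    compartment: str
    a: float
    b: float
    noise_cv: float = 0.2
    dna_bin_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ConfigurationError(
                f"unknown compartment {self.compartment!r}; "
                f"valid compartments: {', '.join(COMPARTMENTS)}"
            )
        if not self.a > 0:
            raise ConfigurationError(f"channel {self.name!r}: amplitude a must be > 0")
        if self.noise_cv < 0:
            raise ConfigurationError(f"channel {self.name!r}: noise_cv must be >= 0")
        if not self.dna_bin_factor > 0:
            raise ConfigurationError(
                f"channel {self.name!r}: dna_bin_factor must be > 0"
            )

    @property
    def column(self) -> str:
        """Column stem used in generated tables (``<name>_<compartment>``)."""
        return f"{self.name}_{self.compartment}"


@dataclass(frozen=True)
class DnaBimodal:
    """Two-mode lognormal mixture for integrated DNA-stain intensity.

    ``low_mode``/``high_mode`` are the pre- and post-replication modes
    (2N vs 4N, ratio 1:2 by default). ``mixing_fraction`` is the high-mode
    weight used when no stage structure is generated; with stage features
    enabled the mode of each cell follows its cell-cycle stage instead.
    """

    low_mode: float = 1.0
    high_mode: float = 2.0
    mixing_fraction: float = 0.5
    cv: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.mixing_fraction <= 1.0):
            raise ConfigurationError("dna mixing_fraction must be in [0, 1]")
        if self.cv < 0:
            raise ConfigurationError("dna cv must be >= 0")
        if not (0 < self.low_mode <= self.high_mode):
            raise ConfigurationError("require 0 < low_mode <= high_mode")


@dataclass(frozen=True)
class NuclearCoupling:
    """Nuclear area model: ``nuclear_area = kappa * area**gamma * noise``.

    The result is capped at 90% of the cell area so the nucleus always
    fits inside the cell.
    """

    kappa: float = 0.25
    gamma: float = 1.0
    noise_cv: float = 0.15

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ConfigurationError("nuclear coupling kappa must be > 0")
        if self.noise_cv < 0:
            raise ConfigurationError("nuclear coupling noise_cv must be >= 0")


@dataclass(frozen=True)
class StageFeatures:
    """Gaussian (mean, sd) parameters of the cycle-marker features for one stage."""

    pcna: tuple[float, float]
    ccna2: tuple[float, float]
    spottiness: tuple[float, float]

    def __post_init__(self) -> None:
        for fname in ("pcna", "ccna2", "spottiness"):
            mean, sd = getattr(self, fname)
            if sd < 0:
                raise ConfigurationError(f"stage feature {fname}: sd must be >= 0")


def _default_stage_features() -> dict[str, StageFeatures]:
    # Separable marker distributions: PCNA rises from G0 through S, CCNA2
    # rises monotonically toward G2/M, and the PCNA texture score
    # ("spottiness", a scalar surrogate for punctate replication foci)
    # is high only in S phase.
    return {
        "G0": StageFeatures(pcna=(0.15, 0.05), ccna2=(0.15, 0.05), spottiness=(0.10, 0.06)),
        "G1": StageFeatures(pcna=(0.65, 0.08), ccna2=(0.20, 0.06), spottiness=(0.15, 0.06)),
        "earlyS": StageFeatures(pcna=(0.75, 0.08), ccna2=(0.55, 0.06), spottiness=(0.30, 0.08)),
        "S": StageFeatures(pcna=(0.85, 0.08), ccna2=(0.70, 0.07), spottiness=(0.80, 0.08)),
        "G2": StageFeatures(pcna=(0.80, 0.08), ccna2=(0.90, 0.07), spottiness=(0.20, 0.08)),
        "M": StageFeatures(pcna=(0.85, 0.08), ccna2=(0.95, 0.08), spottiness=(0.45, 0.10)),
    }


def _default_stage_mix() -> dict[str, float]:
    # Proportions chosen so the early-S fraction equals one quarter of the
    # PCNA+/CCNA2+ pool (earlyS + S + G2), matching the first-quartile
    # rule used by the sequential classifier.
    return {"G0": 0.10, "G1": 0.40, "earlyS": 0.125, "S": 0.15, "G2": 0.225}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of one synthetic cell population.

    Parameters
    ----------
    n_cells : int
        Number of cells (rows) to generate.
    seed : int
        Seed for the random generator; a fixed seed reproduces the table
        bit for bit.
    area_log_mean, area_log_sd : float
        Mean and SD of log2 cell area (units: log2 um^2). The default SD
        of 0.5 puts three standard deviations at an 8-fold size range
        about the mean.
    channels : tuple of ChannelSpec
        Intensity channels to simulate.
    dna_bimodal : DnaBimodal
        DNA-content mixture parameters.
    nuclear_coupling : NuclearCoupling
        Nuclear-area/cell-area power-law coupling.
    neighbour_beta : (float, float)
        Beta distribution parameters for the neighbour fraction on [0, 1].
    mitotic_fraction : float
        Fraction of cells in mitosis (flagged and given condensed-DNA
        Hoechst signatures).
    border_fraction : float
        Fraction of cells flagged as touching the image border.
    stage_mix : dict
        Interphase stage proportions over ``STAGES``; must sum to 1.
    stage_features : dict or None
        Per-stage marker feature parameters; ``None`` disables stage
        structure (DNA content then follows the plain bimodal mixture).
    line_id : str
        Label written to the ``line_id`` column.
    """

    n_cells: int = 5000
    seed: int = 0
    area_log_mean: float = 9.2
    area_log_sd: float = 0.5
    channels: tuple[ChannelSpec, ...] = ()
    dna_bimodal: DnaBimodal = field(default_factory=DnaBimodal)
    nuclear_coupling: NuclearCoupling = field(default_factory=NuclearCoupling)
    neighbour_beta: tuple[float, float] = (2.0, 5.0)
    mitotic_fraction: float = 0.02
    border_fraction: float = 0.05
    stage_mix: dict = field(default_factory=_default_stage_mix)
    stage_features: dict | None = field(default_factory=_default_stage_features)
    line_id: str = "synthline_0"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.area_log_sd < 0:
            raise ConfigurationError("area_log_sd must be >= 0")
        for frac_name in ("mitotic_fraction", "border_fraction"):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{frac_name} must be in [0, 1]")
        a, b = self.neighbour_beta
        if a <= 0 or b <= 0:
            raise ConfigurationError("neighbour_beta parameters must be > 0")
        unknown = set(self.stage_mix) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages in stage_mix: {sorted(unknown)}")
        total = sum(self.stage_mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigurationError(f"stage_mix must sum to 1 (got {total})")
        if any(p < 0 for p in self.stage_mix.values()):
            raise ConfigurationError("stage_mix proportions must be >= 0")
        if self.stage_features is not None:
            missing = [s for s in (*STAGES, "M") if s not in self.stage_features]
            if missing:
                raise ConfigurationError(
                    f"stage_features missing entries for: {missing}"
                )


def _yap_channels() -> tuple[ChannelSpec, ...]:
    return (
        ChannelSpec("yap", "whole_cell", a=5000.0, b=-0.5, noise_cv=0.2, dna_bin_factor=1.4),
        ChannelSpec("yap", "nucleus", a=300.0, b=0.0, noise_cv=0.2, dna_bin_factor=1.4),
        ChannelSpec("yap", "cytoplasm", a=6000.0, b=-0.55, noise_cv=0.2, dna_bin_factor=1.3),
    )


def make_default_config(preset: str, **overrides) -> GeneratorConfig:
    """Build a validated :class:`GeneratorConfig` from a named preset.

    Presets
    -------
    ``breast_default``
        Sub-scaling whole-cell YAP (b = -0.5), size-invariant nuclear YAP
        (b = 0), sub-scaling cytoplasmic YAP, and linearly scaling F-actin
        (concentration b = 0, hence 1:1 abundance scaling).
    ``constant_nuclear``
        YAP channels only; emphasizes the constant-nuclear regime.
    ``flat_actin``
        A single area-independent F-actin channel.
    ``custom``
        A skeleton with no channels; populate via keyword overrides or
        :func:`dataclasses.replace`.

    Any field of :class:`GeneratorConfig` may be overridden by keyword.
    """
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; valid presets: {', '.join(PRESETS)}"
        )
    if preset == "breast_default":
        channels = _yap_channels() + (
            ChannelSpec("actin", "whole_cell", a=150.0, b=0.0, noise_cv=0.2),
        )
    elif preset == "constant_nuclear":
        channels = _yap_channels()
    elif preset == "flat_actin":
        channels = (ChannelSpec("actin", "whole_cell", a=150.0, b=0.0, noise_cv=0.2),)
    else:
        channels = ()
    cfg = GeneratorConfig(channels=channels)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """Serialize a config to plain JSON/YAML-compatible types."""
    d = asdict(cfg)
    d["channels"] = [asdict(ch) for ch in cfg.channels]
    if cfg.stage_features is not None:
        d["stage_features"] = {
            stage: {
                "pcna": list(sf.pcna),
                "ccna2": list(sf.ccna2),
                "spottiness": list(sf.spottiness),
            }
            for stage, sf in cfg.stage_features.items()
        }
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    """Inverse of :func:`config_to_dict`."""
    d = dict(d)
    d["channels"] = tuple(ChannelSpec(**ch) for ch in d.get("channels", ()))
    if d.get("dna_bimodal") is not None and not isinstance(d["dna_bimodal"], DnaBimodal):
        d["dna_bimodal"] = DnaBimodal(**d["dna_bimodal"])
    if d.get("nuclear_coupling") is not None and not isinstance(
        d["nuclear_coupling"], NuclearCoupling
    ):
        d["nuclear_coupling"] = NuclearCoupling(**d["nuclear_coupling"])
    if d.get("neighbour_beta") is not None:
        d["neighbour_beta"] = tuple(d["neighbour_beta"])
    sf = d.get("stage_features")
    if sf is not None:
        d["stage_features"] = {
            stage: StageFeatures(
                pcna=tuple(v["pcna"]),
                ccna2=tuple(v["ccna2"]),
                spottiness=tuple(v["spottiness"]),
            )
            for stage, v in sf.items()
        }
    return GeneratorConfig(**d)


def config_hash(cfg: GeneratorConfig | dict) -> str:
    """Short stable hash of a config, used to tag derived outputs."""
    d = config_to_dict(cfg) if isinstance(cfg, GeneratorConfig) else cfg
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
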