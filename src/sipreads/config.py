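"""Configuration parsing and validation.

Simulations are driven by a single YAML configuration file naming the
input paths, the simulation mode, and every physical/sequencing
parameter.  Validation is aggregated: all problems are reported in one
:class:`ConfigurationError` rather than one at a time.  Unit
conversions happen at parse time -- angles may be given in degrees
(with an explicit ``angle_unit``), rotor speed as ``rpm``, tube
geometry in cm or mm (explicit ``length_unit``) -- so that everything
downstream is radians/(rad/s)/cm.

SIP and shotgun runs use the same configuration file; only the mode
differs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .community import FractionSet, FractionSizeModel
from .exceptions import ConfigurationError
from .fragments import FragmentSizeModel
from .gradient import BDWindow, GradientParams

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "load_config", "config_to_dict"]

MODES = ("window", "fractions", "shotgun")
_GRADIENT_KEYS = {
    "temperature",
    "avg_density",
    "angular_velocity",
    "rpm",
    "r_min",
    "r_max",
    "tube_radius",
    "tube_angle",
    "angle_unit",
    "length_unit",
    "beta",
    "buoyancy_factor",
    "base_pair_mass",
    "gas_constant",
}


@dataclass
class SimulationConfig:
    """Fully validated parameters for one simulation run."""

    mode: str
    seed: int
    reference_dir: Path
    community_table: Path
    output_dir: Path
    incorporator_table: Path | None = None
    gradient: GradientParams = field(default_factory=GradientParams)
    window: BDWindow | None = None
    fractions: FractionSet | None = None
    size_model: FragmentSizeModel = field(default_factory=FragmentSizeModel)
    coverage: float = 2.0
    p_dbl: float = 0.001
    read_length: int = 151
    insert_mean: float = 1000.0
    insert_sd: float = 5.0
    total_pairs: int = 100_000
    output_format: str = "fasta"
    error_platform: str = "novaseq-like"
    threads: int = 1


def _require(raw: dict, key: str, errors: list[str], context: str = ""):
    if key not in raw or raw[key] is None:
        errors.append(f"missing required key {context}{key!r}")
        return None
    return raw[key]


def _build_gradient(raw: dict, errors: list[str]) -> GradientParams:
    unknown = set(raw) - _GRADIENT_KEYS
    if unknown:
        errors.append(f"unknown gradient keys: {sorted(unknown)}")
    kwargs = {}
    geometry_given = any(k in raw for k in ("r_min", "r_max", "tube_radius"))
    if geometry_given:
        unit = raw.get("length_unit")
        if unit not in ("cm", "mm"):
            errors.append(
                "gradient geometry requires an explicit length_unit of 'cm' or 'mm' "
                f"(got {unit!r})"
            )
            unit = "cm"
        scale = 1.0 if unit == "cm" else 0.1
        for key in ("r_min", "r_max", "tube_radius"):
            if key in raw:
                kwargs[key] = float(raw[key]) * scale
    if "tube_angle" in raw:
        angle_unit = raw.get("angle_unit")
        if angle_unit not in ("degrees", "radians"):
            errors.append(
                "tube_angle requires an explicit angle_unit of 'degrees' or 'radians' "
                f"(got {angle_unit!r})"
            )
            angle_unit = "radians"
        angle = float(raw["tube_angle"])
        kwargs["tube_angle"] = math.radians(angle) if angle_unit == "degrees" else angle
    if "rpm" in raw and "angular_velocity" in raw:
        errors.append("give either rpm or angular_velocity, not both")
    elif "rpm" in raw:
        kwargs["angular_velocity"] = float(raw["rpm"]) * 2.0 * math.pi / 60.0
    elif "angular_velocity" in raw:
        kwargs["angular_velocity"] = float(raw["angular_velocity"])
    for key in (
        "temperature",
        "avg_density",
        "beta",
        "buoyancy_factor",
        "base_pair_mass",
        "gas_constant",
    ):
        if key in raw:
            kwargs[key] = float(raw[key])
    try:
        return GradientParams(**kwargs)
    except ConfigurationError as exc:
        errors.append(str(exc))
        return GradientParams()


def _build_size_model(raw: dict, errors: list[str]) -> tuple[FragmentSizeModel, float]:
    coverage = float(raw.get("coverage", 2.0))
    kwargs = {}
    for key in ("family", "location", "scale", "skew", "min_bp", "max_bp"):
        if key in raw:
            kwargs[key] = raw[key]
    try:
        model = FragmentSizeModel(**kwargs)
    except (ConfigurationError, TypeError) as exc:
        errors.append(f"fragments: {exc}")
        model = FragmentSizeModel()
    return model, coverage


def _build_fractions(raw: dict, seed: int, errors: list[str]) -> FractionSet | None:
    try:
        if "boundaries" in raw:
            return FractionSet.from_boundaries([float(b) for b in raw["boundaries"]])
        from .community import generate_fractions

        rho_min = _require(raw, "rho_min", errors, "fractions.")
        rho_max = _require(raw, "rho_max", errors, "fractions.")
        if rho_min is None or rho_max is None:
            return None
        size = FractionSizeModel(
            mean=float(raw.get("mean", 0.004)),
            sd=float(raw.get("sd", 0.0003)),
            min_size=float(raw.get("min_size", 0.002)),
        )
        return generate_fractions(float(rho_min), float(rho_max), size, rng_seed=seed)
    except ConfigurationError as exc:
        errors.append(f"fractions: {exc}")
        return None


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML simulation configuration.

    Relative paths are resolved against the config file's directory.
    All validation problems are aggregated into one error.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")

    errors: list[str] = []
    base = path.parent

    mode = raw.get("mode")
    if mode not in MODES:
        errors.append(f"mode must be one of {MODES}, got {mode!r}")
    seed = raw.get("seed")
    if not isinstance(seed, int):
        errors.append("seed is mandatory and must be an integer (no silent nondeterminism)")
        seed = 0

    paths_raw = raw.get("paths", {})
    ref_dir = _require(paths_raw, "reference_dir", errors, "paths.")
    community = _require(paths_raw, "community_table", errors, "paths.")
    out_dir = _require(paths_raw, "output_dir", errors, "paths.")
    incorporator = paths_raw.get("incorporator_table")
    if mode in ("window", "fractions") and incorporator is None:
        errors.append("paths.incorporator_table is required for SIP modes")

    def _resolve(p):
        return (base / p).resolve() if p is not None else None

    ref_dir, community, incorporator = _resolve(ref_dir), _resolve(community), _resolve(incorporator)
    out_dir = _resolve(out_dir)
    for label, p, must_exist in (
        ("reference_dir", ref_dir, True),
        ("community_table", community, True),
        ("incorporator_table", incorporator, incorporator is not None),
    ):
        if p is not None and must_exist and not p.exists():
            errors.append(f"paths.{label} does not exist: {p}")

    gradient = _build_gradient(raw.get("gradient", {}) or {}, errors)
    size_model, coverage = _build_size_model(raw.get("fragments", {}) or {}, errors)

    window = None
    fractions = None
    if mode == "window":
        wraw = raw.get("window") or {}
        rho_min = _require(wraw, "rho_min", errors, "window.")
        rho_max = _require(wraw, "rho_max", errors, "window.")
        if rho_min is not None and rho_max is not None:
            try:
                window = BDWindow(float(rho_min), float(rho_max), label=wraw.get("label", "window"))
            except ConfigurationError as exc:
                errors.append(f"window: {exc}")
    elif mode == "fractions":
        fraw = raw.get("fractions")
        if fraw is None:
            errors.append("mode=fractions requires a 'fractions' section")
        else:
            fractions = _build_fractions(fraw, seed, errors)

    reads_raw = raw.get("reads", {}) or {}
    read_length = int(reads_raw.get("read_length", 151))
    insert_mean = float(reads_raw.get("insert_mean", 1000.0))
    insert_sd = float(reads_raw.get("insert_sd", 5.0))
    total_pairs = int(reads_raw.get("total_pairs", 100_000))
    output_format = reads_raw.get("format", "fasta")
    if output_format not in ("fasta", "fastq"):
        errors.append(f"reads.format must be 'fasta' or 'fastq', got {output_format!r}")
    if read_length < 1:
        errors.append(f"reads.read_length must be >= 1, got {read_length}")
    if insert_mean < read_length:
        errors.append(
            f"reads.insert_mean ({insert_mean}) must be >= read_length ({read_length})"
        )
    if total_pairs < 0:
        errors.append(f"reads.total_pairs must be >= 0, got {total_pairs}")

    p_dbl = float(raw.get("p_dbl", 0.001))
    if not 0 <= p_dbl < 1:
        errors.append(f"p_dbl must lie in [0, 1), got {p_dbl}")
    threads = int(raw.get("threads", 1))
    if threads < 1:
        errors.append(f"threads must be >= 1, got {threads}")
    error_platform = raw.get("error_platform", "novaseq-like")

    if errors:
        raise ConfigurationError(
            "invalid configuration:\n  - " + "\n  - ".join(errors)
        )

    cfg = SimulationConfig(
        mode=mode,
        seed=seed,
        reference_dir=ref_dir,
        community_table=community,
        incorporator_table=incorporator,
        output_dir=out_dir,
        gradient=gradient,
        window=window,
        fractions=fractions,
        size_model=size_model,
        coverage=coverage,
        p_dbl=p_dbl,
        read_length=read_length,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        total_pairs=total_pairs,
        output_format=output_format,
        error_platform=error_platform,
        threads=threads,
    )
    for key, value in sorted(config_to_dict(cfg).items()):
        logger.info("config %s = %r", key, value)
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Canonical flat dict of every resolved parameter (for logs and the
    run manifest)."""
    d = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "reference_dir": str(cfg.reference_dir),
        "community_table": str(cfg.community_table),
        "incorporator_table": str(cfg.incorporator_table) if cfg.incorporator_table else None,
        "output_dir": str(cfg.output_dir),
        "coverage": cfg.coverage,
        "p_dbl": cfg.p_dbl,
        "read_length": cfg.read_length,
        "insert_mean": cfg.insert_mean,
        "insert_sd": cfg.insert_sd,
        "total_pairs": cfg.total_pairs,
        "output_format": cfg.output_format,
        "error_platform": cfg.error_platform,
        "threads": cfg.threads,
        "size_model": {
            "family": cfg.size_model.family,
            "location": cfg.size_model.location,
            "scale": cfg.size_model.scale,
            "skew": cfg.size_model.skew,
            "min_bp": cfg.size_model.min_bp,
            "max_bp": cfg.size_model.max_bp,
        },
        "gradient": {
            "temperature": cfg.gradient.temperature,
            "avg_density": cfg.gradient.avg_density,
            "angular_velocity": cfg.gradient.angular_velocity,
            "r_min": cfg.gradient.r_min,
            "r_max": cfg.gradient.r_max,
            "tube_radius": cfg.gradient.tube_radius,
            "tube_angle": cfg.gradient.tube_angle,
            "beta": cfg.gradient.beta,
            "buoyancy_factor": cfg.gradient.buoyancy_factor,
            "base_pair_mass": cfg.gradient.base_pair_mass,
            "gas_constant": cfg.gradient.gas_constant,
        },
    }
    if cfg.window is not None:
        d["window"] = {"rho_min": cfg.window.rho_min, "rho_max": cfg.window.rho_max}
    if cfg.fractions is not None:
        d["fractions"] = [[w.rho_min, w.rho_max] for w in cfg.fractions]
    return d
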