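"""Ready-to-run synthetic experiment fixtures.

Writes a small, self-contained SIP experiment to a directory: synthetic
genomes spanning a G+C range, a lognormal community table, an
incorporator table, and a YAML configuration -- everything needed to run
a simulation without downloading anything.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .community import CommunityProfile, IncorporatorTable, write_community_table
from .synthetic import SyntheticGenomeSpec, make_genome, write_genome_fasta

__all__ = ["make_fixture_set"]

DEFAULT_GC_TARGETS = (0.35, 0.40, 0.50, 0.60, 0.65)


def make_fixture_set(
    outdir: str | Path,
    seed: int = 0,
    gc_targets: tuple[float, ...] = DEFAULT_GC_TARGETS,
    genome_length: int = 100_000,
    drift_amplitude: float = 0.03,
    labeled: dict[int, tuple[str, float, float]] | None = None,
    abundances: tuple[float, ...] | None = None,
    sample_id: str = "sample_1",
    mode: str = "window",
    window: tuple[float, float] = (1.72, 1.77),
    total_pairs: int = 20_000,
    read_length: int = 151,
    coverage: float = 2.0,
) -> Path:
    """Create a complete fixture experiment under ``outdir``.

    ``labeled`` maps genome index -> (isotope, mean atom % excess,
    SD atom % excess); the default labels the 40% G+C genome fully with
    13C.  ``abundances`` overrides the lognormal community draw with
    explicit relative abundances (must sum to 1).

    Returns the path of the written config file.
    """
    outdir = Path(outdir)
    refs_dir = outdir / "references"
    refs_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    names = []
    for i, gc in enumerate(gc_targets):
        name = f"genome_gc{int(round(gc * 100)):02d}_{i + 1}"
        spec = SyntheticGenomeSpec(
            length=genome_length,
            gc=gc,
            drift_amplitude=drift_amplitude,
            seed=int(rng.integers(0, 2**31 - 1)),
            name=name,
        )
        write_genome_fasta(make_genome(spec), refs_dir / f"{name}.fasta")
        names.append(name)

    if abundances is None:
        draws = rng.lognormal(mean=np.log(0.02), sigma=0.8, size=len(names))
        abundances = tuple(draws / draws.sum())
    profile = CommunityProfile(sample_id=sample_id, abundances=dict(zip(names, abundances)))
    write_community_table({sample_id: profile}, outdir / "community.tsv")

    if labeled is None:
        labeled = {1: ("13C", 100.0, 0.0)} if len(names) > 1 else {}
    table = IncorporatorTable()
    for idx, (isotope, mean, sd) in labeled.items():
        table.add(sample_id, names[idx], isotope, mean, sd)
    table.to_tsv(outdir / "incorporators.tsv")

    config = {
        "mode": mode,
        "seed": seed,
        "paths": {
            "reference_dir": "references",
            "community_table": "community.tsv",
            "incorporator_table": "incorporators.tsv",
            "output_dir": "output",
        },
        "gradient": {
            "temperature": 293.15,
            "avg_density": 1.70,
            "rpm": 55000,
            "r_min": 2.6,
            "r_max": 4.85,
            "tube_radius": 0.65,
            "length_unit": "cm",
            "tube_angle": 28,
            "angle_unit": "degrees",
        },
        "window": {"rho_min": window[0], "rho_max": window[1], "label": "heavy"},
        "fragments": {
            "family": "normal",
            "location": 9000,
            "scale": 2500,
            "min_bp": 500,
            "max_bp": 20000,
            "coverage": coverage,
        },
        "p_dbl": 0.001,
        "reads": {
            "read_length": read_length,
            "insert_mean": 1000,
            "insert_sd": 5,
            "total_pairs": total_pairs,
            "format": "fasta",
        },
        "threads": 1,
    }
    if mode == "fractions":
        config.pop("window")
        config["fractions"] = {"rho_min": 1.675, "rho_max": 1.771}
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
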