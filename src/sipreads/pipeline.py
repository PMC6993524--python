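"""Simulation orchestration: fragments -> abundances -> reads -> files.

Runs one configured simulation end to end for every sample in the
community table (and every fraction in fraction-based mode), writing
paired read libraries and a JSON manifest of inputs, seeds, per-file
checksums and read counts.

Randomness is fully derived from the master seed: every (sample,
window, fragment) combination gets its own `numpy` seed sequence, so
output is bit-identical across runs and across worker counts -- workers
only change who executes a fragment's stream, never the stream itself.
Fragments are generated once per reference and re-used across samples
and fractions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path

import numpy as np

from .abundance import assign_bd, fragment_window_abundance, read_abundance
from .community import IncorporatorTable, load_community_table, sample_atom_excess
from .config import SimulationConfig, config_to_dict
from .errormodel import ErrorProfile
from .exceptions import InputError, SipReadsError
from .fragments import Reference, fragment_reference
from .gradient import BDWindow
from .reads import allocate_reads, generate_fragment_pairs, write_library

logger = logging.getLogger(__name__)

__all__ = ["run_simulation", "discover_references"]

_FASTA_SUFFIXES = (".fasta", ".fa", ".fna")

# spawn-key tags keeping the per-purpose RNG streams disjoint
_TAG_FRAGMENT, _TAG_LABEL, _TAG_ALLOC, _TAG_PAIRS, _TAG_ERROR = 11, 12, 13, 14, 15


def discover_references(reference_dir: Path) -> list[Reference]:
    """Load every FASTA file in a directory as one reference each."""
    paths = sorted(
        p for p in Path(reference_dir).iterdir() if p.suffix.lower() in _FASTA_SUFFIXES
    )
    if not paths:
        raise InputError(f"no FASTA files found in {reference_dir}")
    return [Reference.from_fasta(p) for p in paths]


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulation(cfg: SimulationConfig) -> dict:
    """Execute one simulation run; returns (and writes) the manifest."""
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    try:
        references = discover_references(cfg.reference_dir)
        communities = load_community_table(cfg.community_table)
        incorporators = (
            IncorporatorTable.from_tsv(cfg.incorporator_table)
            if cfg.incorporator_table is not None
            else IncorporatorTable()
        )
    except SipReadsError as exc:
        raise type(exc)(f"[stage=inputs] {exc}") from exc

    ref_by_id = {ref.id: ref for ref in references}
    for sample_id, profile in communities.items():
        missing = set(profile.reference_ids) - set(ref_by_id)
        if missing:
            raise InputError(
                f"[stage=inputs] sample {sample_id} references absent from "
                f"{cfg.reference_dir}: {sorted(missing)}"
            )

    # Fragment each reference once; fragments are shared by all samples
    # and windows.
    fragments = []
    frag_ref: list[str] = []
    fragment_counts = {}
    for ref_idx, ref in enumerate(references):
        frs = fragment_reference(
            ref, cfg.size_model, cfg.coverage, _rng(cfg.seed, _TAG_FRAGMENT, ref_idx)
        )
        fragment_counts[ref.id] = len(frs)
        fragments.extend(frs)
        frag_ref.extend([ref.id] * len(frs))
    lengths = np.array([f.length for f in fragments])
    sequenceable = lengths >= cfg.read_length
    n_short = int((~sequenceable).sum())
    if n_short:
        logger.warning(
            "%d fragments shorter than the read length are excluded from read allocation",
            n_short,
        )

    if cfg.mode == "window":
        windows: list[BDWindow | None] = [cfg.window]
    elif cfg.mode == "fractions":
        windows = list(cfg.fractions)
    else:
        windows = [None]

    ref_index = {ref.id: i for i, ref in enumerate(references)}
    libraries = []
    for s_idx, sample_id in enumerate(sorted(communities)):
        profile = communities[sample_id]
        alphas = np.array([profile.abundances.get(r, 0.0) for r in frag_ref])

        if cfg.mode != "shotgun":
            for ref in references:
                idx = [i for i, r in enumerate(frag_ref) if r == ref.id]
                entry = incorporators.get(sample_id, ref.id)
                isotope = entry.isotope if entry is not None else "13C"
                excess = sample_atom_excess(
                    incorporators,
                    sample_id,
                    ref.id,
                    _rng(cfg.seed, _TAG_LABEL, s_idx, ref_index[ref.id]),
                    size=len(idx),
                )
                for i, a in zip(idx, excess):
                    assign_bd(fragments[i], float(a), isotope, cfg.gradient)

        for w_idx, window in enumerate(windows):
            label = "bulk" if window is None else (window.label or f"W{w_idx + 1}")
            try:
                lib = _simulate_library(
                    cfg,
                    fragments,
                    alphas,
                    sequenceable,
                    ref_by_id,
                    window,
                    label,
                    s_idx,
                    w_idx,
                    sample_id,
                )
            except SipReadsError as exc:
                raise type(exc)(
                    f"[stage=reads sample={sample_id} window={label}] {exc}"
                ) from exc
            libraries.append(lib)

    manifest = {
        "config": config_to_dict(cfg),
        "fragment_counts": fragment_counts,
        "fragments_below_read_length": n_short,
        "libraries": libraries,
    }
    manifest_path = cfg.output_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote manifest %s", manifest_path)
    return manifest


def _simulate_library(
    cfg: SimulationConfig,
    fragments,
    alphas: np.ndarray,
    sequenceable: np.ndarray,
    ref_by_id: dict[str, Reference],
    window: BDWindow | None,
    label: str,
    s_idx: int,
    w_idx: int,
    sample_id: str,
) -> dict:
    """Allocate, generate, and serialize one paired library."""
    weights = np.zeros(len(fragments))
    for i, frag in enumerate(fragments):
        if not sequenceable[i] or alphas[i] == 0.0:
            continue
        if window is None:
            alpha_f = alphas[i]
        else:
            alpha_f = fragment_window_abundance(
                frag, alphas[i], window, cfg.gradient, cfg.p_dbl
            ).alpha_f
        weights[i] = read_abundance(alpha_f, frag.length, cfg.read_length)

    counts = allocate_reads(
        weights, cfg.total_pairs, _rng(cfg.seed, _TAG_ALLOC, s_idx, w_idx), label
    )

    offsets = np.concatenate([[0], np.cumsum(counts)])
    active = [i for i in range(len(fragments)) if counts[i] > 0]

    def _task(i: int):
        frag = fragments[i]
        seq = ref_by_id[frag.reference_id].scaffolds[frag.scaffold_id]
        ids = [f"pair{j}" for j in range(offsets[i], offsets[i] + counts[i])]
        return generate_fragment_pairs(
            frag,
            seq,
            int(counts[i]),
            cfg.read_length,
            cfg.insert_mean,
            cfg.insert_sd,
            _rng(cfg.seed, _TAG_PAIRS, s_idx, w_idx, i),
            pair_ids=ids,
            window_label=label,
        )

    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            chunks = list(pool.map(_task, active))
    else:
        chunks = [_task(i) for i in active]
    pairs = [p for chunk in chunks for p in chunk]

    ext = "fasta" if cfg.output_format == "fasta" else "fastq"
    r1 = cfg.output_dir / f"{sample_id}_{label}_R1.{ext}"
    r2 = cfg.output_dir / f"{sample_id}_{label}_R2.{ext}"
    error_profile = (
        ErrorProfile.for_platform(cfg.error_platform, cfg.read_length)
        if cfg.output_format == "fastq"
        else None
    )
    n1, n2 = write_library(
        pairs,
        r1,
        r2,
        fmt=cfg.output_format,
        error_profile=error_profile,
        rng=_rng(cfg.seed, _TAG_ERROR, s_idx, w_idx),
    )
    return {
        "sample_id": sample_id,
        "window": label,
        "rho_min": None if window is None else window.rho_min,
        "rho_max": None if window is None else window.rho_max,
        "n_pairs": int(n1),
        "r1": r1.name,
        "r2": r2.name,
        "sha256_r1": _sha256(r1),
        "sha256_r2": _sha256(r2),
    }
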