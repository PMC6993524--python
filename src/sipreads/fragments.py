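"""DNA-extraction fragmentation.

References are sheared in silico into 'fragments' whose lengths follow a
user-chosen distribution, emulating the fragmentation produced by DNA
extraction (e.g. bead beating).  Fragmentation is repeated in tiling
passes until the summed fragment bases reach a user-specified fold
coverage of the reference, giving a diverse sample of fragments whose
G+C (and hence buoyant density) varies around the genome average.

Coordinates are 0-based, half-open throughout; serialization converts to
1-based inclusive for human-readable headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .exceptions import ConfigurationError, DomainError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSizeModel",
    "Fragment",
    "Reference",
    "gc_content",
    "fragment_reference",
    "fragments_to_table",
]

#: resample attempts for rejection-sampled truncation before clamping
_TRUNCATION_CAP = 1000


@dataclass(frozen=True)
class FragmentSizeModel:
    """Distribution of sheared-fragment lengths in bp.

    Families:

    ``uniform``
        Uniform on ``[location, scale]`` (location = low bound,
        scale = high bound; equal bounds give a fixed length).
    ``normal``
        Normal(location, scale), clamped to ``[min_bp, max_bp]``.
    ``truncated-normal``
        Normal(location, scale) rejection-sampled into
        ``[min_bp, max_bp]`` (clamped after a resample cap).
    ``skew-normal``
        Skew-normal with shape ``skew``, location ``location`` and scale
        ``scale``, truncated like ``truncated-normal``.
    """

    family: str = "normal"
    location: float = 9000.0
    scale: float = 2500.0
    skew: float = 0.0
    min_bp: int = 1
    max_bp: int = 10_000_000

    def __post_init__(self) -> None:
        if self.family not in {"uniform", "normal", "truncated-normal", "skew-normal"}:
            raise ConfigurationError(f"unknown size-model family {self.family!r}")
        if self.family == "uniform":
            if self.location > self.scale:
                raise ConfigurationError(
                    "uniform size model requires location (low) <= scale (high), "
                    f"got ({self.location}, {self.scale})"
                )
        elif self.scale <= 0:
            raise ConfigurationError(f"size-model scale must be positive, got {self.scale}")
        if not 1 <= self.min_bp <= self.max_bp:
            raise ConfigurationError(
                f"require 1 <= min_bp <= max_bp, got ({self.min_bp}, {self.max_bp})"
            )

    @property
    def mean(self) -> float:
        """Mean fragment length implied by the model (before truncation)."""
        if self.family == "uniform":
            return 0.5 * (self.location + self.scale)
        if self.family == "skew-normal":
            return float(stats.skewnorm.mean(self.skew, loc=self.location, scale=self.scale))
        return self.location

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` integer fragment lengths."""
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        if self.family == "uniform":
            draws = rng.uniform(self.location, np.nextafter(self.scale, np.inf), size=n)
        elif self.family == "normal":
            draws = rng.normal(self.location, self.scale, size=n)
        else:
            draws = self._sample_truncated(n, rng)
        lengths = np.rint(draws).astype(np.int64)
        return np.clip(lengths, self.min_bp, self.max_bp)

    def _sample_truncated(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "skew-normal":
            dist = stats.skewnorm(self.skew, loc=self.location, scale=self.scale)
        else:
            dist = stats.norm(loc=self.location, scale=self.scale)
        out = np.empty(n)
        pending = np.arange(n)
        for _ in range(_TRUNCATION_CAP):
            draws = dist.rvs(size=pending.size, random_state=rng)
            out[pending] = draws
            pending = pending[(draws < self.min_bp) | (draws > self.max_bp)]
            if pending.size == 0:
                break
        else:  # pragma: no cover - requires pathological truncation bounds
            pass
        if pending.size:
            logger.warning(
                "clamping %d fragment-length draws that failed truncation after %d resamples",
                pending.size,
                _TRUNCATION_CAP,
            )
        return out


@dataclass
class Fragment:
    """One simulated extraction fragment.

    ``start``/``end`` are 0-based half-open coordinates on the parent
    scaffold; ``gc`` is computed over ``[start, end)`` with ambiguous
    bases excluded from the denominator.  The buoyant-density fields
    (``atom_excess``, ``rho_t``, ``rho``, ``sigma``) are filled in by the
    abundance model once an isotope-labeling draw is made.
    """

    reference_id: str
    scaffold_id: str
    start: int
    end: int
    gc: float
    atom_excess: float | None = None
    rho_t: float | None = None
    rho: float | None = None
    sigma: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, scaffold_seq: str) -> str:
        return scaffold_seq[self.start : self.end]


@dataclass
class Reference:
    """A reference organism: one FASTA file, possibly multiple scaffolds."""

    id: str
    scaffolds: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    @classmethod
    def from_fasta(cls, path: str | Path, reference_id: str | None = None) -> "Reference":
        path = Path(path)
        scaffolds = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not scaffolds:
            raise InputError(f"no sequences found in FASTA file {path}")
        return cls(id=reference_id or path.stem, scaffolds=scaffolds)


def gc_content(window: str) -> float:
    """G+C fraction of a sequence window.

    Ambiguous bases (anything outside ACGT, case-insensitive) are
    excluded from the denominator.  An empty or all-ambiguous window has
    no defined G+C and raises :class:`DomainError`.
    """
    if not window:
        raise DomainError("cannot compute G+C of an empty window")
    gc = sum(window.count(b) for b in "GCgc")
    unambiguous = gc + sum(window.count(b) for b in "ATat")
    if unambiguous == 0:
        raise DomainError("cannot compute G+C of an all-ambiguous window")
    return gc / unambiguous


def _ambiguous_fraction(window: str) -> float:
    unambiguous = sum(window.count(b) for b in "ACGTacgt")
    return 1.0 - unambiguous / len(window)


def fragment_reference(
    reference: Reference,
    size_model: FragmentSizeModel,
    coverage: float,
    rng: np.random.Generator | int,
) -> list[Fragment]:
    """Shear a reference into fragments to a target fold coverage.

    Each pass tiles every scaffold left-to-right from a random phase
    offset in ``[0, mean length)``; the sub-offset leading piece is
    emitted as its own fragment (or merged into the first tile when
    shorter than ``min_bp``) and a trailing remainder shorter than
    ``min_bp`` is merged into the final tile, so every pass covers each
    scaffold exactly once.  Passes repeat, stopping at fragment
    granularity, once summed fragment bases reach
    ``coverage * total reference length``.

    Scaffolds shorter than ``min_bp`` fall back to a single
    whole-scaffold fragment per pass (with a logged warning); fragments
    that are more than 50% ambiguous bases are dropped.
    """
    if coverage <= 0:
        raise ConfigurationError(f"fragment coverage must be positive, got {coverage}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    total_target = coverage * reference.total_length
    if reference.total_length == 0:
        raise InputError(f"reference {reference.id} has no sequence")

    fragments: list[Fragment] = []
    total = 0
    mean_len = max(1, int(round(size_model.mean)))
    while total < total_target:
        for scaffold_id, seq in reference.scaffolds.items():
            L = len(seq)
            if L < size_model.min_bp:
                logger.warning(
                    "scaffold %s/%s (%d bp) shorter than min_bp=%d; "
                    "emitting whole-scaffold fragment",
                    reference.id,
                    scaffold_id,
                    L,
                    size_model.min_bp,
                )
                coords = [(0, L)]
            else:
                coords = _tile_scaffold(L, size_model, mean_len, rng)
            for start, end in coords:
                window = seq[start:end]
                if _ambiguous_fraction(window) > 0.5:
                    logger.warning(
                        "dropping fragment %s/%s:%d-%d (>50%% ambiguous bases)",
                        reference.id,
                        scaffold_id,
                        start,
                        end,
                    )
                    continue
                fragments.append(
                    Fragment(
                        reference_id=reference.id,
                        scaffold_id=scaffold_id,
                        start=start,
                        end=end,
                        gc=gc_content(window),
                    )
                )
                total += end - start
                if total >= total_target:
                    break
            if total >= total_target:
                break
    return fragments


def _tile_scaffold(
    L: int, size_model: FragmentSizeModel, mean_len: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """One full tiling pass over a scaffold of length ``L``."""
    offset = int(rng.integers(0, min(mean_len, L)))
    coords: list[tuple[int, int]] = []
    pos = offset
    while pos < L:
        ln = int(size_model.sample(1, rng)[0])
        end = min(pos + ln, L)
        if L - end < size_model.min_bp:
            end = L  # merge trailing remainder into the final tile
        coords.append((pos, end))
        pos = end
    if offset > 0:
        if offset >= size_model.min_bp:
            coords.insert(0, (0, offset))
        elif coords:
            coords[0] = (0, coords[0][1])
        else:  # pragma: no cover - offset capped at L
            coords = [(0, L)]
    return coords


def fragments_to_table(fragments: list[Fragment]) -> pd.DataFrame:
    """Tabulate fragments (one row each) for TSV diagnostics output."""
    return pd.DataFrame(
        {
            "reference_id": [f.reference_id for f in fragments],
            "scaffold_id": [f.scaffold_id for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "length": [f.length for f in fragments],
            "gc": [f.gc for f in fragments],
        }
    )
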