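"""Biological inputs of a SIP experiment.

Per-sample community composition (relative abundance of each reference),
isotope-incorporator assignments (which references are labeled, and how
strongly), and the buoyant-density fraction sets collected from a
gradient.

Tables are plain TSVs with headers.  The community table is long format
(``sample_id``, ``reference_id``, ``abundance``); the incorporator table
has one row per labeled (sample, reference) with the isotope and the
mean/SD of atom % excess in percent.  References absent from the
incorporator table are unlabeled (atom % excess identically zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .gradient import BDWindow, DELTA_BD

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityProfile",
    "IncorporatorTable",
    "FractionSet",
    "FractionSizeModel",
    "load_community_table",
    "write_community_table",
    "sample_atom_excess",
    "generate_community",
    "generate_fractions",
]

_SUM_TOL = 1e-6
_RENORM_TOL = 1e-3


@dataclass
class CommunityProfile:
    """Relative abundances of the references in one sample."""

    sample_id: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances.values()):
            raise InputError(f"negative abundance in sample {self.sample_id}")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > _SUM_TOL:
            if abs(total - 1.0) <= _RENORM_TOL:
                logger.info(
                    "renormalizing sample %s abundances (sum was %.6f)",
                    self.sample_id,
                    total,
                )
                self.abundances = {k: v / total for k, v in self.abundances.items()}
            else:
                raise InputError(
                    f"sample {self.sample_id} abundances sum to {total:.6f}, "
                    "more than 1e-3 away from 1"
                )

    def __getitem__(self, reference_id: str) -> float:
        return self.abundances[reference_id]

    @property
    def reference_ids(self) -> list[str]:
        return list(self.abundances)


def load_community_table(path: str | Path) -> dict[str, CommunityProfile]:
    """Load a long-format community TSV into per-sample profiles."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "reference_id", "abundance"}
    if not required.issubset(df.columns):
        raise InputError(
            f"community table {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    profiles = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        profiles[str(sample_id)] = CommunityProfile(
            sample_id=str(sample_id),
            abundances=dict(zip(grp["reference_id"].astype(str), grp["abundance"])),
        )
    if not profiles:
        raise InputError(f"community table {path} is empty")
    return profiles


def write_community_table(profiles: dict[str, CommunityProfile], path: str | Path) -> None:
    """Serialize profiles back to the canonical long-format TSV.

    Column order is canonicalized so that load -> write is idempotent.
    """
    rows = [
        {"sample_id": p.sample_id, "reference_id": ref, "abundance": a}
        for p in profiles.values()
        for ref, a in p.abundances.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "reference_id", "abundance"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class _IncorporatorEntry:
    isotope: str
    mean_percent: float
    sd_percent: float


@dataclass
class IncorporatorTable:
    """Which references incorporate label, per sample.

    Keyed by (sample_id, reference_id); missing keys mean unlabeled.
    Mean and SD are atom % excess in percent (0-100).
    """

    entries: dict[tuple[str, str], _IncorporatorEntry] = field(default_factory=dict)

    def add(
        self,
        sample_id: str,
        reference_id: str,
        isotope: str,
        mean_percent: float,
        sd_percent: float,
    ) -> None:
        if isotope not in DELTA_BD:
            raise ConfigurationError(
                f"unknown isotope {isotope!r}; expected one of {sorted(DELTA_BD)}"
            )
        if not 0 <= mean_percent <= 100:
            raise ConfigurationError(
                f"mean atom % excess must lie in [0, 100], got {mean_percent}"
            )
        if sd_percent < 0:
            raise ConfigurationError(f"sd atom % excess must be >= 0, got {sd_percent}")
        self.entries[(sample_id, reference_id)] = _IncorporatorEntry(
            isotope, mean_percent, sd_percent
        )

    def get(self, sample_id: str, reference_id: str) -> _IncorporatorEntry | None:
        return self.entries.get((sample_id, reference_id))

    def is_incorporator(self, sample_id: str, reference_id: str) -> bool:
        return (sample_id, reference_id) in self.entries

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IncorporatorTable":
        df = pd.read_csv(path, sep="\t")
        required = {"sample_id", "reference_id", "isotope", "mean_percent", "sd_percent"}
        if not required.issubset(df.columns):
            raise InputError(
                f"incorporator table {path} must have columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        table = cls()
        for row in df.itertuples(index=False):
            table.add(
                str(row.sample_id),
                str(row.reference_id),
                str(row.isotope),
                float(row.mean_percent),
                float(row.sd_percent),
            )
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "sample_id": s,
                "reference_id": r,
                "isotope": e.isotope,
                "mean_percent": e.mean_percent,
                "sd_percent": e.sd_percent,
            }
            for (s, r), e in self.entries.items()
        ]
        pd.DataFrame(
            rows,
            columns=["sample_id", "reference_id", "isotope", "mean_percent", "sd_percent"],
        ).to_csv(path, sep="\t", index=False)


def sample_atom_excess(
    table: IncorporatorTable,
    sample_id: str,
    reference_id: str,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw atom % excess for fragments of a reference in a sample.

    Each labeled fragment gets an independent draw from
    Normal(mean, sd) in percent, clamped to [0, 100] and returned as a
    fraction in [0, 1].  Fragments of unlabeled references get exactly 0.
    Clamping (rather than rejection) avoids biasing the mean near the
    boundaries.
    """
    entry = table.get(sample_id, reference_id)
    n = 1 if size is None else size
    if entry is None:
        out = np.zeros(n)
    else:
        draws = rng.normal(entry.mean_percent, entry.sd_percent, size=n)
        out = np.clip(draws, 0.0, 100.0) / 100.0
    return float(out[0]) if size is None else out


def generate_community(
    n_refs: int,
    mean_abund: float = 0.02,
    sd: float = 0.8,
    permute_frac: float = 0.10,
    rng_seed: np.random.Generator | int = 0,
    sample_id: str = "sample_1",
    reference_ids: list[str] | None = None,
) -> CommunityProfile:
    """Generate a lognormal rank-abundance community.

    Abundances are drawn from a lognormal distribution (median
    ``mean_abund``, log-scale SD ``sd``), ranked in decreasing order,
    normalized to sum to 1, and then ``ceil(permute_frac * n)`` rank
    positions are swapped pairwise to roughen the curve the way replicate
    communities differ in practice.
    """
    if n_refs < 1:
        raise ConfigurationError(f"n_refs must be >= 1, got {n_refs}")
    if sd <= 0:
        raise ConfigurationError(f"lognormal sd must be positive, got {sd}")
    if mean_abund <= 0:
        raise ConfigurationError(f"mean abundance must be positive, got {mean_abund}")
    if not 0 <= permute_frac <= 1:
        raise ConfigurationError(f"permute_frac must lie in [0, 1], got {permute_frac}")
    rng = (
        np.random.default_rng(rng_seed)
        if isinstance(rng_seed, (int, np.integer))
        else rng_seed
    )
    if reference_ids is None:
        width = max(3, len(str(n_refs)))
        reference_ids = [f"ref_{i + 1:0{width}d}" for i in range(n_refs)]
    if len(reference_ids) != n_refs:
        raise ConfigurationError("reference_ids length must equal n_refs")

    draws = rng.lognormal(mean=math.log(mean_abund), sigma=sd, size=n_refs)
    ranked = np.sort(draws)[::-1]
    ranked = ranked / ranked.sum()

    n_permute = math.ceil(permute_frac * n_refs)
    if n_permute >= 2:
        idx = rng.choice(n_refs, size=n_permute, replace=False)
        for a, b in zip(idx[0::2], idx[1::2]):
            ranked[a], ranked[b] = ranked[b], ranked[a]

    return CommunityProfile(
        sample_id=sample_id, abundances=dict(zip(reference_ids, ranked))
    )


@dataclass(frozen=True)
class FractionSizeModel:
    """Normal model of collected fraction widths (g/ml), truncated below.

    Defaults mimic typical empirical fraction tables: mean 0.004 g/ml,
    SD 0.0003 g/ml, never narrower than 0.002 g/ml.
    """

    mean: float = 0.004
    sd: float = 0.0003
    min_size: float = 0.002

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.min_size <= 0:
            raise ConfigurationError(
                "fraction size model admits non-positive sizes "
                f"(mean={self.mean}, min_size={self.min_size})"
            )
        if self.sd < 0:
            raise ConfigurationError(f"fraction size sd must be >= 0, got {self.sd}")

    def sample(self, rng: np.random.Generator) -> float:
        return max(self.min_size, float(rng.normal(self.mean, self.sd)))


@dataclass
class FractionSet:
    """An ordered, contiguous, ascending set of BD windows."""

    windows: list[BDWindow]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ConfigurationError("fraction set must contain at least one window")
        for prev, cur in zip(self.windows, self.windows[1:]):
            if not math.isclose(prev.rho_max, cur.rho_min, abs_tol=1e-12):
                raise ConfigurationError(
                    f"fractions must be contiguous: window ending at {prev.rho_max} "
                    f"followed by window starting at {cur.rho_min}"
                )

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def rho_min(self) -> float:
        return self.windows[0].rho_min

    @property
    def rho_max(self) -> float:
        return self.windows[-1].rho_max

    @classmethod
    def from_boundaries(cls, boundaries: list[float]) -> "FractionSet":
        if len(boundaries) < 2 or any(
            b >= c for b, c in zip(boundaries, boundaries[1:])
        ):
            raise ConfigurationError(
                "fraction boundaries must be a strictly increasing list of >= 2 values"
            )
        return cls(
            [
                BDWindow(lo, hi, label=f"F{i + 1}")
                for i, (lo, hi) in enumerate(zip(boundaries, boundaries[1:]))
            ]
        )


def generate_fractions(
    rho_min: float,
    rho_max: float,
    size_model: FractionSizeModel | None = None,
    rng_seed: np.random.Generator | int = 0,
) -> FractionSet:
    """Partition [rho_min, rho_max] into contiguous fractions with widths
    drawn from ``size_model``; the last fraction is truncated at
    ``rho_max``."""
    if rho_min >= rho_max:
        raise ConfigurationError(
            f"require rho_min < rho_max, got ({rho_min}, {rho_max})"
        )
    size_model = size_model or FractionSizeModel()
    rng = (
        np.random.default_rng(rng_seed)
        if isinstance(rng_seed, (int, np.integer))
        else rng_seed
    )
    boundaries = [rho_min]
    while boundaries[-1] < rho_max - 1e-12:
        boundaries.append(min(boundaries[-1] + size_model.sample(rng), rho_max))
    boundaries[-1] = rho_max  # snap away accumulated floating-point drift
    return FractionSet.from_boundaries(boundaries)
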