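"""Sequencing-error simulation: error-free FASTA reads to FASTQ.

Errors are substitution-only -- no indels are ever introduced, so read
lengths (and hence pairing and coordinates) are preserved exactly.  The
per-cycle substitution probability follows a parametric curve (flat,
linear ramp, or logistic tail degradation) chosen to approximate
Illumina platform behavior; quality scores are drawn per cycle from a
normal model and encoded Phred+33 in [2, 41].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError
from .reads import _open_text, iter_fasta_records

__all__ = ["ErrorProfile", "fastq_convert"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_INDEX[_b] = _i

PHRED_MIN, PHRED_MAX = 2, 41


@dataclass(frozen=True)
class ErrorProfile:
    """Per-cycle substitution probabilities and quality-score model.

    ``subst_prob``, ``qual_mean`` have one entry per sequencing cycle and
    must match the read length of the library they are applied to.
    """

    subst_prob: np.ndarray
    qual_mean: np.ndarray
    qual_sd: float = 2.0
    platform: str = "flat"

    def __post_init__(self) -> None:
        p = np.asarray(self.subst_prob, dtype=float)
        q = np.asarray(self.qual_mean, dtype=float)
        object.__setattr__(self, "subst_prob", p)
        object.__setattr__(self, "qual_mean", q)
        if p.ndim != 1 or q.shape != p.shape:
            raise ConfigurationError(
                "subst_prob and qual_mean must be 1-D arrays of equal length"
            )
        if np.any((p < 0) | (p > 1)):
            raise ConfigurationError("substitution probabilities must lie in [0, 1]")
        if self.qual_sd < 0:
            raise ConfigurationError(f"qual_sd must be >= 0, got {self.qual_sd}")

    @property
    def read_length(self) -> int:
        return self.subst_prob.size

    @classmethod
    def flat(
        cls,
        read_length: int,
        error_rate: float = 0.001,
        qual_mean: float = 37.0,
        qual_sd: float = 2.0,
    ) -> "ErrorProfile":
        """Constant error rate across all cycles."""
        return cls(
            subst_prob=np.full(read_length, error_rate),
            qual_mean=np.full(read_length, qual_mean),
            qual_sd=qual_sd,
            platform="flat",
        )

    @classmethod
    def linear_ramp(
        cls,
        read_length: int,
        start_rate: float = 0.001,
        end_rate: float = 0.01,
        qual_start: float = 37.0,
        qual_end: float = 28.0,
        qual_sd: float = 3.0,
        platform: str = "linear",
    ) -> "ErrorProfile":
        """Error rate rising linearly from the first to the last cycle."""
        return cls(
            subst_prob=np.linspace(start_rate, end_rate, read_length),
            qual_mean=np.linspace(qual_start, qual_end, read_length),
            qual_sd=qual_sd,
            platform=platform,
        )

    @classmethod
    def logistic_tail(
        cls,
        read_length: int,
        base_rate: float = 0.0005,
        tail_rate: float = 0.004,
        midpoint_frac: float = 0.8,
        steepness: float = 15.0,
        qual_base: float = 37.0,
        qual_tail: float = 32.0,
        qual_sd: float = 2.0,
        platform: str = "logistic",
    ) -> "ErrorProfile":
        """Low flat error rate with a logistic rise near the read tail."""
        t = np.linspace(0.0, 1.0, read_length)
        s = 1.0 / (1.0 + np.exp(-steepness * (t - midpoint_frac)))
        return cls(
            subst_prob=base_rate + (tail_rate - base_rate) * s,
            qual_mean=qual_base + (qual_tail - qual_base) * s,
            qual_sd=qual_sd,
            platform=platform,
        )

    @classmethod
    def for_platform(cls, platform: str, read_length: int) -> "ErrorProfile":
        """Preset parametric curves approximating Illumina platforms."""
        presets = {
            "novaseq-like": lambda: cls.logistic_tail(
                read_length,
                base_rate=0.0005,
                tail_rate=0.004,
                qual_base=37.0,
                qual_tail=32.0,
                platform="novaseq-like",
            ),
            "hiseq-like": lambda: cls.logistic_tail(
                read_length,
                base_rate=0.001,
                tail_rate=0.008,
                midpoint_frac=0.7,
                qual_base=36.0,
                qual_tail=30.0,
                platform="hiseq-like",
            ),
            "miseq-like": lambda: cls.linear_ramp(
                read_length,
                start_rate=0.001,
                end_rate=0.012,
                qual_start=37.0,
                qual_end=27.0,
                platform="miseq-like",
            ),
            "flat": lambda: cls.flat(read_length),
        }
        if platform not in presets:
            raise ConfigurationError(
                f"unknown platform {platform!r}; expected one of {sorted(presets)}"
            )
        return presets[platform]()

    def apply(self, seq: str, rng: np.random.Generator) -> tuple[str, str]:
        """Mutate a read and draw its quality string.

        Each base is independently substituted with its cycle's
        probability to a uniformly chosen *different* base; ambiguous
        bases (N) are left untouched.  The output length always equals
        the input length (substitutions only, no gaps).
        """
        n = len(seq)
        if n != self.read_length:
            raise ConfigurationError(
                f"read length {n} does not match error-profile length {self.read_length}"
            )
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        idx = _BASE_INDEX[arr]
        mutable = idx >= 0
        hits = (rng.random(n) < self.subst_prob) & mutable
        if hits.any():
            shift = rng.integers(1, 4, size=int(hits.sum()))
            arr[hits] = _BASES[(idx[hits] + shift) % 4]
        quals = np.rint(rng.normal(self.qual_mean, self.qual_sd)).astype(int)
        quals = np.clip(quals, PHRED_MIN, PHRED_MAX)
        qual_str = (quals + 33).astype(np.uint8).tobytes().decode("ascii")
        return arr.tobytes().decode("ascii"), qual_str


def fastq_convert(
    fasta_in: str | Path,
    fastq_out: str | Path,
    profile: ErrorProfile,
    rng: np.random.Generator | int,
) -> int:
    """Convert an error-free FASTA read file to FASTQ with simulated
    errors and qualities.

    Records are processed in order, one FASTQ record per FASTA record,
    so R1/R2 files converted separately remain pairable.  Returns the
    record count.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = 0
    with _open_text(Path(fastq_out), "w") as out:
        for header, seq in iter_fasta_records(fasta_in):
            mutated, qual = profile.apply(seq, rng)
            out.write(f"@{header}\n{mutated}\n+\n{qual}\n")
            n += 1
    return n
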