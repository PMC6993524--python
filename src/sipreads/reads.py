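"""Paired-end read generation and library serialization.

Read pairs are allocated to fragments by a multinomial draw weighted by
per-fragment read abundance, then each pair is placed on its fragment by
drawing an insert (template) length from a normal model and a uniform
template start.  A fair coin decides which physical end of the template
is written as mate 1; mate 1 is always written in reference orientation
and mate 2 as the reverse complement of its source window, so a library
can be checked byte-for-byte against the references from the header
coordinates alone.

Header grammar (stable):
``pair{n}|{reference}|{scaffold}:{start}-{end}|{window}/{mate}``
with 1-based inclusive coordinates of the mate's own window.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DomainError, EmptyLibraryError, InputError
from .fragments import Fragment

__all__ = [
    "ReadPair",
    "reverse_complement",
    "allocate_reads",
    "generate_pair",
    "generate_fragment_pairs",
    "write_library",
    "iter_fasta_records",
    "parse_read_header",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_HEADER_RE = re.compile(
    r"^(?P<pair_id>[^|]+)\|(?P<reference>[^|]+)\|(?P<scaffold>[^|:]+):"
    r"(?P<start>\d+)-(?P<end>\d+)\|(?P<window>[^/]+)/(?P<mate>[12])$"
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read with provenance coordinates.

    Coordinates are 0-based half-open on the source scaffold.  The
    forward mate's sequence is the reference window as-is; the reverse
    mate's sequence is the reverse complement of its window.
    ``insert_size`` is the total template span in bp.
    """

    pair_id: str
    reference_id: str
    scaffold_id: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    insert_size: int
    read_length: int
    fwd_seq: str
    rev_seq: str
    window_label: str = "bulk"

    def headers(self) -> tuple[str, str]:
        """R1/R2 FASTA identifiers (1-based inclusive coordinates)."""
        h1 = (
            f"{self.pair_id}|{self.reference_id}|{self.scaffold_id}:"
            f"{self.fwd_start + 1}-{self.fwd_end}|{self.window_label}/1"
        )
        h2 = (
            f"{self.pair_id}|{self.reference_id}|{self.scaffold_id}:"
            f"{self.rev_start + 1}-{self.rev_end}|{self.window_label}/2"
        )
        return h1, h2


def allocate_reads(
    read_abundances: np.ndarray,
    total_pairs: int,
    rng: np.random.Generator,
    window_label: str = "",
) -> np.ndarray:
    """Multinomially allocate ``total_pairs`` pairs over fragments.

    Probabilities are the normalized per-fragment read abundances; the
    returned counts sum to ``total_pairs`` exactly.
    """
    if total_pairs < 0:
        raise DomainError(f"total_pairs must be >= 0, got {total_pairs}")
    weights = np.asarray(read_abundances, dtype=float)
    if weights.size == 0 or np.any(weights < 0):
        raise EmptyLibraryError(
            f"invalid read-abundance weights for window {window_label!r}"
        )
    total = weights.sum()
    if total <= 0:
        raise EmptyLibraryError(
            f"no fragment has positive read abundance in window {window_label!r}"
        )
    if total_pairs == 0:
        return np.zeros(weights.size, dtype=np.int64)
    return rng.multinomial(total_pairs, weights / total).astype(np.int64)


def generate_pair(
    fragment: Fragment,
    scaffold_seq: str,
    read_length: int,
    insert_mean: float,
    insert_sd: float,
    rng: np.random.Generator,
    pair_id: str = "pair0",
    window_label: str = "bulk",
) -> ReadPair:
    """Generate a single read pair from a fragment."""
    return generate_fragment_pairs(
        fragment,
        scaffold_seq,
        1,
        read_length,
        insert_mean,
        insert_sd,
        rng,
        pair_ids=[pair_id],
        window_label=window_label,
    )[0]


def generate_fragment_pairs(
    fragment: Fragment,
    scaffold_seq: str,
    n_pairs: int,
    read_length: int,
    insert_mean: float,
    insert_sd: float,
    rng: np.random.Generator,
    pair_ids: list[str] | None = None,
    window_label: str = "bulk",
) -> list[ReadPair]:
    """Generate ``n_pairs`` read pairs from one fragment.

    Inserts are drawn from Normal(insert_mean, insert_sd), rounded and
    clamped into ``[read_length, fragment length]``; template starts are
    uniform over the admissible range; a fair coin decides which template
    end becomes mate 1.
    """
    if fragment.length < read_length:
        raise DomainError(
            f"fragment {fragment.reference_id}:{fragment.start}-{fragment.end} "
            f"({fragment.length} bp) is shorter than the read length {read_length}"
        )
    if n_pairs == 0:
        return []
    inserts = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64)
    inserts = np.clip(inserts, read_length, fragment.length)
    tpl_starts = fragment.start + rng.integers(0, fragment.length - inserts + 1)
    flips = rng.random(n_pairs) < 0.5
    if pair_ids is None:
        pair_ids = [f"pair{i}" for i in range(n_pairs)]

    pairs: list[ReadPair] = []
    for pid, ins, tpl_start, flip in zip(pair_ids, inserts, tpl_starts, flips):
        ins = int(ins)
        left = (int(tpl_start), int(tpl_start) + read_length)
        right = (int(tpl_start) + ins - read_length, int(tpl_start) + ins)
        fwd, rev = (right, left) if flip else (left, right)
        pairs.append(
            ReadPair(
                pair_id=pid,
                reference_id=fragment.reference_id,
                scaffold_id=fragment.scaffold_id,
                fwd_start=fwd[0],
                fwd_end=fwd[1],
                rev_start=rev[0],
                rev_end=rev[1],
                insert_size=ins,
                read_length=read_length,
                fwd_seq=scaffold_seq[fwd[0] : fwd[1]],
                rev_seq=reverse_complement(scaffold_seq[rev[0] : rev[1]]),
                window_label=window_label,
            )
        )
    return pairs


def _open_text(path: Path, mode: str):
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_library(
    pairs,
    r1_path: str | Path,
    r2_path: str | Path,
    fmt: str = "fasta",
    error_profile=None,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Serialize read pairs to paired R1/R2 files, in identical order.

    ``fmt='fasta'`` writes error-free multi-FASTA.  ``fmt='fastq'``
    writes FASTQ; with an ``error_profile`` (see
    :mod:`sipreads.errormodel`) substitution errors and quality scores
    are simulated, otherwise reads are written unchanged at maximum
    quality.  Returns the (R1, R2) record counts, which are always equal.

    ``.gz`` suffixes transparently gzip the output.
    """
    if fmt not in {"fasta", "fastq"}:
        raise InputError(f"unknown library format {fmt!r}")
    if fmt == "fastq" and error_profile is not None and rng is None:
        raise InputError("fastq output with an error profile requires an rng")
    r1_path, r2_path = Path(r1_path), Path(r2_path)
    n = 0
    try:
        with _open_text(r1_path, "w") as r1, _open_text(r2_path, "w") as r2:
            for pair in pairs:
                h1, h2 = pair.headers()
                if fmt == "fasta":
                    r1.write(f">{h1}\n{pair.fwd_seq}\n")
                    r2.write(f">{h2}\n{pair.rev_seq}\n")
                else:
                    for handle, header, seq in ((r1, h1, pair.fwd_seq), (r2, h2, pair.rev_seq)):
                        if error_profile is not None:
                            seq, qual = error_profile.apply(seq, rng)
                        else:
                            qual = "I" * len(seq)
                        handle.write(f"@{header}\n{seq}\n+\n{qual}\n")
                n += 1
    except OSError as exc:
        raise InputError(f"failed writing library to {r1_path}/{r2_path}: {exc}") from exc
    return n, n


def iter_fasta_records(path: str | Path):
    """Yield (header, sequence) from a (possibly gzipped) multi-FASTA."""
    path = Path(path)
    with _open_text(path, "r") as handle:
        header, chunks = None, []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
        if header is not None:
            yield header, "".join(chunks)


def parse_read_header(header: str) -> dict:
    """Parse the stable header grammar back into provenance fields.

    Returns 0-based half-open coordinates.
    """
    m = _HEADER_RE.match(header)
    if m is None:
        raise InputError(f"cannot parse read header {header!r}")
    d = m.groupdict()
    return {
        "pair_id": d["pair_id"],
        "reference_id": d["reference"],
        "scaffold_id": d["scaffold"],
        "start": int(d["start"]) - 1,
        "end": int(d["end"]),
        "window_label": d["window"],
        "mate": int(d["mate"]),
    }
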