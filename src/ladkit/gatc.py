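"""DpnI (GATC) restriction-fragment maps from genome sequence.

DamID quantifies Dam methylation per GATC fragment: the interval between
consecutive DpnI cut sites. This module scans genome sequences for the GATC
motif and builds, per chromosome, the ordered set of half-open fragments that
tile the sequence exactly. These fragments are the bins every downstream
DamID score and LAD call is expressed in.

Conventions
-----------
* Coordinates are 0-based, half-open internally; BED on disk.
* DpnI cuts GA^TC (blunt), so the cut coordinate is ``motif_start + 2``. The
  choice of offset shifts every bin edge by at most 2 bp and is irrelevant to
  any downstream statistic, but it is fixed and documented here.
* Matching is case-insensitive (soft-masked genomes); ``N`` never matches and
  no IUPAC expansion is performed — DpnI recognises the literal motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GatcFragmentMap",
    "scan_gatc_sites",
    "build_fragment_map",
    "read_fasta",
    "write_fragment_bed",
    "read_fragment_bed",
]

_VALID_BASES = frozenset("ACGTNacgtn")

# DpnI cleaves between A and T of GATC (GA^TC), leaving blunt ends.
CUT_OFFSET = 2
MOTIF = "GATC"


class InvalidSequenceError(ValueError):
    """Raised when a sequence is empty or contains a non-DNA character."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome sequence over the alphabet {A,C,G,T,N}."""

    chrom: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GatcFragmentMap:
    """Per-chromosome DpnI fragments tiling ``[0, chrom_length)``.

    ``fragments`` is an ``(n, 2)`` int array of half-open intervals whose
    boundaries are ``{0} ∪ cut_sites ∪ {chrom_length}``; ``cut_sites`` is
    strictly increasing.
    """

    chrom: str
    chrom_length: int
    cut_sites: np.ndarray = field(repr=False)
    fragments: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cut_sites, dtype=np.int64)
        frags = np.asarray(self.fragments, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "cut_sites", cuts)
        object.__setattr__(self, "fragments", frags)
        if cuts.size and not np.all(np.diff(cuts) > 0):
            raise ValueError("cut sites must be strictly increasing")
        bounds = np.concatenate([[0], cuts, [self.chrom_length]])
        if not (np.array_equal(frags[:, 0], bounds[:-1]) and np.array_equal(frags[:, 1], bounds[1:])):
            raise ValueError("fragments must tile [0, chrom_length) at the cut sites")

    @property
    def n_fragments(self) -> int:
        return self.fragments.shape[0]

    @property
    def boundaries(self) -> np.ndarray:
        """Fragment boundary positions, length ``n_fragments + 1``."""
        return np.concatenate([self.fragments[:, 0], [self.chrom_length]])

    def fragment_lengths(self) -> np.ndarray:
        return self.fragments[:, 1] - self.fragments[:, 0]

    def fragment_index(self, pos: int | np.ndarray) -> np.ndarray:
        """Index of the fragment containing genomic position ``pos``."""
        pos = np.asarray(pos)
        if np.any((pos < 0) | (pos >= self.chrom_length)):
            raise ValueError("position outside chromosome bounds")
        return np.searchsorted(self.boundaries, pos, side="right") - 1


def _validate_seq(seq: str) -> None:
    if not seq:
        raise InvalidSequenceError("empty sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise InvalidSequenceError(
            f"illegal character {seq[pos]!r} at position {pos}; expected A/C/G/T/N"
        )


def scan_gatc_sites(seq: str) -> list[int]:
    """Return all 0-based start positions of GATC in ``seq``, sorted.

    Case-insensitive; ``N`` never matches. Overlap is impossible for GATC
    (no self-overlap shorter than 4), but the scan advances by one base so
    any motif would be found completely.
    """
    _validate_seq(seq)
    upper = seq.upper()
    out: list[int] = []
    start = 0
    while True:
        i = upper.find(MOTIF, start)
        if i < 0:
            break
        out.append(i)
        start = i + 1
    return out


def build_fragment_map(genome: GenomeSequence) -> GatcFragmentMap:
    """In-silico DpnI digest: fragments between consecutive GA^TC cuts.

    A motif-free chromosome yields exactly one fragment spanning the whole
    sequence. Terminal sub-fragments (before the first and after the last
    cut) are retained as bins.
    """
    sites = scan_gatc_sites(genome.seq)
    cuts = np.asarray(sites, dtype=np.int64) + CUT_OFFSET
    bounds = np.concatenate([[0], cuts, [genome.length]])
    frags = np.column_stack([bounds[:-1], bounds[1:]])
    return GatcFragmentMap(
        chrom=genome.chrom,
        chrom_length=genome.length,
        cut_sites=cuts,
        fragments=frags,
    )


def read_fasta(path: str) -> list[GenomeSequence]:
    """Load a (multi-record) FASTA into GenomeSequence records."""
    genomes = [GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    names = [g.chrom for g in genomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in FASTA")
    return genomes


def write_fragment_bed(maps: Iterable[GatcFragmentMap], path: str) -> None:
    """Write fragment intervals as BED3, one map after another."""
    with open(path, "w") as fh:
        for m in maps:
            for s, e in m.fragments:
                fh.write(f"{m.chrom}\t{s}\t{e}\n")


def _iter_bed3(path: str) -> Iterator[tuple[str, int, int]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            yield parts[0], int(parts[1]), int(parts[2])


def read_fragment_bed(path: str) -> dict[str, GatcFragmentMap]:
    """Reconstruct per-chromosome fragment maps from a BED3 fragment file."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in _iter_bed3(path):
        per_chrom.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        frags = np.asarray(ivals, dtype=np.int64)
        cuts = frags[1:, 0]
        out[chrom] = GatcFragmentMap(
            chrom=chrom,
            chrom_length=int(frags[-1, 1]),
            cut_sites=cuts,
            fragments=frags,
        )
    return out
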