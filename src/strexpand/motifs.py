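"""Canonical STR repeat units and decoy chromosome construction.

A short tandem repeat (STR) motif is identified up to circular permutation
and reverse complement: CAG, AGC, GCA, CTG, TGC and GCT all describe the
same repeat tract read from either strand at any phase.  Each equivalence
class is represented by its lexicographically smallest member (``AGC`` for
the class above), and motifs that are powers of a shorter motif (``ATAT``)
are excluded because the shorter primitive root (``AT``) already represents
them.  Enumerating all primitive canonical units of length 1-6 bp yields 501
units; one artificial "decoy chromosome" of pure tandem repeat is built per
unit and appended to the reference genome so that reads consisting mostly of
repeat align there instead of scattering across the genome.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from pyfaidx import Fasta

__all__ = [
    "InvalidMotifError",
    "DecoyChromosome",
    "DECOY_PREFIX",
    "MAX_UNIT_LENGTH",
    "revcomp",
    "is_primitive",
    "canonical_unit",
    "enumerate_canonical_units",
    "build_decoy_set",
    "decoy_name",
    "unit_from_decoy_name",
    "augment_reference",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Longest repeat unit considered an STR motif.
MAX_UNIT_LENGTH = 6

#: Contig-name prefix identifying decoy chromosomes ("STR-AGC", ...).
DECOY_PREFIX = "STR-"


class InvalidMotifError(ValueError):
    """Raised for motifs that are empty, too long, or not over {A,C,G,T}."""


def _validated(unit: str) -> str:
    if not isinstance(unit, str) or not unit:
        raise InvalidMotifError(f"empty or non-string motif: {unit!r}")
    u = unit.upper()
    if len(u) > MAX_UNIT_LENGTH:
        raise InvalidMotifError(
            f"motif {u!r} longer than {MAX_UNIT_LENGTH} bp is not an STR unit"
        )
    if any(b not in "ACGT" for b in u):
        raise InvalidMotifError(f"motif {unit!r} contains non-ACGT characters")
    return u


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _primitive_root(unit: str) -> str:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit[:p] * (n // p) == unit:
            return unit[:p]
    return unit


def _rotations(unit: str) -> Iterable[str]:
    return (unit[i:] + unit[:i] for i in range(len(unit)))


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not k>=2 repetitions of a shorter string."""
    u = _validated(unit)
    return _primitive_root(u) == u


def canonical_unit(unit: str) -> str:
    """Canonical representative of ``unit``'s rotation/reverse-complement class.

    Periodic input is first reduced to its primitive root, so the function is
    total on valid motifs: ``canonical_unit("ATAT") == "AT"``.  Lowercase
    (soft-masked) bases are accepted and uppercased.
    """
    root = _primitive_root(_validated(unit))
    return min(itertools.chain(_rotations(root), _rotations(revcomp(root))))


def enumerate_canonical_units(max_len: int = MAX_UNIT_LENGTH) -> list[str]:
    """All primitive canonical units of length <= ``max_len``.

    Sorted by length then lexicographically; 501 units for ``max_len=6``.
    """
    if not 1 <= max_len <= MAX_UNIT_LENGTH:
        raise ValueError(f"max_len must be in 1..{MAX_UNIT_LENGTH}, got {max_len}")
    units: list[str] = []
    for k in range(1, max_len + 1):
        found = set()
        for bases in itertools.product("ACGT", repeat=k):
            s = "".join(bases)
            if _primitive_root(s) == s and canonical_unit(s) == s:
                found.add(s)
        units.extend(sorted(found))
    return units


@dataclass(frozen=True)
class DecoyChromosome:
    """An artificial chromosome of pure tandem repeat."""

    name: str
    unit: str
    sequence: str


def decoy_name(unit: str) -> str:
    return DECOY_PREFIX + unit


def unit_from_decoy_name(name: str) -> str:
    """Canonical unit encoded in a decoy contig name, or raise."""
    if not name.startswith(DECOY_PREFIX):
        raise InvalidMotifError(f"{name!r} is not a decoy contig name")
    return canonical_unit(name[len(DECOY_PREFIX):])


def build_decoy_set(
    units: Sequence[str], decoy_length: int = 2000
) -> list[DecoyChromosome]:
    """One decoy chromosome per canonical unit, each exactly ``decoy_length`` bp.

    The default 2000 bp comfortably exceeds typical short-read insert sizes,
    so a read pair can be wholly contained in repeat sequence.
    """
    if len(set(units)) != len(units):
        raise ValueError("duplicate units in decoy set")
    decoys = []
    for unit in units:
        u = _validated(unit)
        if decoy_length < len(u):
            raise ValueError(f"decoy_length {decoy_length} shorter than unit {u!r}")
        seq = (u * (decoy_length // len(u) + 1))[:decoy_length]
        decoys.append(DecoyChromosome(name=decoy_name(u), unit=u, sequence=seq))
    return decoys


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike,
                line_width: int = 70) -> str:
    """Write (name, sequence) records as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
    return os.fspath(path)


def augment_reference(
    reference_fasta: str | os.PathLike,
    decoys: Sequence[DecoyChromosome],
    out_fasta: str | os.PathLike,
    line_width: int = 70,
) -> str:
    """Append decoy chromosomes to a reference genome FASTA.

    Output holds the reference sequences (re-wrapped at ``line_width``)
    followed by the decoys.  Decoy names must not collide with reference
    contig names.  Re-running overwrites the output.
    """
    ref = Fasta(os.fspath(reference_fasta))
    existing = set(ref.keys())
    for d in decoys:
        if d.name in existing:
            raise ValueError(f"decoy name {d.name!r} collides with reference contig")

    def records():
        for name in ref.keys():
            yield name, str(ref[name][:])
        for d in decoys:
            yield d.name, d.sequence

    return write_fasta(records(), out_fasta, line_width=line_width)
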