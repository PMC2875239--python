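"""Reading and normalising genome sequences.

Input genomes come either as FASTA (multi-record: chromosomes, plasmids,
supercontigs) or as bare plain-text sequence files (one sequence, no line
numbers, no spaces).  All residues are normalised to uppercase ACGTN;
IUPAC ambiguity codes other than N are conservatively mapped to N, because
an ambiguous base can never be asserted to match a restriction site.

Each record carries a topology flag: bacterial replicons may be treated as
circular, in which case restriction sites may span the origin and the
digest tiles the sequence without terminal fragments.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from typing import Iterable, List, Literal

from Bio import SeqIO

logger = logging.getLogger(__name__)

Topology = Literal["linear", "circular"]

_VALID = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeSequence:
    """One input sequence: identifier, ACGTN residues, topology."""

    id: str
    residues: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}; "
                "normalise input through read_fasta/read_plain"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be 'linear' or 'circular', got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)


def _normalize(raw: str, label: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN characters to N; return (residues, n_mapped)."""
    seq = raw.upper()
    if "U" in seq:
        raise ValueError(f"sequence {label!r} contains U: RNA input is not supported")
    n_mapped = 0
    if not _VALID.issuperset(seq):
        cleaned = []
        for ch in seq:
            if ch in _VALID:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_mapped += 1
        seq = "".join(cleaned)
        logger.warning("sequence %s: %d non-ACGTN characters mapped to N", label, n_mapped)
    return seq, n_mapped


def read_fasta(path: str | os.PathLike, topology: Topology = "linear") -> List[GenomeSequence]:
    """Read all records of a FASTA file as :class:`GenomeSequence` items.

    Record order is preserved; residues are uppercased and non-ACGTN
    characters (including other IUPAC ambiguity codes) become N, with a
    logged warning count.  Records are digested independently downstream:
    fragments never span records.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        On an empty file or a record with an empty sequence.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such FASTA file: {path}")
    genomes: List[GenomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"FASTA record #{len(genomes) + 1} in {path} has an empty id")
        if len(rec.seq) == 0:
            raise ValueError(f"FASTA record {rec.id!r} in {path} has an empty sequence")
        residues, _ = _normalize(str(rec.seq), rec.id)
        genomes.append(GenomeSequence(id=rec.id, residues=residues, topology=topology))
    if not genomes:
        raise ValueError(f"no FASTA records found in {path}")
    return genomes


def read_plain(path: str | os.PathLike, id: str = "sequence", topology: Topology = "linear") -> GenomeSequence:
    """Read a bare plain-text sequence file (no header, no line numbers).

    Whitespace and newlines are stripped; normalisation is as in
    :func:`read_fasta`.  Files containing digits are rejected — numbered
    sequence dumps must be cleaned before use.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as fh:
        raw = fh.read()
    if re.search(r"\d", raw):
        raise ValueError(f"{path}: plain-text sequence input must not contain line numbers/digits")
    raw = re.sub(r"\s+", "", raw)
    residues, _ = _normalize(raw, id)
    return GenomeSequence(id=id, residues=residues, topology=topology)


def reverse_complement(residues: str) -> str:
    """Reverse complement of an ACGTN string (N maps to N)."""
    s = residues.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> int:
    """Write (id, sequence) pairs as FASTA; returns the number of records."""
    n = 0
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
            n += 1
    return n
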