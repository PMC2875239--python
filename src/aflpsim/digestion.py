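"""Restriction digestion: site scanning and the cut-to-cut fragment pool.

A double digest with a rare cutter (6 bp site, e.g. EcoRI or PstI) and a
frequent cutter (4 bp site, e.g. MseI) is simulated as a complete digest:
every exact occurrence of either recognition site is cut.  Fragments are the
intervals between consecutive cut positions, annotated with the enzyme that
produced each end.  Linear sequences additionally yield two terminal
fragments (flagged, since an uncut end cannot ligate an adaptor); circular
sequences with k >= 1 cuts yield exactly k fragments, one wrapping the
origin.

Coordinates are 0-based, half-open, forward strand.  A cut at position p
splits [.., p) | [p, ..); with this convention the fragment lengths always
sum to the sequence length.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List

from aflpsim.genome_io import GenomeSequence, reverse_complement

logger = logging.getLogger(__name__)

#: End label for fragments touching a linear sequence end (no cut site there).
TERMINAL = "TERMINAL"


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: non-degenerate recognition site and cut offset.

    The cut falls immediately before site position ``cut_offset`` on the
    forward strand, so EcoRI (G^AATTC) has site ``GAATTC`` and offset 1.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.site or set(self.site) - set("ACGT"):
            raise ValueError(f"enzyme {self.name}: site must be non-empty ACGT, got {self.site!r}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"enzyme {self.name}: cut_offset {self.cut_offset} outside 0..{len(self.site)}")

    @property
    def is_palindromic(self) -> bool:
        return self.site == reverse_complement(self.site)


#: Standard enzymes of EcoRI/MseI and PstI/MseI AFLP chemistry.
BUILTIN_ENZYMES: Dict[str, Enzyme] = {
    "EcoRI": Enzyme("EcoRI", "GAATTC", 1),
    "MseI": Enzyme("MseI", "TTAA", 1),
    "PstI": Enzyme("PstI", "CTGCAG", 5),
}


def get_enzyme(name: str) -> Enzyme:
    """Look up a built-in enzyme by name (case-sensitive)."""
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; built-ins: {sorted(BUILTIN_ENZYMES)}") from None


def load_enzyme_table(path: str | os.PathLike) -> Dict[str, Enzyme]:
    """Load extra enzymes from delimited text: columns name, site, cut_offset."""
    table: Dict[str, Enzyme] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) == 1:
                row = row[0].split()
            name, site, offset = row[0], row[1], int(row[2])
            table[name] = Enzyme(name, site.upper(), offset)
    return table


@dataclass(frozen=True)
class CutSite:
    """One cut: position of the first base after the cut, plus site context."""

    seq_id: str
    pos: int
    enzyme: str
    site_start: int


@dataclass(frozen=True)
class RestrictionFragment:
    """A cut-to-cut interval; the atom of homoplasy counting.

    For a circular wrap fragment ``end < start`` and the length is
    ``seq_length - start + end``.  ``left_enzyme``/``right_enzyme`` name the
    enzyme that cut each end, or :data:`TERMINAL` for a linear sequence end.
    ``ambiguous`` marks fragments with an end where both enzymes cut at the
    same position; these are excluded from amplification.
    """

    seq_id: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str
    length: int
    ambiguous: bool = False

    @property
    def key(self) -> tuple:
        return (self.seq_id, self.start, self.end)


def find_cut_sites(genome: GenomeSequence, enzyme: Enzyme) -> List[CutSite]:
    """All exact (possibly overlapping) occurrences of the recognition site.

    Windows containing N never match.  On circular sequences, sites spanning
    the origin are also found; their ``site_start`` is the forward-strand
    start index and ``pos`` is reported modulo the sequence length.
    """
    seq = genome.residues
    site = enzyme.site
    L = len(site)
    n = len(seq)
    out: List[CutSite] = []
    if n == 0 or L == 0 or L > n:
        return out
    # overlapping scan: advance by one from each hit
    i = seq.find(site)
    while i != -1:
        out.append(CutSite(genome.id, i + enzyme.cut_offset, enzyme.name, i))
        i = seq.find(site, i + 1)
    if genome.topology == "circular" and L > 1:
        # windows spanning the origin: start in [n-L+1, n)
        wrap = seq[n - (L - 1) :] + seq[: L - 1]
        j = wrap.find(site)
        while j != -1:
            start = n - (L - 1) + j
            out.append(CutSite(genome.id, (start + enzyme.cut_offset) % n, enzyme.name, start))
            j = wrap.find(site, j + 1)
        out.sort(key=lambda c: c.pos)
    return out


def double_digest(genome: GenomeSequence, rare: Enzyme, frequent: Enzyme) -> List[RestrictionFragment]:
    """Complete double digest: the pool of cut-to-cut restriction fragments.

    Cut positions of both enzymes are merged; fragments are the intervals
    between consecutive cuts.  Coinciding cut positions from the two enzymes
    are merged with a logged note; the adjacent fragments carry a combined
    end label ("EcoRI|MseI") and are flagged ambiguous.
    """
    if rare.name == frequent.name:
        raise ValueError("double digest needs two distinct enzymes")
    n = len(genome.residues)
    cuts: Dict[int, List[str]] = {}
    for enz in (rare, frequent):
        for cs in find_cut_sites(genome, enz):
            cuts.setdefault(cs.pos, []).append(enz.name)
    positions = sorted(cuts)
    for pos in positions:
        if len(set(cuts[pos])) > 1:
            logger.info(
                "%s: coinciding cut at %d from %s; adjacent fragments flagged ambiguous",
                genome.id, pos, "+".join(sorted(set(cuts[pos]))),
            )

    def end_label(pos: int) -> str:
        names = sorted(set(cuts[pos]))
        return "|".join(names)

    frags: List[RestrictionFragment] = []
    if genome.topology == "linear":
        if not positions:
            return [RestrictionFragment(genome.id, 0, n, TERMINAL, TERMINAL, n)]
        bounds = [0] + positions + [n]
        labels = [TERMINAL] + [end_label(p) for p in positions] + [TERMINAL]
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1]
            left, right = labels[i], labels[i + 1]
            amb = "|" in left or "|" in right
            frags.append(RestrictionFragment(genome.id, start, end, left, right, end - start, amb))
    else:
        if not positions:
            return []
        for i, start in enumerate(positions):
            end = positions[(i + 1) % len(positions)]
            # last fragment wraps the origin; with one cut it is the whole circle
            length = end - start if i < len(positions) - 1 else n - start + end
            left, right = end_label(start), end_label(end)
            amb = "|" in left or "|" in right
            frags.append(RestrictionFragment(genome.id, start, end, left, right, length, amb))
    return frags


def fragments_to_tsv(frags: Iterable[RestrictionFragment], path: str | os.PathLike) -> None:
    """Write fragments as TSV: seq_id, start, end, left_enzyme, right_enzyme, length."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tleft_enzyme\tright_enzyme\tlength\n")
        for f in frags:
            fh.write(f"{f.seq_id}\t{f.start}\t{f.end}\t{f.left_enzyme}\t{f.right_enzyme}\t{f.length}\n")


def fragments_to_bed(frags: Iterable[RestrictionFragment], path: str | os.PathLike) -> None:
    """Write fragments as BED (0-based half-open); wrap fragments are split."""
    with open(path, "w") as fh:
        for f in frags:
            name = f"{f.left_enzyme}--{f.right_enzyme}"
            if f.end >= f.start:
                fh.write(f"{f.seq_id}\t{f.start}\t{f.end}\t{name}\t{f.length}\n")
            else:  # circular wrap: emit the two arcs
                fh.write(f"{f.seq_id}\t{f.start}\t{f.start + f.length - f.end}\t{name};wrap5\t{f.length}\n")
                fh.write(f"{f.seq_id}\t0\t{f.end}\t{name};wrap3\t{f.length}\n")


def fragment_sequence(fragment: RestrictionFragment, genome: GenomeSequence) -> str:
    """Forward-strand core sequence of a fragment (handles circular wrap)."""
    seq = genome.residues
    if fragment.length == fragment.end - fragment.start:
        return seq[fragment.start : fragment.end]
    return seq[fragment.start :] + seq[: fragment.end]
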