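"""Selective amplification: which digest fragments a primer pair amplifies.

AFLP primers carry 0-4 selective bases at their 3' end.  A fragment is
amplified only if the genomic bases immediately inside each restriction-site
remnant equal the corresponding primer's selective bases exactly (idealised
PCR: no mismatch tolerance, N never matches).  Each added selective base
subsamples the fragment pool roughly four-fold.

Under the default fragment-class policy only rare-frequent fragments are
scored: in standard EcoRI/MseI AFLP the labelled primer sits on the
rare-cutter side, so rare-rare products are scarce and frequent-frequent
products are unlabelled.  Alternative policies exist for sensitivity
analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Literal, Mapping, Optional, Tuple

from aflpsim.digestion import TERMINAL, BUILTIN_ENZYMES, Enzyme, RestrictionFragment
from aflpsim.genome_io import GenomeSequence, reverse_complement

Policy = Literal["rare-freq", "rare-rare", "all"]


@dataclass(frozen=True)
class PrimerSpec:
    """One primer: its enzyme (by name) and its 3' selective bases (0-4)."""

    enzyme: str
    selective: str = ""

    def __post_init__(self) -> None:
        if len(self.selective) > 4:
            raise ValueError(f"selective bases limited to 4, got {self.selective!r}")
        if set(self.selective) - set("ACGT"):
            raise ValueError(f"selective bases must be ACGT, got {self.selective!r}")


@dataclass(frozen=True)
class Combination:
    """A rare+frequent primer pair, e.g. EcoRI+ATG/MseI+ATG."""

    rare: PrimerSpec
    frequent: PrimerSpec

    @property
    def n_sb(self) -> int:
        """Total number of selective bases over both primers."""
        return len(self.rare.selective) + len(self.frequent.selective)

    @property
    def label(self) -> str:
        return f"{self.rare.enzyme}+{self.rare.selective}/{self.frequent.enzyme}+{self.frequent.selective}"


_COMBO_RE = re.compile(r"^([A-Za-z0-9]+)\+([ACGTacgt]*)/([A-Za-z0-9]+)\+([ACGTacgt]*)$")


def parse_combination(text: str) -> Combination:
    """Parse "EcoRI+ATG/MseI+ATG" (rare side first) into a :class:`Combination`."""
    m = _COMBO_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse combination {text!r}; expected RARE+sel/FREQ+sel")
    return Combination(PrimerSpec(m.group(1), m.group(2).upper()), PrimerSpec(m.group(3), m.group(4).upper()))


@dataclass(frozen=True)
class AmplifiedFragment:
    """A fragment passing the selective-base filter.

    ``orientation`` records the end carrying the rare (labelled) primer;
    ``symmetric`` is used for rare-rare / frequent-frequent fragments under
    non-default policies, where the two ends are equivalent.

    ``core_length`` is the genomic span of the labelled amplicon strand.
    Restriction cuts are staggered, so the two strands of a mixed-end
    fragment differ in length: the electrophoresed (labelled) strand runs
    cut-to-cut on the top strand when the rare primer sits on the left, and
    cut-to-cut on the bottom strand when it sits on the right.  Measuring
    on the labelled strand keeps amplicon lengths independent of which
    genome strand was read (a fragment and its reverse-complement image
    land on the same peak).
    """

    fragment: RestrictionFragment
    orientation: Literal["rare_left", "rare_right", "symmetric"]
    core_length: int


def _stagger(enzyme: Enzyme) -> int:
    """Offset between bottom- and top-strand cuts of a palindromic site."""
    return len(enzyme.site) - 2 * enzyme.cut_offset


def amplicon_core_span(
    af: AmplifiedFragment, enzymes: Optional[Mapping[str, Enzyme]] = None
) -> Tuple[int, int]:
    """Genomic [start, end) of the labelled amplicon strand's core.

    Equals the fragment's cut-to-cut interval for ``rare_left`` and
    ``symmetric`` orientations; for ``rare_right`` the labelled strand is
    the bottom strand, whose cuts sit ``site length - 2 * cut offset``
    further 3' on each side.
    """
    frag = af.fragment
    if af.orientation != "rare_right":
        return frag.start, frag.end
    left_e = _resolve(frag.left_enzyme, enzymes)
    right_e = _resolve(frag.right_enzyme, enzymes)
    return frag.start + _stagger(left_e), frag.end + _stagger(right_e)


def amplicon_core_sequence(
    af: AmplifiedFragment,
    genome: GenomeSequence,
    enzymes: Optional[Mapping[str, Enzyme]] = None,
) -> str:
    """Sequence of the labelled amplicon strand's core, 5'->3'.

    Read forward from the genome for ``rare_left``/``symmetric``
    fragments and as the reverse complement of the (shifted) span for
    ``rare_right`` ones, so co-migrating members of one peak always have
    equal length.
    """
    start, end = amplicon_core_span(af, enzymes)
    if genome.topology == "circular":
        seq = _slice_wrap(genome.residues, start, start + af.core_length)
    else:
        seq = genome.residues[start:end]
    return reverse_complement(seq) if af.orientation == "rare_right" else seq


def _resolve(name: str, enzymes: Optional[Mapping[str, Enzyme]]) -> Enzyme:
    table = enzymes if enzymes is not None else BUILTIN_ENZYMES
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"enzyme {name!r} not in enzyme table") from None


def _slice_wrap(seq: str, start: int, end: int) -> str:
    """Slice [start, end) with circular wrap-around (indices may be out of range)."""
    n = len(seq)
    length = end - start
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    return seq[start:] + seq[: start + length - n]


def selective_end_bases(
    fragment: RestrictionFragment,
    genome: GenomeSequence,
    k_left: int,
    k_right: int,
    enzymes: Optional[Mapping[str, Enzyme]] = None,
) -> Tuple[str, str]:
    """Genomic context read by the two primers' selective bases.

    Left string: the ``k_left`` bases immediately 3' of the full left
    recognition site on the forward strand.  Right string: reverse
    complement of the ``k_right`` bases immediately 5' of the right
    recognition site — what the right-end primer reads on the bottom
    strand.  Windows wrap on circular genomes; on linear genomes a window
    running past a sequence end is an error.  N bases are returned as-is
    (they never match selective bases).
    """
    if TERMINAL in (fragment.left_enzyme, fragment.right_enzyme):
        raise ValueError("selective context undefined for terminal fragments")
    if fragment.ambiguous:
        raise ValueError("selective context undefined for ambiguous (coinciding-cut) fragments")
    left_e = _resolve(fragment.left_enzyme, enzymes)
    right_e = _resolve(fragment.right_enzyme, enzymes)
    seq = genome.residues
    n = len(seq)
    site_start_left = fragment.start - left_e.cut_offset
    site_start_right = fragment.end - right_e.cut_offset
    lo = site_start_left + len(left_e.site)
    hi = site_start_right
    if genome.topology == "linear":
        if lo + k_left > n or hi - k_right < 0:
            raise ValueError(
                f"unreadable selective context for fragment {fragment.seq_id}:{fragment.start}-{fragment.end}"
            )
        left = seq[lo : lo + k_left]
        right = reverse_complement(seq[hi - k_right : hi])
    else:
        left = _slice_wrap(seq, lo, lo + k_left)
        right = reverse_complement(_slice_wrap(seq, hi - k_right, hi))
    return left, right


def amplify(
    fragments: List[RestrictionFragment],
    genome: GenomeSequence,
    combo: Combination,
    policy: Policy = "rare-freq",
    enzymes: Optional[Mapping[str, Enzyme]] = None,
) -> List[AmplifiedFragment]:
    """Fragments of one genome record amplified by *combo* under *policy*.

    A fragment is amplified iff (a) its end-enzyme pair is allowed by the
    policy and (b) the primer assigned to each end (rare primer on rare-cut
    ends, frequent primer on frequent-cut ends) matches that end's selective
    context exactly.  Terminal and ambiguous fragments are never amplified;
    fragments whose selective context cannot be read are not amplified.
    """
    rare_name = combo.rare.enzyme
    freq_name = combo.frequent.enzyme
    known = {rare_name, freq_name}
    out: List[AmplifiedFragment] = []
    for frag in fragments:
        ends = (frag.left_enzyme, frag.right_enzyme)
        for label in ends:
            if label != TERMINAL and not set(label.split("|")) <= known:
                raise ValueError(
                    f"fragment end enzyme {label!r} does not belong to combination {combo.label}"
                )
        if TERMINAL in ends or frag.ambiguous:
            continue
        el, er = ends
        if el == rare_name and er == freq_name:
            klass, orientation = "rare-freq", "rare_left"
            sel_left, sel_right = combo.rare.selective, combo.frequent.selective
        elif el == freq_name and er == rare_name:
            klass, orientation = "rare-freq", "rare_right"
            sel_left, sel_right = combo.frequent.selective, combo.rare.selective
        elif el == er == rare_name:
            klass, orientation = "rare-rare", "symmetric"
            sel_left = sel_right = combo.rare.selective
        else:
            klass, orientation = "freq-freq", "symmetric"
            sel_left = sel_right = combo.frequent.selective
        if policy == "rare-freq" and klass != "rare-freq":
            continue
        if policy == "rare-rare" and klass == "freq-freq":
            continue
        try:
            left, right = selective_end_bases(frag, genome, len(sel_left), len(sel_right), enzymes)
        except ValueError:
            continue
        if left == sel_left and right == sel_right:
            core = frag.length
            if orientation == "rare_right":
                left_e = _resolve(el, enzymes)
                right_e = _resolve(er, enzymes)
                core += _stagger(right_e) - _stagger(left_e)
            out.append(AmplifiedFragment(frag, orientation, core))
    return out
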