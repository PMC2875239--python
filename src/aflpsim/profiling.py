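"""Virtual electropherograms and size-homoplasy statistics.

The final amplicon observed on a capillary trace is the cut-to-cut genomic
fragment plus the constant adaptor/primer tails ligated at each end.
Fragments are binned at exact integer peak length: distinct fragments
(different sequence or genomic position) that land on the same length
co-migrate, forming one homoplasious peak.  The profile-level homoplasy
rate H is the fraction of peaks containing two or more co-migrating
fragments.

Default adaptor extensions are 11 bp on the rare (EcoRI) side and 13 bp on
the frequent (MseI) side — the tails of the standard Vos et al. primers
beyond the restriction-site remnants — and are fully configurable for
other chemistries.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from aflpsim.amplification import AmplifiedFragment, Combination, amplicon_core_sequence
from aflpsim.genome_io import GenomeSequence, reverse_complement

#: Peak-length window scored in a standard AFLP profile (bp, inclusive).
DEFAULT_WINDOW: Tuple[int, int] = (50, 500)


@dataclass(frozen=True)
class AdaptorModel:
    """Constant length added to each fragment end by the ligated adaptors."""

    ext_rare: int = 11
    ext_freq: int = 13

    def __post_init__(self) -> None:
        if self.ext_rare < 0 or self.ext_freq < 0:
            raise ValueError("adaptor extensions must be >= 0")


@dataclass(frozen=True)
class Peak:
    """One scored length position and its co-migrating member fragments."""

    peak_length: int
    members: Tuple[AmplifiedFragment, ...]

    @property
    def n_comigrating(self) -> int:
        return len(self.members)

    @property
    def homoplasious(self) -> bool:
        return self.n_comigrating >= 2


@dataclass(frozen=True)
class Profile:
    """The virtual AFLP profile of one primer combination."""

    combo: Combination
    window: Tuple[int, int]
    peaks: Tuple[Peak, ...]

    @property
    def n_fragments(self) -> int:
        return sum(p.n_comigrating for p in self.peaks)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def H(self) -> Optional[float]:
        return homoplasy_rate(self)

    @property
    def max_comigrating(self) -> int:
        return max((p.n_comigrating for p in self.peaks), default=0)


def peak_length_of(af: AmplifiedFragment, combo: Combination, adaptor: AdaptorModel) -> int:
    """Amplicon length: core length plus the extension of each end's adaptor."""
    frag = af.fragment
    ext = 0
    for end in (frag.left_enzyme, frag.right_enzyme):
        ext += adaptor.ext_rare if end == combo.rare.enzyme else adaptor.ext_freq
    return af.core_length + ext


def build_profile(
    amplified: Iterable[AmplifiedFragment],
    combo: Combination,
    adaptor: AdaptorModel = AdaptorModel(),
    window: Tuple[int, int] = DEFAULT_WINDOW,
    window_on: str = "peak",
) -> Profile:
    """Group amplified fragments into peaks by exact integer peak length.

    The scoring window (inclusive) applies to the adaptor-extended peak
    length by default, or to the core fragment length with
    ``window_on="core"``.  Duplicate fragments (same seq_id/start/end) are
    counted once; peaks are sorted by length.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window min {lo} exceeds max {hi}")
    if window_on not in ("peak", "core"):
        raise ValueError("window_on must be 'peak' or 'core'")
    seen = set()
    by_length: Dict[int, List[AmplifiedFragment]] = {}
    for af in amplified:
        if af.fragment.key in seen:
            continue
        seen.add(af.fragment.key)
        gauge = af.core_length if window_on == "core" else peak_length_of(af, combo, adaptor)
        if not lo <= gauge <= hi:
            continue
        by_length.setdefault(peak_length_of(af, combo, adaptor), []).append(af)
    peaks = tuple(
        Peak(length, tuple(sorted(by_length[length], key=lambda a: a.fragment.key)))
        for length in sorted(by_length)
    )
    return Profile(combo=combo, window=window, peaks=peaks)


def homoplasy_rate(profile: Profile) -> Optional[float]:
    """H = (# peaks with >=2 co-migrating fragments) / (# peaks).

    Undefined (``None``) for an empty profile — never reported as 0.
    """
    if profile.n_peaks == 0:
        return None
    return sum(1 for p in profile.peaks if p.homoplasious) / profile.n_peaks


def h_percent(h: Optional[float], convention: str = "truncate") -> Optional[float]:
    """Render H as a percentage with one decimal.

    ``truncate`` drops digits past the first decimal (2/7 -> 28.5);
    ``round`` rounds half away from zero (2/7 -> 28.6).  Reports carry the
    raw fraction alongside so either convention can be checked.
    """
    if h is None:
        return None
    if convention == "truncate":
        return math.floor(h * 1000) / 10
    if convention == "round":
        return math.floor(h * 1000 + 0.5) / 10
    raise ValueError("convention must be 'truncate' or 'round'")


def comigration_spectrum(profile: Profile) -> Dict[int, int]:
    """Histogram: number of peaks per co-migration count."""
    spectrum: Dict[int, int] = {}
    for p in profile.peaks:
        spectrum[p.n_comigrating] = spectrum.get(p.n_comigrating, 0) + 1
    return spectrum


def _pair_identity(a: str, b: str) -> float:
    fwd = sum(x == y for x, y in zip(a, b)) / len(a)
    rb = reverse_complement(b)
    rev = sum(x == y for x, y in zip(a, rb)) / len(a)
    return max(fwd, rev)


def mean_pairwise_identity(
    peak: Peak, genomes: GenomeSequence | Dict[str, GenomeSequence]
) -> Tuple[float, Tuple[float, float]]:
    """Mean and range of pairwise per-position identity within one peak.

    Member core sequences share one length, so the comparison is ungapped
    and position-wise, taking the better of the forward and
    reverse-complement orientations for each pair.  Distinguishes
    repeat-driven co-migration (identity near 1) from chance co-migration.
    """
    if peak.n_comigrating < 2:
        raise ValueError("pairwise identity needs a peak with >= 2 members")
    lookup = {genomes.id: genomes} if isinstance(genomes, GenomeSequence) else genomes
    seqs = [amplicon_core_sequence(af, lookup[af.fragment.seq_id]) for af in peak.members]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError(
            "peak members differ in core length (mixed fragment classes); "
            "ungapped identity is undefined"
        )
    idents = [
        _pair_identity(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    return sum(idents) / len(idents), (min(idents), max(idents))


def profile_header(
    combo: Combination,
    adaptor: AdaptorModel,
    window: Tuple[int, int],
    policy: str,
    topology: str,
) -> List[str]:
    """Provenance header lines recorded in every profile export."""
    return [
        f"# combo={combo.label}",
        f"# policy={policy}",
        f"# adaptor_ext_rare={adaptor.ext_rare} adaptor_ext_freq={adaptor.ext_freq}",
        f"# window={window[0]}:{window[1]}",
        f"# topology={topology}",
    ]


def profile_to_tsv(
    profile: Profile,
    path: str | os.PathLike,
    adaptor: AdaptorModel = AdaptorModel(),
    policy: str = "rare-freq",
    topology: str = "linear",
) -> None:
    """Write a profile as TSV: peak_length, n_comigrating, homoplasious, members."""
    with open(path, "w") as fh:
        for line in profile_header(profile.combo, adaptor, profile.window, policy, topology):
            fh.write(line + "\n")
        fh.write("peak_length\tn_comigrating\thomoplasious\tmembers\n")
        for p in profile.peaks:
            coords = ",".join(
                f"{af.fragment.seq_id}:{af.fragment.start}-{af.fragment.end}/{af.orientation}"
                for af in p.members
            )
            fh.write(f"{p.peak_length}\t{p.n_comigrating}\t{int(p.homoplasious)}\t{coords}\n")


def amplified_to_fasta(
    profile: Profile,
    genomes: Dict[str, GenomeSequence],
    path: str | os.PathLike,
) -> int:
    """Export the core sequences of all peak members as FASTA; returns count."""
    from aflpsim.genome_io import write_fasta

    records = []
    for p in profile.peaks:
        for af in p.members:
            f = af.fragment
            records.append(
                (
                    f"{f.seq_id}:{f.start}-{f.end}/{af.orientation}",
                    amplicon_core_sequence(af, genomes[f.seq_id]),
                )
            )
    return write_fasta(records, path)
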