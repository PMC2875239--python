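"""Synthetic genomes with planted, fully known AFLP structure.

Real repeat-driven homoplasy comes from transposable elements and other
repetitive DNA: hundreds of near-identical copies of one element yield
hundreds of co-migrating fragments in a single peak.  The generator
emulates this with cassettes — a rare-cutter site, the rare primer's
selective bases, a neutral filler, the frequent primer's selective context
and a frequent-cutter site — inserted at random non-disruptive host
positions, so the expected amplified fragment, its core length and its
copy number are known exactly by construction.

The module also carries a naive position-by-position digest oracle that
shares no code with the digestion module, used to verify the production
scanner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from aflpsim.digestion import TERMINAL, BUILTIN_ENZYMES, Enzyme, RestrictionFragment
from aflpsim.amplification import Combination
from aflpsim.genome_io import GenomeSequence, reverse_complement

#: Study-range GC fraction used for fixture genomes by default.
DEFAULT_GC = 0.36


def random_genome(
    length: int,
    gc: float = DEFAULT_GC,
    seed: int = 0,
    id: str = "synthetic",
    topology: str = "linear",
) -> GenomeSequence:
    """I.i.d. random genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    return GenomeSequence(id=id, residues="".join(bases), topology=topology)  # type: ignore[arg-type]


@dataclass(frozen=True)
class CassetteSpec:
    """A plantable repeat cassette targeting one primer combination.

    The cassette reads: rare site, rare selective bases, filler, reverse
    complement of the frequent selective bases, frequent site.  Its internal
    rare->frequent fragment has exactly ``core_length`` bp and matches the
    combination's selective bases, so each planted copy contributes one
    amplified fragment to one known peak.  ``mutation_rate`` substitutes
    filler bases independently per copy (sites and selective contexts stay
    intact), producing co-migrating members with identity < 1.
    """

    combo: Combination
    core_length: int
    copies: int
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")


def _enzyme_pair(spec: CassetteSpec) -> Tuple[Enzyme, Enzyme]:
    return BUILTIN_ENZYMES[spec.combo.rare.enzyme], BUILTIN_ENZYMES[spec.combo.frequent.enzyme]


def _filler_length(spec: CassetteSpec) -> int:
    rare, freq = _enzyme_pair(spec)
    fixed = (
        (len(rare.site) - rare.cut_offset)
        + len(spec.combo.rare.selective)
        + len(spec.combo.frequent.selective)
        + freq.cut_offset
    )
    n = spec.core_length - fixed
    if n < 0:
        raise ValueError(f"core_length {spec.core_length} too short for cassette scaffold ({fixed} bp)")
    return n


def build_cassette(spec: CassetteSpec, seed: int = 0, gc: float = DEFAULT_GC) -> str:
    """One clean cassette copy: contains each enzyme site exactly once."""
    rare, freq = _enzyme_pair(spec)
    n_fill = _filler_length(spec)
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for _ in range(1000):
        filler = "".join(rng.choice(np.array(list("ACGT")), size=n_fill, p=p))
        cassette = (
            rare.site
            + spec.combo.rare.selective
            + filler
            + reverse_complement(spec.combo.frequent.selective)
            + freq.site
        )
        if _count_occurrences(cassette, rare.site) == 1 and _count_occurrences(
            cassette, freq.site
        ) == 1:
            return cassette
    raise RuntimeError("could not draw a cassette free of accidental restriction sites")


def _count_occurrences(seq: str, site: str) -> int:
    n, i = 0, seq.find(site)
    while i != -1:
        n += 1
        i = seq.find(site, i + 1)
    return n


def _allowed_insertion_points(seq: str, sites: List[str]) -> np.ndarray:
    """Offsets where an insertion does not split an existing site occurrence."""
    mask = np.ones(len(seq) + 1, dtype=bool)
    for site in sites:
        i = seq.find(site)
        while i != -1:
            mask[i + 1 : i + len(site)] = False
            i = seq.find(site, i + 1)
    return np.flatnonzero(mask)


def _mutate_filler(cassette: str, spec: CassetteSpec, rng: np.random.Generator) -> str:
    """Substitute filler bases at ``mutation_rate``; re-check site cleanliness."""
    rare, freq = _enzyme_pair(spec)
    lo = len(rare.site) + len(spec.combo.rare.selective)
    hi = len(cassette) - len(freq.site) - len(spec.combo.frequent.selective)
    for _ in range(100):
        chars = list(cassette)
        for i in range(lo, hi):
            if rng.random() < spec.mutation_rate:
                chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
        mutated = "".join(chars)
        if _count_occurrences(mutated, rare.site) == 1 and _count_occurrences(mutated, freq.site) == 1:
            return mutated
    raise RuntimeError("mutation kept re-creating restriction sites; lower mutation_rate")


def plant_cassette(
    genome: GenomeSequence, cassette: CassetteSpec, seed: int = 0
) -> Tuple[GenomeSequence, List[int]]:
    """Insert ``cassette.copies`` cassette copies at random host positions.

    Positions are drawn uniformly among host offsets that do not split an
    existing recognition site, so no background fragment is disturbed; the
    cassette itself is screened against accidental internal sites, and its
    fixed flanks cannot complete a site across a junction.  Returns the
    planted genome and the cassette start coordinates in it; the target
    combination's profile is guaranteed a peak with at least ``copies``
    co-migrating fragments.
    """
    rare, freq = _enzyme_pair(cassette)
    base = build_cassette(cassette, seed=seed)
    clen = len(base)
    host = genome.residues
    rng = np.random.default_rng(seed)
    allowed = _allowed_insertion_points(host, [rare.site, freq.site])
    if len(allowed) < cassette.copies:
        raise ValueError(
            f"genome of {len(host)} bp cannot host {cassette.copies} cassette copies"
        )
    positions = sorted(allowed[rng.choice(len(allowed), size=cassette.copies, replace=False)].tolist())
    pieces: List[str] = []
    planted_positions: List[int] = []
    prev = 0
    for k, pos in enumerate(positions):
        pieces.append(host[prev:pos])
        planted_positions.append(pos + k * clen)
        copy = base if cassette.mutation_rate == 0 else _mutate_filler(base, cassette, rng)
        pieces.append(copy)
        prev = pos
    pieces.append(host[prev:])
    planted = GenomeSequence(id=genome.id, residues="".join(pieces), topology=genome.topology)
    return planted, planted_positions


def write_truth_tsv(
    path, spec: CassetteSpec, positions: List[int], ext_total: int = 24
) -> None:
    """Truth table for a planted fixture: one row per cassette copy."""
    with open(path, "w") as fh:
        fh.write("cassette_start\tcombo\tcore_length\texpected_peak_length\tcopies\n")
        for pos in positions:
            fh.write(
                f"{pos}\t{spec.combo.label}\t{spec.core_length}\t"
                f"{spec.core_length + ext_total}\t{spec.copies}\n"
            )


def validation_replica(seed: int = 0) -> Tuple[GenomeSequence, Combination, dict]:
    """Synthetic replica of a sequencing-validated EcoRI+ATG/MseI+ATG profile.

    Builds a genome whose profile under the frozen default conventions
    (rare-frequent fragments, linear topology, 50-500 bp window on peak
    length, 11/13 bp adaptor extensions) contains exactly 13 peaks: two
    homoplasious peaks of 2 and 6 co-migrating fragments at 113 and 318 bp,
    singleton peaks at 115 and 410 bp, and nine further singletons.  The
    genome is synthetic; only the peak structure mirrors the validation
    profile.  Returns (genome, combination, {peak_length: expected CF}).
    """
    from aflpsim.amplification import parse_combination

    combo = parse_combination("EcoRI+ATG/MseI+ATG")
    # (core length, copies); peak length = core + 24
    plan = [(89, 2), (91, 1), (294, 6), (386, 1),
            (40, 1), (50, 1), (126, 1), (150, 1), (180, 1),
            (210, 1), (250, 1), (350, 1), (450, 1)]
    expected = {core + 24: copies for core, copies in plan}
    rare, freq = BUILTIN_ENZYMES["EcoRI"], BUILTIN_ENZYMES["MseI"]
    rng = np.random.default_rng(seed)
    p = [(1 - DEFAULT_GC) / 2, DEFAULT_GC / 2, DEFAULT_GC / 2, (1 - DEFAULT_GC) / 2]

    def spacer(length: int = 120) -> str:
        # no restriction site, and ends that cannot satisfy the selective bases
        # of the flanking inter-cassette fragment
        for _ in range(1000):
            s = "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))
            if (
                rare.site not in s
                and freq.site not in s
                and not s.startswith(combo.frequent.selective)
                and not s.endswith(reverse_complement(combo.rare.selective))
            ):
                return s
        raise RuntimeError("could not draw a clean spacer")

    pieces = [spacer()]
    for i, (core, copies) in enumerate(plan):
        cassette = build_cassette(CassetteSpec(combo, core, copies), seed=seed + 1000 + i)
        for _ in range(copies):
            pieces.append(cassette)
            pieces.append(spacer())
    genome = GenomeSequence(id="validation_replica", residues="".join(pieces))
    return genome, combo, expected


def naive_digest_oracle(
    genome: GenomeSequence, rare: Enzyme, frequent: Enzyme
) -> List[RestrictionFragment]:
    """Independent re-derivation of the double digest, for verification only.

    Scans every position with explicit character comparison (no shared code
    with the production scanner) and rebuilds fragments from first
    principles under the same output contract.
    """
    seq = genome.residues
    n = len(seq)
    cut_map: dict = {}
    for enz in (rare, frequent):
        L = len(enz.site)
        last = n - L if genome.topology == "linear" else n - 1
        for start in range(0, last + 1):
            ok = True
            for j in range(L):
                if seq[(start + j) % n] != enz.site[j]:
                    ok = False
                    break
            if ok:
                cut_map.setdefault((start + enz.cut_offset) % n, set()).add(enz.name)
    cuts = sorted(cut_map)

    def label(p: int) -> str:
        return "|".join(sorted(cut_map[p]))

    frags: List[RestrictionFragment] = []
    if genome.topology == "linear":
        if not cuts:
            return [RestrictionFragment(genome.id, 0, n, TERMINAL, TERMINAL, n)]
        edges = [0] + cuts + [n]
        names = [TERMINAL] + [label(p) for p in cuts] + [TERMINAL]
        for i in range(len(edges) - 1):
            amb = "|" in names[i] or "|" in names[i + 1]
            frags.append(
                RestrictionFragment(
                    genome.id, edges[i], edges[i + 1], names[i], names[i + 1],
                    edges[i + 1] - edges[i], amb,
                )
            )
    else:
        for i in range(len(cuts)):
            a = cuts[i]
            b = cuts[(i + 1) % len(cuts)]
            length = b - a if i + 1 < len(cuts) else n - a + b
            amb = "|" in label(a) or "|" in label(b)
            frags.append(RestrictionFragment(genome.id, a, b, label(a), label(b), length, amb))
    return frags
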