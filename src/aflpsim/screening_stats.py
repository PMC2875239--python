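"""Primer-combination screening and descriptive homoplasy statistics.

A screen runs one genome (all its records pooled) across a set of primer
combinations, producing one row per combination: number of amplified
fragments, number of peaks, homoplasy rate H and the maximum co-migration
count.  Rows aggregate into groups sharing the total number of selective
bases and the GC class of those bases, the summary used to choose
combinations for a study.  Pearson correlations relate profile size to
homoplasy and compare in-silico peak counts with empirical profiles from
related species for which no genome is available.
"""

from __future__ import annotations

import itertools
import os
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from scipy import stats

from aflpsim.amplification import Combination, Policy, PrimerSpec, amplify
from aflpsim.digestion import Enzyme, double_digest
from aflpsim.genome_io import GenomeSequence
from aflpsim.profiling import (
    DEFAULT_WINDOW,
    AdaptorModel,
    Profile,
    build_profile,
    h_percent,
)

_BASES = "ACGT"  # lexicographic base order used for enumeration

_PATTERN_RE = re.compile(r"^([A-Za-z0-9]+)\+(\d)/([A-Za-z0-9]+)\+(\d)$")

GCClass = str  # "AT" | "m" | "GC"

_CLASS_ORDER = {"AT": 0, "m": 1, "GC": 2}


def enumerate_combinations(
    expr: Union[str, Sequence[str]],
    rare: Enzyme,
    frequent: Enzyme,
) -> List[Combination]:
    """Expand count patterns like "E+1/M+2" into all selective-base choices.

    Each pattern "<RARE>+a/<FREQ>+b" (a, b integers 0-4) expands to the
    4^a * 4^b combinations of selective bases, in lexicographic order
    (A < C < G < T); explicit combinations such as "EcoRI+ATG/MseI+ATG" are
    accepted verbatim.  Duplicates across patterns are removed, keeping the
    first occurrence.
    """
    patterns = [expr] if isinstance(expr, str) else list(expr)
    out: List[Combination] = []
    seen = set()
    for pat in patterns:
        m = _PATTERN_RE.match(pat.strip())
        if m:
            a, b = int(m.group(2)), int(m.group(4))
            if a > 4 or b > 4:
                raise ValueError(f"selective-base count above 4 in pattern {pat!r}")
            expanded = (
                Combination(PrimerSpec(rare.name, "".join(sl)), PrimerSpec(frequent.name, "".join(sr)))
                for sl in itertools.product(_BASES, repeat=a)
                for sr in itertools.product(_BASES, repeat=b)
            )
        else:
            from aflpsim.amplification import parse_combination

            combo = parse_combination(pat)
            if {combo.rare.enzyme, combo.frequent.enzyme} != {rare.name, frequent.name}:
                raise ValueError(f"combination {pat!r} does not use enzymes {rare.name}/{frequent.name}")
            expanded = iter([combo])
        for combo in expanded:
            if combo.label not in seen:
                seen.add(combo.label)
                out.append(combo)
    return out


def gc_class(combo: Combination) -> GCClass:
    """GC-content class of a combination's selective bases.

    Strict majority of G/C over all selective bases of both primers -> "GC";
    strict majority of A/T -> "AT"; tie (or no selective bases) -> "m".
    """
    sel = combo.rare.selective + combo.frequent.selective
    n_gc = sum(1 for b in sel if b in "GC")
    n_at = len(sel) - n_gc
    if n_gc > n_at:
        return "GC"
    if n_at > n_gc:
        return "AT"
    return "m"


@dataclass(frozen=True)
class ScreenRow:
    """Per-combination screen result (one row of the report table)."""

    combo: Combination
    n_fragments: int
    n_peaks: int
    H: Optional[float]
    max_comigrating: int
    profile: Optional[Profile] = None

    @property
    def H_percent(self) -> Optional[float]:
        return h_percent(self.H)

    @property
    def n_sb(self) -> int:
        return self.combo.n_sb

    @property
    def gc_class(self) -> GCClass:
        return gc_class(self.combo)


def screen_combinations(
    genomes: Sequence[GenomeSequence],
    combos: Sequence[Combination],
    adaptor: AdaptorModel = AdaptorModel(),
    window: Tuple[int, int] = DEFAULT_WINDOW,
    policy: Policy = "rare-freq",
    window_on: str = "peak",
    enzymes: Optional[Dict[str, Enzyme]] = None,
    keep_profiles: bool = False,
) -> List[ScreenRow]:
    """Screen all genome records (pooled) across primer combinations.

    The double digest is computed once per enzyme pair and reused across
    combinations; amplified fragments are pooled over records (chromosomes
    and plasmids contribute to one profile) before peak construction.
    """
    if not genomes:
        raise ValueError("screen needs at least one genome record")
    from aflpsim.digestion import BUILTIN_ENZYMES

    table = dict(BUILTIN_ENZYMES)
    if enzymes:
        table.update(enzymes)
    digest_cache: Dict[Tuple[str, str, str], list] = {}
    rows: List[ScreenRow] = []
    for combo in combos:
        rare_e, freq_e = table[combo.rare.enzyme], table[combo.frequent.enzyme]
        pooled = []
        for g in genomes:
            key = (g.id, rare_e.name, freq_e.name)
            if key not in digest_cache:
                digest_cache[key] = double_digest(g, rare_e, freq_e)
            pooled.extend(amplify(digest_cache[key], g, combo, policy=policy, enzymes=table))
        profile = build_profile(pooled, combo, adaptor, window, window_on)
        rows.append(
            ScreenRow(
                combo=combo,
                n_fragments=profile.n_fragments,
                n_peaks=profile.n_peaks,
                H=profile.H,
                max_comigrating=profile.max_comigrating,
                profile=profile if keep_profiles else None,
            )
        )
    return rows


def rows_to_dataframe(rows: Iterable[ScreenRow]) -> pd.DataFrame:
    """Screen report as a DataFrame (columns mirror the per-combination table)."""
    return pd.DataFrame(
        {
            "combo": [r.combo.label for r in rows],
            "n_sb": [r.n_sb for r in rows],
            "gc_class": [r.gc_class for r in rows],
            "n_fragments": [r.n_fragments for r in rows],
            "n_peaks": [r.n_peaks for r in rows],
            "H": [r.H for r in rows],
            "H_percent": [r.H_percent for r in rows],
            "max_comigrating": [r.max_comigrating for r in rows],
        }
    )


@dataclass(frozen=True)
class GroupSummary:
    """Aggregate over combinations sharing (n_sb, gc_class)."""

    n_sb: int
    gc_class: GCClass
    n_tested: int
    mean_peaks: float
    range_peaks: Tuple[int, int]
    mean_H: Optional[float]
    range_H: Optional[Tuple[float, float]]
    max_comigrating: int


def summarize_by_group(report: Sequence[ScreenRow]) -> List[GroupSummary]:
    """Group screen rows by (n_sb, gc_class); mean/range of peaks and H%.

    Rows whose H is undefined (empty profiles) are excluded from the H
    statistics but counted in ``n_tested``.  Sorted by n_sb, then class
    order AT < m < GC.
    """
    if not report:
        raise ValueError("cannot summarize an empty report")
    groups: Dict[Tuple[int, GCClass], List[ScreenRow]] = {}
    for row in report:
        groups.setdefault((row.n_sb, row.gc_class), []).append(row)
    out: List[GroupSummary] = []
    for (n_sb, klass) in sorted(groups, key=lambda k: (k[0], _CLASS_ORDER[k[1]])):
        rows = groups[(n_sb, klass)]
        peaks = [r.n_peaks for r in rows]
        hs = [r.H_percent for r in rows if r.H_percent is not None]
        out.append(
            GroupSummary(
                n_sb=n_sb,
                gc_class=klass,
                n_tested=len(rows),
                mean_peaks=sum(peaks) / len(peaks),
                range_peaks=(min(peaks), max(peaks)),
                mean_H=sum(hs) / len(hs) if hs else None,
                range_H=(min(hs), max(hs)) if hs else None,
                max_comigrating=max(r.max_comigrating for r in rows),
            )
        )
    return out


def summary_to_dataframe(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_sb": [s.n_sb for s in summaries],
            "gc_class": [s.gc_class for s in summaries],
            "n_tested": [s.n_tested for s in summaries],
            "mean_peaks": [s.mean_peaks for s in summaries],
            "min_peaks": [s.range_peaks[0] for s in summaries],
            "max_peaks": [s.range_peaks[1] for s in summaries],
            "mean_H_percent": [s.mean_H for s in summaries],
            "min_H_percent": [s.range_H[0] if s.range_H else None for s in summaries],
            "max_H_percent": [s.range_H[1] if s.range_H else None for s in summaries],
            "max_comigrating": [s.max_comigrating for s in summaries],
        }
    )


def homoplasy_length_profile(
    profiles: Sequence[Profile], bin_width: int = 20
) -> Dict[int, float]:
    """Fraction of homoplasious peaks per length bin, pooled over profiles.

    Keys are bin start lengths (multiples of ``bin_width``); bins without
    any peak are absent from the mapping, not reported as zero.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    totals: Dict[int, int] = {}
    homo: Dict[int, int] = {}
    for profile in profiles:
        for p in profile.peaks:
            b = (p.peak_length // bin_width) * bin_width
            totals[b] = totals.get(b, 0) + 1
            if p.homoplasious:
                homo[b] = homo.get(b, 0) + 1
    return {b: homo.get(b, 0) / totals[b] for b in sorted(totals)}


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Product-moment correlation; ``None`` if either input has no variance."""
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 points")
    if len(set(x)) == 1 or len(set(y)) == 1:
        return None
    return float(stats.pearsonr(list(x), list(y)).statistic)


def read_empirical_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-combination empirical peak-count table from delimited text.

    Required columns: ``combo`` (label matching the screen, e.g.
    "EcoRI+ATG/MseI+ATG") and ``mean_peaks``; optional ``n_individuals``
    and per-bin count columns named ``bin_<start>`` (20 bp bins).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"combo", "mean_peaks"} - set(df.columns)
    if missing:
        raise ValueError(f"empirical table missing columns: {sorted(missing)}")
    return df


def compare_to_empirical(
    insilico: Sequence[ScreenRow],
    empirical: Union[pd.DataFrame, str, os.PathLike],
    bin_width: int = 20,
    profiles: Optional[Sequence[Profile]] = None,
) -> Dict[str, object]:
    """Compare in-silico peak counts with empirical profiles of a related species.

    Returns the per-combination table (in-silico vs empirical counts), their
    Pearson correlation, and — when per-bin empirical counts and profiles
    are supplied — the observed-vs-predicted peak counts per length bin with
    a flag for bins where the empirical count falls short of the prediction
    (the small-fragment and long-fragment deficits seen on capillary
    traces).
    """
    if not isinstance(empirical, pd.DataFrame):
        empirical = read_empirical_table(empirical)
    by_label = {r.combo.label: r for r in insilico}
    shared = [c for c in empirical["combo"] if c in by_label]
    if not shared:
        raise ValueError("no combinations shared between in-silico report and empirical table")
    emp = empirical.set_index("combo").loc[shared]
    per_combo = pd.DataFrame(
        {
            "combo": shared,
            "insilico_peaks": [by_label[c].n_peaks for c in shared],
            "empirical_peaks": emp["mean_peaks"].tolist(),
        }
    )
    r = None
    if len(shared) >= 3:
        r = pearson_r(per_combo["insilico_peaks"].tolist(), per_combo["empirical_peaks"].tolist())
    result: Dict[str, object] = {"n_shared": len(shared), "pearson_r": r, "per_combo": per_combo}

    bin_cols = [c for c in empirical.columns if c.startswith("bin_")]
    if bin_cols and profiles is not None:
        predicted: Dict[int, int] = {}
        for profile in profiles:
            for p in profile.peaks:
                b = (p.peak_length // bin_width) * bin_width
                predicted[b] = predicted.get(b, 0) + 1
        observed = {int(c[4:]): float(emp[c].sum()) for c in bin_cols}
        bins = sorted(set(predicted) | set(observed))
        bin_df = pd.DataFrame(
            {
                "bin_start": bins,
                "predicted": [predicted.get(b, 0) for b in bins],
                "observed": [observed.get(b, 0.0) for b in bins],
            }
        )
        bin_df["deficit"] = bin_df["observed"] < bin_df["predicted"]
        result["bins"] = bin_df
    return result
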