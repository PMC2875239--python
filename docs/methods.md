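# Methods

## Model

`aflpsim` simulates AFLP as an idealised, deterministic chemistry in three
stages.

**1. Complete double digest.** Every exact occurrence of each enzyme's
recognition site is found (overlapping occurrences included) and cut at
`site_start + cut_offset` on the forward strand. Fragments are the
intervals between consecutive cut positions, in 0-based half-open
coordinates, so fragment lengths tile the sequence exactly. Built-in
enzymes: EcoRI (G^AATTC), MseI (T^TAA), PstI (CTGCA^G); any explicit
ACGT site can be added through a config table. Linear sequences produce
two terminal fragments, flagged because an uncut end cannot ligate an
adaptor; circular replicons produce exactly one fragment per cut, one of
them wrapping the origin. If both enzymes cut at the same position the
adjacent fragments are flagged ambiguous and excluded from amplification.
Assumptions: complete digestion (no partial digests or star activity), no
methylation sensitivity.

**2. Selective amplification.** Each primer carries 0–4 selective bases
that must equal, with strict identity, the genomic bases immediately
inside the restriction-site remnant at its end (read on the strand the
primer anneals to, i.e. the right-end context is the reverse complement of
the bases 5′ of the right site). A base `N` never matches. Under the
default fragment-class policy only rare–frequent fragments are scored: the
labelled primer sits on the rare-cutter side, rare–rare products are
scarce and frequent–frequent products unlabelled. `rare-rare` and `all`
policies exist for sensitivity analysis.

**3. Peak profile.** The amplicon length is the fragment core plus a
constant adaptor extension per end (defaults 11 bp on the EcoRI side,
13 bp on the MseI side — the tails of the standard Vos-et-al primers
beyond the site remnants). Fragments are grouped at exact integer amplicon
length; distinct fragments (different sequence or position) sharing one
length form a homoplasious peak. Peaks are scored inside a 50–500 bp
window, applied to the adaptor-extended peak length by default
(`--window-on core` applies it to the core instead). The homoplasy rate is
H = (peaks with ≥2 members) / peaks, undefined (never 0) for an empty
profile.

### Strand-invariant amplicon lengths

Restriction cuts are staggered, so the two strands of a mixed-end fragment
differ in length: with single top-strand cut coordinates, an EcoRI–MseI
fragment and its reverse-complement image would differ by 2 bp and land on
different peaks. The electrophoresed molecule is the labelled strand,
which runs cut-to-cut on the strand the rare primer extends. `aflpsim`
therefore measures `core_length` on the labelled strand: for fragments
with the rare site on the right, both ends shift by `site length − 2 ×
cut offset`. This makes amplicon lengths and sequences exactly invariant
under reverse-complementing the input — a property the test suite asserts
— while raw fragment coordinates keep their plain cut-to-cut meaning.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| topology | linear | per-run flag; bacterial replicons may be circular. Recorded in every report header. |
| fragment-class policy | rare-freq | only rare–frequent fragments scored (labelled-primer argument above). |
| adaptor extensions | 11 / 13 bp | standard EcoRI/MseI primer tails; maps a 89 bp core to a 113 bp peak. Configurable per chemistry (PstI kits differ). |
| scoring window | 50–500 bp on peak length | the range a capillary profile is scored over. |
| selective bases | 0–4 per primer | each base subsamples the pool ~4-fold; totals of 1–3 suit bacterial genomes, 5–8 large animal genomes. |
| H percentage | truncate to 1 decimal | matches how such rates are conventionally printed (2/7 → 28.5); round-half-away available, raw fraction always reported. |

## Synthetic fixtures

`random_genome` draws i.i.d. bases at a given GC fraction (default 0.36,
the study range for AT-rich genomes). `plant_cassette` inserts identical
(optionally filler-mutated) copies of a cassette — rare site, rare
selective bases, filler, frequent selective context, frequent site — at
uniform host positions that do not split an existing site; the cassette is
screened against accidental internal sites and its fixed flanks cannot
complete a site across a junction. Each copy therefore contributes exactly
one amplified fragment of known core length, so planted-truth assertions
(a peak with ≥ R co-migrating fragments for R planted copies) are exact.
This emulates repeat-driven homoplasy (transposable-element families) but
not real genome structure: no compositional heterogeneity, no site
clustering, no scaffold gaps. Passing tests show the pipeline's
bookkeeping and invariants are exact, not that any particular real genome
yields particular counts.

`validation_replica` assembles a genome whose EcoRI+ATG/MseI+ATG profile
under the frozen defaults has 13 peaks with homoplasious peaks of 2 and 6
co-migrating fragments at 113 and 318 bp and singletons at 115 and 410 bp
(19 fragments in total — 11 singletons plus 2 plus 6; a 13-peak profile
with exactly those two homoplasious peaks cannot hold 20 fragments). It
exercises the calibration conventions end to end on known truth.

An independent digest oracle (`naive_digest_oracle`, position-by-position
character comparison, no code shared with the production scanner) verifies
`double_digest` on 100 seeded genomes across GC contents and topologies.

## Numerical and edge-case choices

- Non-ACGTN input characters become `N` (they can never match a site or a
  selective base); `U` is rejected. Sites never match across `N`.
- Plain-text genome input rejects digits outright (numbered dumps must be
  cleaned first).
- Fragments whose selective context would run past a linear sequence end
  are simply not amplified; inside the genome the context is always
  readable (it is plain sequence, even when it overlaps the opposite site
  remnant in very short fragments).
- Peak member order and profile ordering are deterministic (sorted by
  coordinates and peak length); duplicate fragments (same seq_id, start,
  end) are counted once.
- Pairwise identity within a peak is the best of forward vs
  reverse-complement ungapped position-wise identity; members always have
  equal labelled-strand length within one peak under the default policy.
  This approximates an aligner-based identity except for rare
  indel-offset pairs.
- GC class of a combination: strict majority of G/C over all selective
  bases of both primers → GC, strict majority A/T → AT, tie (or zero
  bases) → m. This is the unique simple rule consistent with the group
  sizes of the enumerated one-to-three-base combination set (2/2, 4/8/4,
  32/0/32).
- Pearson correlations use `scipy.stats.pearsonr`; zero-variance input
  returns an explicit undefined result.

## Problem sizes

The acceptance script screens a seeded 5.23 Mb + 77 kb chromosome/plasmid
pair (GC 35.4%) over all 84 EcoRI/MseI combinations with 1–3 total
selective bases, plants a 582-copy repeat in a 2 Mb host, and sweeps 100
random genomes of 1–12 kb for oracle equivalence — sizes chosen to mirror
a bacterial study genome while keeping a full run in single-digit minutes
on one CPU. Property tests use 5–30 kb genomes.

## Known limitations

- No PCR competition, fluorescence intensity or detection-threshold
  modelling: empirical profiles lose faint long fragments and small
  fragments that the simulation retains; the per-bin comparison report
  flags exactly those deficits rather than modelling them.
- Complete-digestion idealisation; no methylation-sensitive isoschizomer
  logic beyond supplying a different site/offset.
- Inter-individual ("technical") homoplasy is out of scope; all statistics
  are within one profile.
- Genome-based reference counts depend on assembly versions; the screen of
  the pinned bacterial assemblies is only run when those genomes are
  present on disk.
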