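# Methods

`tedyn` analyses transposable-element (TE) dynamics in a pair of related
genome assemblies — canonically a predominantly selfing species against an
outcrossing relative — and ships a ground-truthed simulator of exactly the
scenario the analysis targets. This note describes the models, the
parameters that matter, the numerical choices, and what the synthetic data
can and cannot show.

## The analysis pipeline

1. **Family discovery** (`tedyn.discovery`). Repetitive l-mers (canonical
   form, default l = 14, count ≥ 5) seed a majority-vote extension across all
   their genomic occurrences; extension stops on a side after 20 consecutive
   columns whose majority base is supported by fewer than half the
   occurrences. Candidates shorter than 100 bp (2,000 bp in conservative
   mode), supported by fewer than 3 copies, with mononucleotide entropy below
   1.2 bits/base, or self-matching at an offset ≤ 50 bp over more than 80% of
   their length (tandem arrays) are removed, each with a logged reason. De
   novo candidates with **more than** 80% identity to a known-library entry
   are redundant and dropped (identity measured over the shorter sequence,
   best orientation; the boundary is strict — exactly 80% survives). Classes
   are called from structure alone: direct terminal repeats → LTR, inverted
   terminal repeats → DNA, a 3′ poly-A run ≥ 10 bp without terminal repeats →
   non-LTR, else unknown. Terminal repeats are searched over a ladder of
   lengths (≥ 20 bp up to 15% of the element), so short perfect TIRs and long
   LTRs are both found; on random 1-kb sequence the false-call rate is ~0.

2. **Copy annotation** (`tedyn.annotate`). Each family consensus is scanned
   against both genomes on both strands: exact 12-mer seeds are chained along
   diagonals (band 50 bp, gap ≤ 400 bp), each chain is refined by a full
   edit-distance alignment and trimmed to its maximum-scoring local segment
   under match/mismatch/gap-open/gap-extend = +3/−4/−6/−1. Hits need score
   ≥ 250 and length ≥ 100 bp; under this scheme a 100-bp exact copy scores
   300 and clears the cutoff, while short diverged fragments do not — the
   cutoff, not the length floor, is the effective stringency knob.
   Low-entropy genomic windows are excluded from seeding (not from
   alignment). Overlapping hits are resolved best-score-first (ties: longer
   span, then lower start, then family id); the result is provably identical
   to brute-force best-score selection when scores are distinct. The 100-bp
   rule is applied *before* overlap resolution, so sub-threshold fragments
   never displace reportable hits; the alternative order would let them.

3. **Insertion dating** (`tedyn.dating`). Copies of a family are projected
   onto consensus columns (copy insertions relative to the consensus are
   dropped and counted). For every pair sharing **more than** 200 aligned bp
   (strict boundary), divergence is the p-distance or its Jukes–Cantor
   correction K = −(3/4)·ln(1 − (4/3)p); pairs at p ≥ 0.75 are saturated and
   excluded. A copy's age is T = K/2r to its nearest (lowest-K) neighbor,
   with r = 0.015 substitutions/site/Myr by default; a family's average age
   is the mean qualified pairwise K over 2r. Per-genome age distributions
   restrict neighbors to the same genome: a cross-genome ortholog of an
   ancestral copy coalesces at the lineage split, which would floor old
   copies' ages at the split time. Ties in K break to the lexicographically
   smaller partner id; copies with no qualified pair are excluded from
   distributions (not imputed). Per-family PHYLIP distance matrices are
   exported for members with > 200 aligned bp; unqualified pairs are encoded
   as −1.

4. **Comparison** (`tedyn.compare`). Families are partitioned into
   shared/unique/absent; copy totals, means over families present in a
   genome, maxima, and copies-per-Mbp densities are tabulated overall and
   per class. Copy-number vectors are compared with a Wilcoxon rank-sum
   test: exact by full enumeration for tie-free pooled samples ≤ 20,
   otherwise a normal approximation with midranks, tie correction and
   continuity correction; two-sided p doubles the smaller tail (capped
   at 1). Genome length for densities includes N runs by default.

5. **Age distributions** (`tedyn.agedist`). Ages are binned right-open.
   Half-lives come from a truncated-exponential maximum-likelihood fit
   (default window 0–2 Myr, where the exponential describes the data best);
   λ solves the truncated-mean equation by bisection and may legitimately be
   negative when density rises with age (e.g. a flat age spectrum) — the
   identity half_life·λ = ln 2 always holds. A recent insertion deficit is
   tested by fitting the exponential strictly *outside* the suspect window
   (default fit on [w₁, 2w₁+2] Myr for a window ending at w₁), extrapolating
   the expected count into the window, and comparing the observed count via
   an exact (Garwood) 95% Poisson interval on the observed/expected ratio; a
   drop is declared when the interval's upper bound is below 1. The
   rate-sensitivity analysis recomputes ages from stored K at alternative r
   values, rescaling both windows by r_ref/r so that halving the rate
   exactly doubles every boundary.

## The simulator (`tedyn.simulate`)

Each of `n_families` (default 30) TE families is founded `ancestral_depth`
(default 5) Myr before a lineage split at `split_time` (default 5) Myr.
Transposition is a Poisson process per family per lineage
(`insertion_rate_per_family`, default 2.5 events/Myr — with the defaults,
~1,500 copies across two 3-Mbp genomes, close to a realistic per-family copy
count of tens). Copies present at the split are inherited by both lineages.
Sequences evolve by exact Jukes–Cantor transition sampling at `subst_rate`
(default 0.015/site/Myr); with uniform base composition JC coincides with
richer models' equal-frequency limits and is closed-form invertible, which
the tests exploit. In lineage A, insertions inside `suppression_window`
(default 0–0.413 Myr, the selfing-onset analog) succeed with probability
`suppression_factor` (default 0.2). At observation, 30% of copies are
truncated to ≥ 200 bp fragments and all copies are placed unnested,
non-overlapping, random strand, in random background (one contig per
lineage); placement is a direct random layout, failing only when copies
exceed the genome. Family consensi carry the structural signatures the
classifier detects (LTR/TIR/poly-A), in a 4:3:2:1 LTR:DNA:non-LTR:unknown
mix.

**Source model.** New insertions derive from the family *master* — the
classical master-gene model (`p_copy_master = 1.0`; uniform source choice is
available below 1). Under the master model any two observed copies coalesce
at the older of their insertion times, so the nearest-neighbor estimand
equals the copy's own age whenever any younger family member survives. The
master lineage abstracts the *succession* of active source elements and is
not itself emitted as a genomic copy by default (`emit_master`): a placed
source element is intrinsically mis-dated by nearest-neighbor dating (its
nearest relative is its youngest offspring), and under uniform source choice
that failure spreads to every internal node of the copy genealogy — we
measured rank correlation with truth collapsing from ~0.98 to ~0.6-0.74.
These two switches are the difference between a generator that can validate
the dating method and one that mostly probes the method's known blind spot.

Truth records give per-copy family, coordinates, strand, insertion age and
source; the full genealogy is kept so true pairwise divergence times are
computable exactly (`coalescence_time`).

**What the simulator omits** (deliberately): nested/TE-in-TE insertions,
ectopic recombination and gene conversion, rate variation among copies and
sites, indel mutations, population-level polymorphism (one haploid genome
per lineage), and copy deletion. Consequences: annotation never faces
nested fragments, alignment never faces indels (real divergent copies
align harder), and the true age spectrum is flat rather than exponentially
decaying — the half-life machinery is therefore validated on directly
drawn exponential samples, and the deficit detector's null is the flat
spectrum, a *harder* null than an exponential for this purpose since the
fit must extrapolate a rising-toward-the-past density. Passing tests show
the measurement chain is correct under the model's assumptions, not that
those assumptions hold in any real genome.

## Estimator biases, quantified by the tests

* **Upper-limit property.** With the source element unobserved, the
  noise-free nearest-neighbor estimand is ≥ the true insertion age
  (asserted exhaustively against the truth genealogy, same-genome scope).
* **Minimum-statistic noise.** The nearest neighbor minimizes a *noisy* K
  across many partners, pulling estimates downward; in the default
  conditions the net mean signed error is below ~1 Myr against a 0–10 Myr
  range, and rank correlation with truth stays ≥ 0.98.
* **Youngest bins and the deficit test.** Because a very young copy rarely
  has a still-younger relative, its nearest-neighbor age is pulled up toward
  the next older insertion; estimated-age distributions therefore
  under-populate the youngest bins even without any suppression, and the
  deficit detector applied to *estimated* ages overstates drops (both
  simulated lineages show one at default conditions). The detector's power
  and false-positive rate are accordingly specified and tested on true event
  ages; pipeline-level drop reports on estimated ages should be read as
  upper-limit statements, exactly like the per-copy ages themselves.
* **Family averages.** Mean pairwise K/2r estimates the mean pairwise
  *divergence* time, which exceeds the mean insertion age for any branching
  history; the recovery test therefore scores it against the genealogy-true
  mean pairwise coalescence time (within ±20% for families with ≥ 10
  matched copies), not against mean insertion age.

## Problem sizes

Default study conditions are two 3-Mbp lineages with ~1,500 copies in 30
families; the full simulate–annotate–date cycle takes seconds, and the
acceptance script (which adds 100 half-life replicates at n = 2,000 and
2×50 deficit-detector replicates at event-history level) completes in well
under a minute. Discovery demonstrations use a 0.8-Mbp low-divergence pair,
where de novo recovery of all planted families at ≥ 90% identity is
routine.

## Reference fixtures

`tedyn/data/` packages a transcription of a published genome-wide TE census
for *Arabidopsis thaliana* vs *A. lyrata* (per-class copy numbers,
copies/Mbp, percent of genome) and the corresponding family partition
(1,447 shared, 26 unique to the selfer, 345 unique to the outcrosser, 1
undetected — 1,819 total), used for exact aggregation regression tests. One
transcription caveat: the census table's Total copies/Mbp cells (200.6 and
343.4) are inconsistent with the sum of their own class rows (191.8 and
338.4, which match the prose densities of 192 and 338); the tests validate
against the mutually consistent class rows.
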