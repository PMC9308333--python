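# Methods

This note documents the models implemented in `orbimine`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions used throughout.

## Repeat anatomy and the profile family

A repeat unit is modelled as five flanking signature sites around a
hypervariable core of 4–13 residues:

```
-2    -1    core(4..13)    +1     +2    +3
{D}  {D,A,G}   random    {F,V,I}  {G}  {K}
```

The core length window covers the known flax cycle domains (8–9 residues,
mean 8.5) ± 4, the span of published orbitides generally.  A
`FlankingProfile` fixes a subset of the five sites to these signature sets
and leaves the others random.  Two families are provided:

- the **canonical six**: the fully specified profile plus the five
  single-site relaxations (in position order −2, −1, +1, +2, +3);
- the **extended family**: every specified/random assignment with at least
  `min_specified` specified sites.  The default of 2 gives
  2⁵ − C(5,0) − C(5,1) = 26 profiles, with the canonical six first.

**Information content** is Σ over specified sites of ln(20/|allowed|), in
nats, against a uniform 20-residue background (no background composition is
assumed).  Under this measure every profile with ≥4 specified sites exceeds
9 nats (minimum 2·ln 20 + 2·ln(20/3) ≈ 9.79) while no 3-specified profile
does (maximum 3·ln 20 ≈ 8.99), so the commonly used threshold of 9 nats
separates exactly the six most constrained profiles.  Base-2 units would not
produce this separation, which is why nats are the package default.

## Scanning semantics

`scan_sequence` supports two modes.

- `mode="all"` returns every (start, core length) pair satisfying all site
  constraints.  This mode obeys the *relaxation-subset invariant*: relaxing
  any one site can only grow the match set.  It exists chiefly for property
  testing and enumeration.
- `mode="canonical"` returns leftmost, longest-core, non-overlapping matches;
  scanning resumes after each accepted match's end.  This mirrors the
  greedy-quantifier semantics of common regex engines and is the default used
  by the pipeline.  Note that canonical matches of a *relaxed* profile are
  not necessarily a superset of the fully specified profile's canonical
  matches — greediness can shift or merge match windows — so per-profile call
  sets may legitimately differ in either direction; only `mode="all"` is
  monotone under relaxation.

Non-canonical residues (X, *, gaps) never match, at flanks or in the core.
The scanner is a vectorized set-membership sweep; tests verify it against a
brute-force (start, length) enumeration oracle.

## Mining pipeline

1. **Primary pool** — every protein with ≥1 canonical match for ≥1 profile.
2. **Multi-match filter** — keep (protein, profile) entries with
   ≥ `min_matches` matches (default 3: a single match is most likely chance).
3. **Repeat confirmation** — a surrogate for an external repeat finder, fully
   specified and testable: repeat units run from each match start to the next
   match start (last unit = last match span); the protein is confirmed iff
   the *median* of all pairwise unit identities is ≥ θ (default 0.3).
   Identity is identical columns / alignment columns under BLOSUM62 global
   alignment.  The median is robust to one divergent unit; θ = 0.3 sits well
   above the ≈0.1 identity of unrelated random units and well below the
   ≈0.8 identity of genuine tandem duplicates.  Fewer than 3 matches is an
   input error: two matches cannot establish a repeat pattern under the
   multi-match rule.
4. **Calls** — one call per protein confirmed for ≥1 profile;
   `matched_profiles` records every profile independently passed, which
   drives the Venn categorization (each protein falls in exactly one region,
   its exact matched-profile set).

All coordinates everywhere are 0-based half-open on the protein (or on the
forward genome strand for ORFs).

## Iterative PSSM search

The PSSM is per-column log-odds with pseudocounts:
p(a) = (count(a) + α·b(a)) / (n_ungapped + α), score = ln(p(a)/b(a)),
α = 1, b uniform by default; gap-only columns are dropped.  Proteins are
scored with a fixed-width ungapped window (repeats are anchored and
near-constant width; gapped local alignment internals are not reproducible
and add nothing at this scale).  The best window per protein is the hit;
ties resolve to the smallest start.

**Empirical E-values.**  Each of `n_shuffles` replicates draws a complete
surrogate database — one i.i.d. sequence per database entry, residues from
the database composition, lengths equal to the database lengths — and records
the database-wide best window score.  Then

E(s) = #{replicates with best ≥ s} / n_shuffles × database_size.

A hit is accepted when E < 0.01 (the standard inclusion threshold for
iterative searches).  Using the database-wide maximum as the null statistic
makes acceptance mean "better than the best of an entire random database",
which keeps the false-accept probability per protein at ~1/(n_shuffles·N)
rather than ~1/n_shuffles — necessary for a search whose accepted set feeds
back into the query.  The alternative per-sequence null would admit roughly
one random background protein per thousand trials and poison the profile.

**Iteration.**  Accepted best windows are appended to the alignment at the
PSSM coordinates (no realignment — deterministic and sufficient for anchored,
fixed-width repeats), the PSSM is rebuilt, and the search repeats until a
round accepts nothing or `max_rounds` is hit.  The accepted set is
monotonically non-decreasing.  Leader-peptide searches reuse this machinery
on `leader_region` extracts; no separate code path exists.

The per-domain/per-sequence dual-threshold logic of profile-HMM tools has no
analogue here and is deliberately not emulated.

## Repeat analysis

Anchor alignment places the five flank residues in fixed columns and
left-justifies cores, right-padded with gaps to the longest core (a
deterministic, reversible convention).  Logo matrices hold per-column
frequencies over non-gap residues and IC = log₂ 20 − H in bits, with **no**
small-sample correction by default (exact testability); the WebLogo-style
correction (19/(2·ln 2·n)) is available behind a flag.  All-gap columns are
flagged and carry undefined IC.

Note that column IC is not monotone under appending a single duplicate row
(duplicating a minority residue can equalize frequencies and raise entropy);
the invariants that do hold — IC ∈ [0, log₂ 20], conserved columns exactly at
the maximum, invariance under doubling the alignment — are the ones tested.

Candidate mature peptides: the core itself, plus the glycine-appended form
iff the −1 residue is G (alternative cleavage N-terminal of the −1 glycine,
as observed for the G-appended cycle variants).  Head-to-tail cyclization
consumes the terminal water, so the cyclic monoisotopic mass is the plain sum
of residue masses (pyteomics standard table).  Cycles are rotationally
equivalent; the lexicographically smallest rotation is the canonical
representative.

## Phylogenetics

Distances are 1 − fractional identity from global alignment with BLOSUM62,
gap open 10, gap extend 1 (positive magnitudes; a gap of length k costs
open + (k−1)·extend, terminal gaps included).  This distance is simple,
monotone in dissimilarity and exactly testable; no model correction is
applied.  Neighbor joining is the standard Saitou–Nei agglomeration;
negative branch estimates are clamped to zero with the deficit moved to the
sibling branch, preserving the joined pair's path length.  For additive
matrices the algorithm reproduces every leaf-to-leaf path length exactly
(tested on 100 random trees of ≤8 leaves) and its topologies agree with an
independent NJ implementation.  Midpoint rooting bisects the longest
leaf-to-leaf path (2-leaf trees are rebalanced directly).  Bootstrap support
resamples alignment columns with replacement, rebuilds the NJ tree from
p-distances on the resampled columns, and reports the percentage of
replicates containing each internal bipartition of the reference tree.

## Trend statistics

Linear fits are ordinary least squares.  Exponential (y = a·e^{bx}) and
power (y = a·x^b) fits use least squares on log-transformed data — the
spreadsheet-trendline convention, which is also what scattered mining
summaries are usually fitted with; a nonlinear refinement starting from the
log-linear estimate is available behind a flag.  R² is always computed on
the original y scale, so noiseless model-generated data give R² = 1 to
machine precision for all three families.  Profiles are weighted equally.
Ratio summaries report the arithmetic mean and the n−1 sample standard
deviation; a single value yields sd = 0 with an explicit flag.

## Synthetic data generator

The generator emulates a proteome (optionally a genome) containing:

- **background proteins** (default 200, lengths uniform 100–400, residues
  i.i.d. from configurable frequencies, uniform by default), each starting
  with M so genome encoding is uniform;
- **planted repeat proteins** (default 5, each with 3–8 repeats): an
  N-terminal leader (20–60 residues; leader-region extraction needs *some*
  leader, and real leader peptides are of this order), then repeat units
  separated by short spacers (3–15 residues).
  Repeats within one protein are **diverged copies of a per-protein template
  unit** (default 0.15 substitutions/residue, `repeat_divergence`): tandem
  repeats arise by duplication, and real precursor repeats are highly similar
  within a protein while cores stay hypervariable across proteins.  Fully
  independent cores would make planted units no more self-similar than
  noise (median identity ≈ 0.25) and contradict the repeat structure being
  emulated.  Specified flank sites are drawn from the profile's allowed set
  (held fixed across the protein's repeats); per-site **corruption**
  substitutes a uniformly drawn *disallowed* residue, so corrupted sites
  provably break the profile — clean negative controls.
- Planted proteins are rejection-sampled (seeded, bounded retries) until the
  canonical scan of the planting profile returns exactly the uncorrupted
  planted coordinates, so truth-table round trips are exact, not
  probabilistic.
- **genome mode** encodes every protein as a single-exon gene (ATG … stop,
  codons uniform over synonyms, reverse-complemented with probability 0.5)
  between random intergenic stretches that are checked to contain no in-frame
  planted repeat string.  Multi-exon genes are out of scope (six-frame ORF
  extraction cannot interpret splice sites anyway).

What passing tests on this generator show: the pipeline's machinery —
scanning, filtering, confirmation, E-value calibration, truth recovery — is
correct under the stated repeat model.  What they do not show: performance on
real proteomes, whose background composition is non-uniform, whose repeats
carry indels and length drift inside cores, and whose annotation quality
dominates what is findable.  Genome-scale counts from the original study
(e.g. numbers of proteins or repeats recovered from a specific flax
annotation) are annotation-pipeline-dependent and are exercised only
qualitatively here.

## Problem sizes used in the checks

The shipped test suite and acceptance checks run: 5-seed mining round trips
(60 background + 5 planted proteins each), 20-replicate iterative-search
recovery (48 proteins per replicate, 1000-shuffle nulls), a background
match-rate check over >10⁶ scanned positions, 100 additive-matrix NJ
recoveries, 400-replicate repeat-confirmation rejection simulations, and
brute-force oracle sweeps for the scanner (≤60-residue sequences), the ORF
extractor (≤300 nt) and the aligner (≤12 residues).  These sizes were chosen
as the smallest at which the binomial/Poisson bounds in the assertions are
comfortably sharp.

## Known limitations

- Ungapped fixed-width windows in the iterative search cannot follow repeats
  with internal indels relative to the seed alignment.
- The repeat-confirmation rule is a deliberate surrogate for a full repeat
  finder; θ is a config knob, not a calibrated constant.
- Canonical-scan greediness means per-profile protein sets are not nested
  across profile relaxations (see Scanning semantics).
- Pairwise-identity distances saturate for deeply diverged repeats; trees on
  real sequences are exploratory, not inferential.
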