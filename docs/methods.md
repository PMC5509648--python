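# Methods

## Problem and model

The package searches annotated case–control B-cell receptor (IgG-VH)
repertoires for *disease-only motifs* (DOMs): position-specific gapped
amino-acid patterns present in a large fraction of disease-category
subjects and absent from every control. A motif is a set of explicit
motif subsequences (EMSs) — contiguous runs of exactly specified residues
— each anchored by an integer offset counting residues to the left of the
first CDR3 residue of a sequence. A sequence matches a motif iff every
specified position lies inside the sequence and carries exactly the
specified residue; there is no similarity scoring or position weighting.
Writing a motif with `n` gaps requires `n + 1` components; canonical form
sorts components by decreasing offset and fuses touching consistent
components, so the gap count is well defined and parsing round-trips.

Matching is grouped by subject: for motif M, `a` and `b` count the
*distinct* category-A (disease) and category-B (control) subjects with at
least one matching sequence. M is a DOM when `b = 0` and
`a ≥ floor(Dt·|A|)`, with `Dt` the DOM-determining threshold. The floor
(rather than ceiling) reconciles a fractional threshold with integer
match counts: at `Dt = 0.6`, `|A| = 51` the cutoff is 30 subjects even
though 30/51 < 0.6. An implicit `a ≥ 1` guard applies because the
significance bound below is undefined at `a = 0` and floor can reach 0
on very small cohorts.

## The search

Motifs form a network whose edges are three operators, all of which only
*add* constraints (match sets are anti-monotone along every edge):

- **EMS extension** — lengthen one component by one residue at its N- or
  C-side endpoint (N-side extension increments the offset);
- **cardinality extension** — append a new atomic component (a residue
  triplet with an offset), adding one gap;
- **merging** — fold another motif's components in: disjoint components
  append, overlapping-or-adjacent consistent components fuse into longer
  EMSs, and residue conflicts prune the candidate.

One run is a breadth-first traversal seeded at atomic vectors:

1. tally every residue triplet, keeping those carried by at least
   `floor(Dt·|A|)` distinct category-A subjects (a raw-occurrence tally
   over the whole database is available as `tally_mode="occurrences"`);
2. give each surviving triplet the offset maximizing `a` (ties break
   toward the smallest offset, i.e. closest to the CDR3 anchor — any
   fixed rule would do; this one keeps the biologically anchored
   position);
3. add every one-residue extension supported by at least one record;
4. for each frontier motif M, restrict the store to the sub-repertoire
   matching M (the restricted store inherits the parent's |A| and |B|
   denominators) and rerun steps 1–3 there;
5. merge the resulting short motifs into M, discarding conflicts and
   candidates whose gap count exceeds the budget `Gc`;
6. survivors of the separation filter form the next frontier.

The separation score `S_M = a − b` (or the category-blind alternative
`−(a + b − k)²`, maximized when the total match count hits the center
`k`, default `|A|`) is compared against the threshold `St` after seeding,
after non-gapped extension, and after every merge — the most aggressive
filtering consistent with pruning being the point of the threshold. The
DOM test itself is applied to *every* motif scored, independent of `St`.

Every unique canonical motif scored against the main store counts toward
the traversal total `C`; sub-database queries inside the recursive step
do not. Frontiers are processed in canonical-string order and a visited
set guarantees nothing is scored twice, so runs are fully deterministic.
Stop policies: `finish_level` (default) completes the level in which the
first DOM appears and reports all DOMs found by then; `first_dom` stops
immediately; `exhaust` runs the frontier dry. Termination is guaranteed
by the visited set, the gap budget, and the finite motif space a finite
repertoire supports.

The pruning is greedy and can miss DOMs whose individual components
separate poorly in the full cohort (a demonstration fixture in the test
suite constructs exactly this case). That trade-off is what makes
million-sequence repertoires searchable.

## Significance: the ML/Mev bound

A discovered DOM could be *homogeneous* — equally likely to match any
subject — and still show `(a, b=0)` by luck. For homogeneous per-subject
match probability `p`, the probability of exactly `a` category-A matches
and zero category-B matches is `C(|A|,a)·p^a·(1−p)^(|A|+|B|−a)`, which is
maximized at `p = w = a/(|A|+|B|)`. Substituting gives the ceiling

    ML(a,|A|,|B|) = C(|A|,a) · w^a · (1−w)^(|A|+|B|−a)

(the exponent `a(1/w − 1)` is the integer `|A|+|B|−a` and is computed as
such). Over a traversal of `C` motifs the expected number of spurious
homogeneous DOMs with at least `a` matches is bounded by

    Mev = C · Σ_{i=a}^{|A|} ML(i,|A|,|B|)

`Mev ≪ 1` means the discovery is unlikely to be a traversal artifact; the
cutoff is exposed as a configurable `alpha` defaulting to 1.0. Magnitudes
reach 1e−15 and binomial coefficients 1e14, so the fast path works in log
space (log-gamma plus logsumexp) and an exact path using rational
arithmetic (`fractions.Fraction`; the closed form is rational in `w`)
serves as the verification route. The two agree to at least ten
significant digits across the production-scale range.

At the production constants (C = 2,743,571, |A| = 51, |B| = 46) the bound
evaluates to 3.98e−6 at a = 30 and 7.49e−9 at a = 35. Note that the sign
change of −ln(Mev) falls between a = 17 and a = 18 at these constants;
a = 20 gives −ln(Mev) = +2.06, already significant.

Two caveats are worth stating. The bound treats the `C` traversed motifs
via a union bound as if they were a fixed family, but the traversal
steers *toward* separating motifs, so the effective multiplicity is the
motif space reachable by the search, not just the motifs scored; and the
homogeneity model ignores realized sampling fluctuations that the greedy
search can climb. Both effects matter most on small cohorts (see the
threshold discussion below).

## Synthetic cohorts

The generator emulates the statistical shape the search assumes, not
B-cell biology in full. Defaults, chosen once as desk-scale study
conditions:

| parameter | default | rationale |
|---|---|---|
| subjects | 20 cases + 20 controls | large enough to exercise recursion, minutes-scale runs |
| sequences/subject | Poisson(500) | ~20,000 records per cohort |
| framework | one IGHV3-like 95-residue template | see below |
| CDR3 | "CAR" + uniform(10,17)-length random tail | germline-templated start, junctional diversity |
| FR4 | fixed `WGQGTLVTVSS` | J-segment stand-in |
| substitution rate | 0.05/residue on germline-derived positions | IgG-plausible amino-acid-level hypermutation load |
| planted motif | `(TNE, 14), (DTA, 6), (CAR, 0)` | a three-component pattern whose FR3 component (TNE) differs from the template at all positions, whose DTA component coincides with germline, and whose CAR component is universal — so only the full conjunction (or its TNE-containing parts) is disease-private |
| prevalence | 0.7 cases / 0.0 controls | carrier flags drawn per subject |
| carrier fraction | 0.01 of a carrier's sequences | a handful of hits per carrier, mirroring a biomarker-scale signal well under 0.1% of all sequences |

Planted positions are written after mutation and protected from it, so
ground truth is exact; by default every carrier receives
`max(1, round(fraction·n))` planted sequences. A `planting="bernoulli"`
mode draws the planted count as Binomial(n, fraction) instead — carriers
can then hold zero planted sequences, which is what makes the detection
limit observable: pushing the fraction below 1/(sequences per subject)
degrades the recovered carrier fraction monotonically in expectation (the
test suite asserts the trend over seeds).

Carrier flags, repertoire sizes and sequence content draw from
independent spawned substreams of the seed, so structural changes to one
aspect of the generator do not perturb the others' realizations.

**Why a single framework template.** A pool of allelic framework
variants is available (`TEMPLATE_VARIANTS`), but the default uses one
shared framework. With subjects split across variants, any
template-private position sees an effective control denominator of
|B|/(number of variants); at 20 controls that is ~7 subjects, and
ordinary hypermutation noise at such positions then produces `b = 0` by
chance at rates that swamp a desk-scale null experiment. This is an
artifact of small-cohort scale — at 51/46 subjects the same arithmetic is
harmless — so the default removes the confound rather than modeling it.

**What the generator does not model:** V(D)J recombination, clonal
lineage structure, insertions/deletions (the frameshift origin of
real FR3 motifs is a nucleotide-level phenomenon outside amino-acid
scope), per-subject repertoire composition differences, and nucleotide
space generally. Passing recovery tests therefore show that the search
finds low-frequency case-restricted conjunctions in realistic noise —
not that it would survive every artifact of real sequencing data.

## Scaled-down thresholds for the synthetic experiments

The production-scale settings are `Dt = 0.6`, `St = 15`, `Gc = 2`. The
synthetic experiments at 20+20 subjects use `Dt = 0.5`, `St = 13`,
`Gc = 2`, for reasons that follow from the noise arithmetic rather than
from linear scaling:

- **Dt = 0.5.** The DOM count threshold `floor(Dt·|A|)` must sit below
  the plausible Binomial(20, 0.7) carrier count (so planted signal is
  detectable) and above the reach of boundary-noise triplets. Triplets
  spanning the CDR3/FR4 boundary match a given subject with probability
  ~0.15 (a specific random two-residue context times the CDR3-length
  probability, accumulated over ~500 sequences); at threshold 10 the
  chance such a triplet reaches `a ≥ 10` is ~4e−5, while at threshold 8
  spurious atomic DOMs appear at a rate the Mev bound itself predicts
  (Mev(C≈8000, a=8, 20, 20) ≈ 1).
- **St = 13.** Separation noise for a homogeneous motif at match
  probability q is approximately Normal(0, sqrt(2·20·q(1−q))) ≈ sd 2.8
  at the q ≈ 0.7 of single-substitution framework triplets. St = 15 at
  51/46 sits 3–4σ above the corresponding noise; the σ-equivalent at a
  symmetric 20+20 cohort is ~13, not the linearly scaled 6. The
  operating point matters twice over: below ~4σ, hundreds of noise
  atomics enter the frontier, and the recursive step can then fuse a
  noise substitution with weakly-constraining germline context until,
  on a 20-subject control arm, all control carriers are pruned away —
  an adaptive-search effect the homogeneous Mev bound does not cover.
  At ~4.5σ no noise atomic enters the frontier and the control arms
  stay silent. Planted separations (13–19 across the pinned seeds)
  remain above the threshold, and DOM reporting is independent of `St`
  in any case.

Problem sizes throughout (20+20 × ~500 sequences; 10 recovery seeds,
10 reversed and 10 null control replicates; randomized-store oracles up
to 1,000 records; ML maximality grid up to 12+12 at 1% probability
steps) are the package's chosen desk-scale study conditions.

## Numerical and degenerate-input choices

- Sequences are packed into a CDR3-aligned uint8 matrix; a motif query
  is a set of vectorized column comparisons, and restriction slices rows
  while keeping column geometry, so parent and child stores agree
  exactly on every query.
- Out-of-bounds motif positions mean "no match", never an error.
- Records with ambiguity codes (X, B, Z, ...) are rejected at load and
  counted: match semantics over non-standard residues are undefined in
  an exact-match model.
- `w = 1` (a = |A|+|B|) is handled as the closed-form limit ML = 1.
- `mev(C=0, ...) = 0` by linearity.
- Empty DOM lists, empty restricted stores, and empty frontiers are all
  legal, quietly handled outcomes.

## Known limitations

- Coordinates anchor to the CDR3 *left* endpoint only; right-endpoint
  anchoring is not implemented (all reported motifs in the motivating
  use case anchor left of or at the CDR3 start). Components may extend
  past the CDR3 into FR4 when the sequence is long enough.
- Exact residue matching only; no amino-acid similarity classes.
- The scoring function does not weigh how many sequences per subject
  match, only whether any does.
- The greedy St-pruning can miss optimal DOMs (demonstrated in tests).
- The Mev bound is anti-conservative under adaptive traversal on small
  cohorts, as discussed above; significance calls on desk-scale runs
  should be read accordingly.
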