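# Methods

## Model and assumptions

`thermosector` operationalizes a sequence-only route to thermostability
engineering built on two signals that can be read off a labeled family
alignment:

1. **Coevolution.** Residues that co-vary across the family form
   *protein sectors* — groups under shared evolutionary constraint.
   Covariation is measured as the Pearson correlation of BLOSUM50-scored
   substitution events across all unordered sequence pairs
   (residue-correlation analysis, RCA). The method assumes the leading
   eigenmode of this correlation matrix is dominated by shared ancestry
   (all positions load together because related sequences are globally
   similar), so sector analysis uses modes 2–4. No explicit
   phylogenetic correction is attempted beyond dropping mode 1.
2. **Thermal divergence.** At positions that matter for thermal
   adaptation, thermophilic and mesophilic sub-alignments deviate from
   the family background in different directions. Per position each
   class gets a 21-component relative-entropy vector (binary KL of each
   symbol's class frequency against background), and the angle θ
   between the two vectors quantifies divergence. θ is invariant to the
   logarithm base and to rescaling of either vector, and is defined as 0
   when either vector is zero (a position exactly at background carries
   no divergence evidence and must not rank as a design site).

The design step assumes that stabilizing residues can be imported from
thermophiles by consensus: sites in the maximal-mean-θ sector with
θ above threshold are mutated to the thermophilic consensus. The method
deliberately proposes *candidates* ranked by evidence; it predicts no
melting temperatures and performs no structural or energetic checks.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| substitution matrix | BLOSUM50 (pinned) | scores substitution events; embedded as a constant table so results never depend on a library version |
| gap vs residue | −8 | substitution-event score when exactly one sequence is gapped |
| gap vs gap | 0 | two gaps carry no substitution information |
| selected modes | 2, 3, 4 | mode 1 ≈ shared ancestry; three modes support up to ~4 separable sectors |
| null trials | 10 | column-shuffling replicates pooled before the Gaussian fit |
| n_sigma | 2.0 | boundary half-width in null standard deviations |
| k (sectors) | 4 | k-means cluster count; set it to the number of clusters visible in eigenvector space (truth-matched analyses of the default synthetic family use k = 3) |
| k-means restarts | 100 | best-inertia restart count; sector ids relabeled by size then smallest member, so labels are reproducible |
| θ threshold | 0.5 rad | minimum divergence angle for a design site |
| q_floor | 1e-4 | background-frequency floor preventing infinite KL components |
| min subset size | 5 | smallest labeled sub-alignment for which frequencies are estimated at all |

Pearson normalization uses population variance over the pair
population; since numerator and denominator share the convention, the
choice cannot change r, but the brute-force oracle uses the same
convention so equivalence tests are exact at 1e-9.

## Numerical choices

* **Fast RCA route.** Sums over M(M−1)/2 sequence pairs are collapsed
  onto joint 21×21 symbol-pair counts per position pair, turning the
  cost O(N²M²) into O(N²A⁴ + NM); the k = l self-pairs are subtracted
  explicitly. A direct pair-enumeration implementation is retained as
  the independent oracle and the two agree to ≤1e-9 (measured ~1e-14).
* **Degenerate positions** (zero substitution-event variance, e.g. a
  strictly conserved column) have undefined correlation; their rows,
  columns and diagonal are zeroed, they are flagged, and they are
  excluded from sector analysis.
* **Eigenvectors** are sign-fixed (largest-magnitude component
  positive) because eigenvector sign is arbitrary but downstream
  boundaries and clustering must be reproducible. Eigenvalue ties fall
  back on the solver's stable ordering.
* **Null boundaries** are fit on the pooled components of all trials
  (pooled-then-fit, not per-trial-then-averaged) by maximum likelihood
  (sample mean/std); retention requires |v_k(i) − μ_k| > 2σ_k in at
  least one selected mode — the complement of the removal rule "all
  selected-mode weights within the boundary".
* **θ endpoints.** The binary-KL form is used rather than the exact
  log-binomial: the exact form scales with sub-alignment depth M, which
  differs sharply between the thermophilic and mesophilic subsets and
  would distort the angle; the KL form is depth-free. The exact form is
  available (`exact_relative_entropy_vector`) for comparison. The
  0·log 0 = 0 convention makes f = 0 and f = 1 exact; cosines are
  clamped to [−1, 1]; identical vectors short-circuit to θ = 0 exactly.
* **Background q** is taken from the full projected MSA by default
  (gap frequency = overall gap fraction; amino-acid mass scaled by
  1 − q_gap), floored and renormalized. A fixed external background
  table can be supplied instead; which convention a given study used is
  often ambiguous, so both are supported.
* **Replacement ranking** excludes gap and the wild type, breaks
  frequency ties alphabetically, and demotes a thermophile/mesophile
  shared consensus below the runner-up with an explicit rule note. A
  side-chain-class-change annotation (5 classes: hydrophobic, polar,
  positive, negative, special) is attached as advice, never a filter.
* **Tie in target-sector selection** (mean θ equal within 1e-12) is a
  hard error demanding a manual choice, since everything downstream
  hangs on the target.

## The synthetic-family generator

Real inputs at the scale this method targets (thousands of curated,
growth-temperature-annotated homologs) cannot ship with the package, so
every stage is validated on generated families with known truth
(defaults: 150 thermophilic + 150 mesophilic + 100 unlabeled sequences,
60 positions, 5% gaps, plus a gap-free reference row `REF` that defines
the numbering and is excluded from all statistics):

* **Lineage background.** Each sequence belongs to one of two flat
  "clades"; each column carries clade-specific consensus residues at
  weight 0.6. This reproduces the dominant phylogenetic eigenmode of
  real families — making mode-1 exclusion meaningful — without
  simulating a tree.
* **Neutral sectors.** Two position groups (10 and 8 members) driven by
  a per-sequence latent state (3 states, weight 0.75) with per-column,
  per-state distinct consensus residues: covarying but independent of
  thermal class, hence low θ.
* **Thermal sector.** Five dispersed positions whose latent state *is*
  the thermal class: thermophiles show one consensus, mesophiles (and
  unlabeled sequences) another, at weight 0.7. The planted consensus
  pairs change side-chain character strongly (W/D, F/K, C/E, W/S, F/D)
  — as thermal-adaptation substitutions typically do — because pairs
  that are BLOSUM-similar would plant "divergence" invisible to
  substitution-event correlation by construction.
* Unlabeled sequences follow the mesophilic distribution, so including
  them in the background (as the pipeline does) is a realistic stressor.

With these defaults the thermal-sector per-member eigenvector loading
is ≈1/√5 against a null cutoff of ≈2/√60, leaving real but finite
margin: across many seeds roughly one run in twelve loses its weakest
planted site to the significance boundary. That is the intrinsic noise
floor of eigenvector estimates at this family size, and it is why
recovery guarantees are stated per-seed over a 10-seed panel (≥9/10)
rather than absolutely.

What the generator does **not** emulate: true phylogenetic nesting
(only a flat lineage mixture), indel evolution (gaps are i.i.d.),
correlated gap patterns from fragment sequences, biased amino-acid
composition of thermophilic proteomes, and overlapping sectors. Passing
tests therefore demonstrate correctness of the statistical machinery on
data matching its assumptions, not performance on any real family.

## Known limitations

* On signal-free (fully shuffled) alignments the default boundary rule
  retains ~13% of positions (three modes, two-sided 2σ: ≈1 − 0.955³),
  not 5%; with real sector structure present the false-positive rate is
  far lower because modes 2–4 concentrate on the sectors. Users wanting
  a stricter null can raise `--null-sigma`.
* Sector count k is user-chosen; no model selection is attempted.
* No sequence weighting: heavily sampled clades influence both r and
  the profiles in proportion to their abundance.
* The θ threshold (0.5) is a practical default on an absolute scale
  that depends on family depth and background; inspect the θ bar plot
  before trusting the site list on shallow alignments.
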