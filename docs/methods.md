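# Methods

## Model and procedure

The package quantifies amino-acid covariation in a gapped protein multiple
sequence alignment and compares two alignments' covariation patterns.  The
underlying model is purely observational: columns are treated as
categorical random variables over the 20-residue alphabet, sampled once
per sequence, and dependence between two columns is measured by mutual
information computed from raw frequencies.  Two corrections shape the raw
MI into the working score:

- the **average-product correction** subtracts MĪᵢ·MĪⱼ/MĪ from MI(i,j),
  absorbing the systematic component that high-entropy or
  phylogenetically biased columns contribute to every pair they touch;
- the **double column z-scoring (Zpx)** standardizes MIp within each of
  the pair's two columns and combines the two z-scores by a signed square
  root of their product.  This suppresses columns that are uniformly
  "hot" (e.g. misaligned regions) because a pair must stand out in both
  of its columns at once.  A column whose MIp values have zero spread
  contributes a z-score of 0.

Assumptions worth stating: sequences are exchangeable (no tree-aware
weighting — redundancy is instead removed up front by the identity
filter), columns used for scoring are entirely gap-free, and entropies use
plain plug-in frequencies with no pseudocounts.  The logarithm base is 2
(bits); the choice is immaterial for Zpx because z-scoring removes scale,
and a regression test asserts this shift/scale invariance.

## Preprocessing

Two filters emulate the standard curation of family alignments before
covariation analysis:

- **gap-pattern filter**: a sequence is dropped if it has a gap in a
  column where ≥ 90% of the reference (seed) sequences have a residue, or
  a residue where ≥ 90% have a gap.  The 90% rule is applied inclusively
  (≥); the boundary case is tested explicitly.
- **redundancy filter**: greedy first-seen clustering; a sequence is
  dropped if it is ≥ 80% identical to any kept sequence.  Identity is
  matching columns over columns where not both sequences are gapped; the
  80% boundary is inclusive ("80% or greater" is redundant).  Greedy
  first-seen clustering is deterministic and order-stable; its output
  depends on input order, which we accept for reproducibility at this
  scale.

"Ungapped column" is read strictly: a column with zero gaps in the
filtered alignment, which guarantees every frequency denominator equals
the number of sequences.

## Thresholds and parameters

| parameter | default | meaning |
|---|---|---|
| k_sd | 2.0 | covarying-pair threshold: Zpx > mean + k·SD (population SD, off-diagonal pairs) |
| occupancy | 0.9 | gap-pattern filter majority rule |
| identity_threshold | 0.8 | redundancy filter |
| near_far_cutoff | 10 residues | sequence-separation split (near is ≤ 10, inclusive) |
| top_n_transitions | 10 | transitions kept per covarying position pair |
| min size change | 18 Å³ | one methyl group; both positions must change oppositely by at least this |
| burial shell | 8 Å | Cβ-neighbor count, strict <, self excluded |
| burial bins | 0–8 / 9–14 / >14 | exposed / intermediate / buried |
| interface cutoff | 6 Å | heavy-atom rule, strict <; reused for active sites |

The covarying-pair threshold is strict (>): when the Zpx landscape is flat
(SD = 0) the set is empty, since a flat score surface carries no signal.

## Overlap statistics

Percent overlap between pair sets A and B is 100·2C/(A+B) (0 when both
sets are empty).  Significance is the upper-tail hypergeometric
P(X ≥ C) with the population equal to the **universe of unordered pairs of
columns eligible in both alignments** (intersection of the two gap-free
column masks); pairs outside the shared universe are excluded from the
counts so both statistics live on one sample space.  The tail includes the
observed count, the standard enrichment convention.  No multiple-testing
correction is applied; comparisons are reported per alignment pair.

## Pair propensities

PP(x,y) at a set of covarying position pairs is the frequency of the
unordered residue pair {x,y}, pooled over all sequences and all position
pairs, divided by the independence expectation — f(x)·f(y) for x = y and
2·f(x)·f(y) otherwise (the factor 2 reflects unordered pairs).  Expected
single-residue frequencies come from the covarying positions themselves
by default; a switch (`expected_from="alignment"`) pools the whole
alignment instead.  Cysteine-containing pairs are dropped before any
normalization (cysteine is rare in designed sequences and its disulfide
chemistry is a confounder).  Tables are reported as Z-scores over the
defined cells (expected frequency > 0), and two tables are compared by
Pearson r over mutually defined cells.

## Mechanism classification

For a covarying position pair, each residue pair (x,y) observed there is
described by φ(x,y), the phi (Matthews) correlation of the binary row
indicators [column i = x] and [column j = y]; φ is 0 when either
indicator is constant.  A transition between residue pairs is scored

    PT = φ(x,y) + φ(a,b) − φ(x,b) − φ(a,y),

the minimal linear contrast that rewards co-occurring diagonal pairs and
penalizes the cross pairs.  This is our instantiation of the published
favor/disfavor description; the original printed formula is not available,
so PT should be treated as this package's definition.

Two robustness choices depart from the most permissive reading and are
deliberate:

- **candidate support**: transitions are enumerated between residue pairs
  observed in at least max(2, ⌈1% of sequences⌉) rows.  A pair observed
  once yields a φ estimated from a single row; admitting such pairs
  floods the top-10 ranking with artifacts that carry real but
  meaningless volume/hydropathy differences.  `min_fraction=0` restores
  the observed-once rule.
- **per-pair consensus**: the mechanism assigned to a position pair is
  the class with the largest PT-weighted vote (weight max(PT, 0)) over
  its top-10 transitions, falling back to plain counts when all scores
  are non-positive, with ties resolved to the higher-priority class.  An
  unweighted majority lets several near-zero-score runners-up outvote a
  single dominant transition; under the synthetic study conditions this
  mislabeled up to a quarter of hydrogen-bonding pairs, while the
  weighted vote recovers the planted mechanism essentially always.

Classes are tested in fixed priority order — charge, cation-π, π-π, size,
hydrogen bonding, other (hydrophobic), other (hydrophilic), other
(mixed) — and the first match wins:

- **charge**: an oppositely charged pair that swaps signs position-wise
  or becomes fully uncharged; also any transition whose cross pairs
  (x,b) or (y,a) would juxtapose like charges.
- **cation-π / π-π**: exactly one of the two pairs contains a
  cation+aromatic (resp. aromatic+aromatic) combination.
- **size**: one position's residue shrinks by ≥ 18 Å³ while the other
  grows by ≥ 18 Å³.
- **hbond**: exactly one pair contains a donor+acceptor combination.
- residual classes by the hydropathy of all four residues.

The classifier is symmetric under swapping the two residue pairs and
under swapping the two positions; both symmetries are property-tested.

Annotation defaults (all overridable): Zamyatnin residue volumes;
positive K,R; negative D,E; histidine uncharged and non-cationic;
cations K,R; aromatics F,W,Y; side-chain donors R,K,W,N,Q,H,S,T,Y;
side-chain acceptors D,E,N,Q,H,S,T,Y; hydrophobic A,V,L,I,M,F,W,C,P,G.
These tables are conventional rather than derived; sensitivity to them
can be probed through `ResidueAnnotations`.

## Profile similarity

The per-column profile-similarity score is the product of (1) the
probability that the two column distributions share a source,
instantiated as 1 − JS(p,q), and (2) the prior surprise of the merged
source against the background, instantiated as JS((p+q)/2, background),
with base-2 Jensen–Shannon divergence (bounded in [0,1]) and a uniform
default background.  This is a JS instantiation of the two-factor
prof_sim structure, not a numerical reimplementation of the original
tool; scores are comparable within this package only.

## Structural context

Burial uses Cβ atoms; glycine (or any residue missing Cβ) gets a virtual
Cβ from ideal N/CA/C geometry, with the standard tetrahedral coefficients.
Distance rules are strict (<) wherever the convention is ambiguous
("within 8 Å", "within 6 Å"); the boundary behavior is pinned by tests.
Pair distances are minima over non-hydrogen atoms.  Ensemble structural
variation samples up to 10 members with a seeded generator and averages
pairwise Cα RMSD after Kabsch (SVD) superposition restricted to proper
rotations; reflections are rejected via the determinant correction, and
agreement with an independent superposition routine is tested.  Alternate
locations collapse to the highest-occupancy conformer on reading.
Residue-to-column maps are supplied explicitly (TSV) rather than inferred
by alignment, to avoid hidden heuristics.

## Synthetic data: what it does and does not emulate

`SyntheticSpec` draws background columns i.i.d. from the Robinson–Robinson
natural amino-acid frequencies (a realistic marginal composition; any
distribution can be supplied) and plants couplings as two-state models: a
sequence carries either state (x,y) or state (a,b) at the planted pair,
chosen by a Bernoulli draw with the configured balance, after which
per-position substitution noise, duplicated sequences and gap noise are
applied.  The two-state model was chosen over a general Potts sampler
because its mutual information has a closed form (the binary entropy of
the state balance), which makes the generator usable as an oracle.

Default conditions used throughout the tests and the acceptance script:
500 sequences × 50 columns, three planted pairs (one per mechanism:
RE/DR, IA/VV, AP/SS), balance 0.5, noise 0.05.  The "strong coupling"
conditions used for overlap calibration are 500 × 30 with ten noise-free
planted pairs, where planted signal dominates the pair universe.

What the generator does **not** emulate: tree-structured evolution and
the resulting phylogenetic correlation between sequences, insertions and
deletions, composition heterogeneity along the chain, and couplings
involving more than two states or more than two positions.  Passing the
planted-recovery tests therefore demonstrates the statistical machinery,
not robustness to phylogenetic confounding — on real family alignments
the average-product correction mitigates but does not eliminate shared
ancestry effects.

A consequence of the 2-SD rule worth knowing when interpreting overlap
numbers: because the threshold is relative, roughly the upper ~2% tail of
background pairs always enters the detected set.  With sparse planting
(3 pairs among 1225) the detected sets are dominated by this tail and the
percent overlap between two independent realizations is small even with
identical planting; with dense planting the planted pairs inflate the
score SD, push the threshold past the background tail, and the overlap
approaches the constructed sharing fraction.  Real natural-vs-designed
comparisons sit between these regimes.

Toy structures are pseudo-residue chains (N/CA/C/CB) along a self-avoiding
random walk (3.8 Å steps, ≥ 3.5 Å non-adjacent clearance), with the second
residue of each planted pair relocated into contact (< 6 Å minimum
heavy-atom distance, asserted at construction).  They exercise the
geometry code paths; they are not physically plausible backbones.

## Numerical conventions

- 0·log 0 ≡ 0 in all entropies; MI clamped at 0 from below.
- Population SD (divide by N) everywhere: per-column z-scores, the Zpx
  threshold and propensity Z-scores; at realistic pair counts the
  distinction from the sample SD is negligible, and one convention avoids
  mixed estimators.
- APC is undefined for fewer than 3 columns (error) and defined as
  identically 0 when the mean MI is 0.
- Transition ties break lexicographically on (x,y,a,b); transitions are
  reported once, oriented with the lexicographically smaller pair first.
- All user-facing column indices are 1-based; internal indices 0-based.
- Reports serialize with sorted keys so identical inputs yield
  byte-identical output.

## Problem sizes

The test suite and acceptance script run the full chain at 500 × 50 (20
replicates), the dense 500 × 30 configuration (10 replicates per sharing
level), 200 brute-force oracle cases at ≤ 8 × 6, and 2000-replicate null
calibration of the hypergeometric p-value; the entire suite completes in
well under a minute on one CPU.

## Known limitations

- Greedy redundancy filtering is order-dependent (first-seen wins).
- The PT score and the profile-similarity instantiation are this
  package's definitions of verbally described methods; absolute values
  are not comparable to other implementations.
- The hypergeometric universe choice (pairs eligible in both alignments)
  is one defensible convention; p-values shift slightly under others.
- No sequence weighting beyond the redundancy filter; heavily biased
  families should be subsampled upstream.
- mmCIF, symmetry mates and solvent accessibility are out of scope for
  the structure module.
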