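# covarcomp

Compare amino-acid covariation between two protein multiple sequence
alignments — typically a family of natural homologs and a set of sequences
designed computationally for the same fold — and characterize the pairs
they share: how significant the overlap is, which amino-acid pairings are
enriched, what physical mechanism drives each coupling, and where the
pairs sit in the three-dimensional structure.

## Who this is for

Structural bioinformaticians and protein designers who want to ask: *how
much of the covariation seen in a natural protein family is explained by
the structure alone?*  Sequences designed onto a backbone (or a backbone
ensemble) feel only structural constraints; covariation they share with
the natural family is structure-driven, while nature-specific covariation
points at function or phylogeny.

## The statistic

Covariation between alignment columns *i* and *j* is scored with the
mutual-information chain:

1. Shannon entropy per column, H(i) = −Σₓ Pₓ log₂ Pₓ, and joint entropy
   H(i,j) over residue pairs, from raw frequencies (no pseudocounts).
2. Mutual information MI(i,j) = H(i) + H(j) − H(i,j).
3. Average-product correction, removing background signal from column
   entropy and shared ancestry:
   MIp(i,j) = MI(i,j) − MĪᵢ·MĪⱼ / MĪ, where MĪᵢ is the mean MI of column
   *i* and MĪ the overall mean.
4. **Zpx**: MIp(i,j) is z-scored within column *i* and within column *j*;
   the product of the two z-scores is mapped through a signed square root,
   Zpx = sign(zᵢzⱼ)·√|zᵢzⱼ|.

Pairs with Zpx more than two standard deviations above the alignment mean
are the *highly covarying pairs*.  Two alignments' pair sets A and B are
compared by the percent overlap **2C/(A+B)** (C = shared pairs) with an
upper-tail hypergeometric p-value over the universe of column pairs
eligible in both alignments.

Shared pairs are then characterized by:

- **pair propensities** PP(x,y) = f_obs(x,y)/(f(x)·f(y)) at covarying
  positions (cysteine excluded), compared between alignments by the
  Pearson correlation of the per-cell Z-scores;
- **mechanism classification** of the top-scoring residue-pair
  transitions (x,y)→(a,b), scored with the phi-correlation contrast
  PT = φ(x,y) + φ(a,b) − φ(x,b) − φ(a,y), into eight classes in priority
  order: charge, cation-π, π-π, size (≥ 18 Å³ compensating volume change),
  hydrogen bonding, and other (hydrophobic / hydrophilic / mixed);
- **structural context**: Cβ-neighbor burial classes (exposed 0–8,
  intermediate 9–14, buried >14 within 8 Å), minimum heavy-atom pair
  distances, 6 Å interface/active-site flags, and ensemble structural
  variation as mean pairwise Cα RMSD after Kabsch superposition.

A synthetic-data module generates alignments with planted two-state
couplings (charge swap RE/DR, size compensation IA/VV, hydrogen bonding
AP/SS), optional substitution noise, redundancy and gaps, plus toy
structures in which planted pairs are in spatial contact — so the whole
pipeline is testable offline.

## Worked example

```python
import covarcomp as cc

# "natural" vs "designed" synthetic sequence sets: 500 sequences x 30
# columns with ten coupled column pairs planted at identical positions
couplings = (cc.CHARGE_SWAP, cc.SIZE_COMP, cc.HBOND)
spec = cc.SyntheticSpec(
    n_seq=500, n_col=30, noise=0.0, seed=42,
    planted_pairs=tuple((2*k, 2*k+1, couplings[k % 3]) for k in range(10)),
)
natural, designed = cc.generate_alignment_pair(spec, shared_fraction=1.0)

pairs_nat = cc.top_covarying_pairs(cc.compute_covariation(natural), k=2.0)
pairs_des = cc.top_covarying_pairs(cc.compute_covariation(designed), k=2.0)

report = cc.compare_pair_sets(pairs_nat, pairs_des)
print(f"natural covarying pairs:  {report.n_a}")
print(f"designed covarying pairs: {report.n_b}")
print(f"shared pairs:             {report.n_overlap}")
print(f"percent overlap:          {report.percent_overlap:.1f}")
print(f"hypergeometric p:         {report.p_value:.2e}")

trans = cc.top_transitions(natural, spec.planted_pair_set())
for (i, j) in sorted(spec.planted_pair_set())[:3]:
    best = trans[(i, j)][0]
    print(f"columns {i+1:2d},{j+1:2d}: {''.join(best.from_pair)}->"
          f"{''.join(best.to_pair)}  PT={best.score:.2f}  {best.mechanism}")
```

Output:

```
natural covarying pairs:  10
designed covarying pairs: 10
shared pairs:             10
percent overlap:          100.0
hypergeometric p:         1.66e-20
columns  1, 2: DR->RE  PT=4.00  charge
columns  3, 4: IA->VV  PT=4.00  size
columns  5, 6: AP->SS  PT=4.00  hbond
```

Both independently realized alignments carry the same ten planted
couplings, so the two detected pair sets coincide exactly (overlap 100%,
p ≈ 10⁻²⁰ against a universe of 435 column pairs), and the top-scoring
transition at each planted pair recovers the generative mechanism: the
charge swap R·E ↔ D·R, the size compensation I·A ↔ V·V, and the
hydrogen-bond gain A·P ↔ S·S, each with the maximal contrast score
PT = 4 (both diagonal pair correlations +1, both cross pairs −1).

## Command line

```bash
covar simulate --n-seq 200 --n-col 24 --seed 4 --out demo/
covar all --natural demo/natural.fasta --designed demo/designed.fasta \
          --structure demo/structure.pdb --seed 1 --out demo/report/
```

writes `report.json`, `pairs.tsv` and `transitions.tsv` (1-based column
indices throughout).  Subcommands `filter`, `covary`, `compare`,
`mechanisms` and `context` expose the individual stages.

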