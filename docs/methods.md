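# Methods

This note records the statistical model, the conventions chosen where the
underlying method admits variants, and the limits of the synthetic
generator used for validation.

## Semantic similarity (`go_semantics`)

Term similarity follows the Wang graph-based measure. For a term *t*, the
S-value of an ancestor *a* is the maximum over paths from *t* to *a* of the
product of edge weights (`is_a` = 0.8, `part_of` = 0.6; configurable),
with S(t, t) = 1. The semantic value SV(t) is the sum of S-values over the
ancestor closure. Similarity of terms *a*, *b* is

    sim(a, b) = Σ_{c ∈ A(a) ∩ A(b)} (S_a(c) + S_b(c)) / (SV(a) + SV(b)).

S-values are computed once per term by a topological sweep of the ancestor
sub-DAG and cached; cycles and unknown terms are hard errors at
construction/lookup time.

**Gene-level convention.** Similarity of two annotation sets T1, T2 is the
average of the two directional best-match means:

    ½ [ (1/|T1|) Σ_{a∈T1} max_{b∈T2} sim(a,b)
      + (1/|T2|) Σ_{b∈T2} max_{a∈T1} sim(a,b) ].

A common alternative pools both directional maxima over |T1| + |T2|; the
two agree when |T1| = |T2| and differ slightly otherwise. The averaged
form is used throughout and asserted by the test oracles. Similarity
against an unannotated gene is *undefined* (raises), not zero.

## Catalogue compilation (`catalogue_builder`)

Complex significance = mean pairwise gene similarity over all member
pairs; pairs involving an unannotated member are excluded from the mean
(not zeroed); singletons and fully unannotated complexes score 0.

Compilation ranks complexes by (significance desc, size desc, id asc) and
scans down the ranking. A candidate whose Jaccard overlap with an
already-retained complex exceeds `overlap_thres` is removed; if the
overlap also exceeds `merge_thres` its members are merged (set union) into
the retained complex, otherwise it is discarded. Defaults
`overlap_thres = 0.5`, `merge_thres = 0.8`: this ordering is the only one
in which the discard branch (overlap in (0.5, 0.8]) is reachable. With
`grow_absorber=True` (default), later candidates are compared against the
grown member set; `False` freezes comparisons at the original members.
Because merging grows retained complexes, a single pass can leave residual
redundancy; the CLI `--passes` option re-scores and re-compiles until the
pairwise redundancy count (`count_redundancy`, strict `>` on Jaccard)
reaches zero or passes are exhausted. On the synthetic generator's
defaults one pass suffices for every seed probed.

## Downstream statistics

- **Co-complex/PPI overlap** (`cocomplex_ppi`): the co-complex pair set is
  the union of unordered within-complex protein pairs; the overlap ratio
  with a reference edge set is reported as a percentage rounded to two
  decimals, matching the convention of published comparison tables.
- **DDI permutation test** (`drug_network`): observed statistic = number
  of known drug–drug interaction pairs that are co-complex drug pairs
  (two drugs hitting the same complex). DDIs naming drugs outside the
  network's drug universe are excluded. Null replicates draw the same
  number of distinct drug pairs uniformly from the universe;
  p = (1 + #{replicate ≥ observed}) / (reps + 1), so p ≥ 1/(reps+1).
- **Druggability** (`drug_network`): fraction of proteins shared between
  complexes that are established drug targets, with a one-sided binomial
  tail P(X ≥ k | n, p0). The background rate p0 (default 2500/20500,
  roughly established-target genes over protein-coding genes) is an
  explicit parameter because published tail values for this style of test
  are not reproducible from any single obvious p0.
- **Disease enrichment** (`disease_assoc`): per-study disease–gene
  p-values are combined with Fisher's method (χ²(2k) survival function)
  and screened at a cutoff (default 1e-5). Complex association uses the
  inclusive hypergeometric upper tail P(X ≥ t) with universe N = union of
  catalogue members (or user-supplied), K = disease genes in the universe,
  n = complex size, t = overlap. Disease subnetworks connect a disease to
  its significantly associated complexes and their drugs; repositioning
  candidates are drugs attached to a significant complex of the disease.
- **Evaluation** (`complex_eval`): neighborhood affinity
  NA(P,B) = |P∩B|² / (|P||B|); a predicted complex matches a reference
  complex when NA ≥ ω (default 0.2). Precision = matched predicted /
  predicted, recall = matched reference / reference, with F their harmonic
  mean. Clustering-wise Sn, PPV and Accuracy (geometric mean) come from
  the reference×predicted overlap matrix. Predicted singletons are
  excluded by default (`min_predicted_size=2`).

## Synthetic generator (`synthetic_data`)

All randomness flows from one `numpy.random.default_rng(seed)`. The
generator plants: a random acyclic ontology (child → lower-index parent);
disjoint true complexes with limited shared-member adoption; per-module
term annotations; a redundant raw catalogue containing each truth plus
perturbed copies differing by at most one member (Jaccard ≥ 0.7 to the
original, so copies fall in the merge or discard band); a PPI edge set
with within-complex probability `p_in` > background `p_bg`; drug targets
with Zipf-ish multiplicity; DDIs oversampling co-complex drug pairs at
odds `ddi_enrichment` (Gumbel top-k weighted sampling; factor 1 reduces
exactly to uniform); and disease gene sets planted inside chosen
complexes with a configurable leak rate. The manifest records every
planted answer.

Scope: the generator validates pipeline mechanics and statistical
calibration, not biological realism — no degree-corrected PPI topology,
no annotation depth bias, no literature ascertainment bias.

## Numerical choices

- Hypergeometric, binomial and χ² tails come from `scipy.stats`
  (`hypergeom.sf(t-1, …)` for the inclusive tail); tests verify them
  against exhaustive subset enumeration (all universes N ≤ 12) and the
  closed-form Fisher product series.
- The permutation test encodes drug pairs as integers (i·n + j over the
  upper triangle) and vectorises replicate counting with `numpy.isin`.
- Empirical p-values use the add-one convention and are therefore never 0.

## Known limitations

- Significance scoring is O(pairs × annotation terms) with caching at the
  term level; very large catalogues would need batching.
- Merging is greedy and order-dependent only through the deterministic
  ranking; no global optimisation over merge partitions is attempted.
- The redundancy count is a pair count, not an equivalence-class count: k
  mutually redundant complexes contribute C(k,2).
- Evaluation treats complexes as sets; stoichiometry and multi-condition
  variants are out of scope.
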