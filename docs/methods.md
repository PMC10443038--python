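# Methods

## The problem

Secretory proteins reach the endoplasmic reticulum through an N-terminal
signal peptide that is cleaved from the mature chain. The encoded ER
translocation rate is a vector-design parameter: too slow starves secretion,
too fast can outrun folding and assembly capacity, and the optimum is
product-specific — drastically so for two-chain products such as IgG mAbs,
where the light-chain/heavy-chain ratio matters as much as the absolute
rates. `sigpepkit` packages an in-silico route to product-specific
signal-peptide selection: build a large synthetic design space, keep a
diverse, plausible subset, and rank candidates for a given partner protein
with a regression model over simple sequence features.

## Tripartite decomposition

A signal peptide is modelled as N + H + C. The first residue is reserved as
the minimal N-region and the final three residues as the minimal C-region.
Within the remaining interior, every 6-residue window is scored for
hydrophobic content against the nine-residue set {F, I, W, L, V, M, A, Y, C};
a window qualifies at ≥ 4 hydrophobic residues. The H-region is the hull
from the start of the first qualifying window to the end of the last —
intervening sub-threshold windows do not split the domain — **trimmed** to
hydrophobic residues at both ends. The trim is a deliberate design choice:
a qualifying window may overlap up to two flanking polar residues, so the
untrimmed hull systematically leaks into the N/C flanks; trimming makes the
clean case exact (a fully hydrophobic core flanked by non-hydrophobic
remainders is recovered precisely, which the structured fixture database
exploits) while leaving genuinely ambiguous cases to the rule checks.

Rule validation is separated from partitioning because natural signal
peptides frequently breach the synthetic-design bounds (|N| ≤ 10,
6 ≤ |H| ≤ 12 with each left-tiled 6-block ≥ 4 hydrophobic, 3 ≤ |C| ≤ 10);
partitions carry violation flags and a strict mode raises instead. A
trailing partial H-block of length *m* < 6 requires ⌈4·*m*/6⌉ hydrophobic
residues, the pro-rata extension of the full-block rule. Lowercase input is
upper-cased; ambiguity codes are rejected outright, since every downstream
parameter is undefined for them.

## Synthetic library

Per-position alphabets define a 22-mer: N = M then four positions over
{K, T, A, G, S, P, R}; H = eleven positions over {L, A, V} and a final
helix-breaking {P, G}; C = {A,G,S,L,V,I}, {A,G,S,T,C}, {A,G,S}, {A,G,S,C},
{A,G,S,T} at positions −5…−1. Counts are exact products (2401 / 354,294 /
1440; total 1,224,950,247,360). Enumeration streams in lexicographic order
under the fixed residue order A…Y so output is bit-reproducible; sampling
draws per-position index tuples uniformly (switching to a dense
permutation draw when the space is small and the request covers most of
it), so the full space is never materialised. Position conversion helpers
map the −k convention (last residue −1) to 0-based indices.

## Diversity selection

The most mutually different `floor(fraction·N)` strings are retained under
unit-cost Levenshtein distance (computed with edlib; an independent
recursive implementation backs the tests). Maximin subset selection is
solved exactly by enumeration when the instance admits at most 20,000
candidate subsets — small instances deserve the true optimum, and the exact
result is seed-free with lexicographic tie-breaks. Above that bound the
farthest-point greedy heuristic is used: a seeded first pick, then
repeatedly the candidate whose minimum distance to the selected set is
largest (lexicographic ties); its objective is provably ≥ half the optimum.
A mean-distance ranking method is provided as an alternative, with a seeded
reference subsample for very large inputs. At the default 1% fraction the
three regions retain 24, 3542 and 14 domains.

## Sequence features

Seven parameters summarise a sequence context (signal peptide alone, or
signal peptide + first 50 residues of the partner protein; the default
`concat7` mode uses the concatenation, `split14` returns both blocks):

| parameter | definition | units / scale |
|---|---|---|
| pI | Henderson–Hasselbalch net-charge root, Bjellqvist pKa set | pH |
| instability index | Guruprasad DIWV dipeptide weights | dimensionless |
| flexibility | Vihinen normalised flexibility, window 9, mean over windows | dimensionless |
| aliphatic index | Ikai: X(A) + 2.9·X(V) + 3.9·(X(I)+X(L)), mole-% | dimensionless |
| GRAVY | mean Kyte–Doolittle hydropathy | dimensionless |
| ΔG | summed per-residue apparent membrane-insertion free energy, Hessa et al. biological scale | kcal/mol |
| GP% | 100·(G+P)/length, **always on the signal peptide alone** | percent |

pI, instability, flexibility and GRAVY are delegated to Biopython ProtParam;
the aliphatic index, ΔG table and GP% are implemented here. The ΔG scale is
configurable and its identifier is recorded in output metadata. Sequences
shorter than one flexibility window fall back to the unweighted mean of
per-residue scale values (window means are undefined below length 9).
Feature tables are min–max scaled per column with stored (min, max) so the
transform inverts exactly; a constant column maps to 0. Model-side scaling
always reuses the stored training ranges, never re-fits on prediction data.

## Titer model

`TiterRegressor` wraps an XGBoost squared-error booster behind the sklearn
estimator contract. Defaults: colsample_bytree 0.7, learning_rate 0.05,
max_depth 3, min_child_weight 1, n_estimators 100, subsample 1. A
randomised 90/10 split provides both the held-out metrics and the early
stopping monitor (5 rounds). The stopping metric is RMSE: the objective is
unbounded regression, for which log loss is undefined, so a squared-error-
consistent metric is the coherent choice (it remains configurable). All
randomness — split, CV shuffles, booster — derives from one `random_state`,
recorded in the saved bundle (native JSON booster + plain-text metadata);
reload reproduces predictions bit-identically. Model quality is summarised
by repeated K-fold CV (5 splits × 10 repeats, fresh shuffles per repeat)
mean/SD of per-fold MAE. Attributions are XGBoost's native TreeSHAP,
restricted to the early-stopped tree range so the local-accuracy identity
(base value + attributions = prediction) holds row-exactly. Candidate
selection restricts to predictions at or above a percentile (default 95th)
and returns the top *k* (default 3) by value with lexicographic tie-breaks,
flagging a short pool instead of failing.

## Two-chain screen design

Replicate titer tables (construct × molecule, replicate-level values) are
fold-normalised by dividing every value by the control construct's mean, so
the control lands at exactly 1.0 and unexpressed constructs keep fold 0.0
with an `NE` flag. Strength tiering picks high = argmax fold, medium =
nearest to 1.0, low = nearest to 0.8 — the nearest-match rule is this
package's operationalisation of "control-equivalent" and "0.8-fold"
targets — with ties broken by smaller SD then id, and distinctness enforced
by next-nearest substitution (recorded). Designs enumerate ordered (LC, HC)
pairs: P² for full factorial, 3P for the three-tier fractional design
(> 90% reduction at P = 37). Chain-pair features are the element-wise mean
of the two per-chain vectors. Replicate aggregation averages duplicates
within a transfection before averaging transfections.

## External predictors and the naive scorer

SignalP-style short tables (4.x whitespace D-score layout; 6.x tab-separated
probability layout) are parsed into a common score record; the 0.7 cut-off
is applied as strictly-greater (the probability rule) or
greater-or-equal (the D-score rule) — both semantics exist in the field and
the two scores are not interchangeable. The built-in naive scorer is an
in-package heuristic over the toolkit's own design rules (M start,
qualifying hydrophobic window, small −3/−1 residues, proline-free terminal
triplet); it exists so the pipeline runs fully offline and is labelled in
every manifest — it does not emulate any external predictor.

## Synthetic fixtures: what they do and do not show

The structured database generator plants an exact tripartite architecture:
M + a non-hydrophobic N-remainder, a fully hydrophobic H-core (6–12), and a
small/polar C-region (≥ 3), total length 15–30. In this regime the
window-hull-plus-trim decomposition is provably exact, so recovery tests
certify the algorithm, not the data. A hard mode contaminates flanks with
hydrophobic residues at a stated rate to exercise violation flags. Real
signal peptides have graded hydrophobicity and blurred boundaries, so
passing recovery tests does not bound decomposition accuracy on natural
sequences — it verifies the stated window semantics only.

The titer generator produces construct-level expected titers
`clip(w·scaled_features + ε, 0, 1)` with ε ~ N(0, σ²) and replicate
structure of three transfections × two duplicates (small per-transfection
and per-duplicate jitter). Defaults: σ = 0.05; weights pI 0.60, GRAVY 0.10,
ΔG 0.10, GP% 0.10, aliphatic 0.06, instability 0.02, flexibility 0.02 —
pI-dominant, mirroring the feature-importance ordering seen in single-chain
screens, and chosen so the linear signal's spread (SD ≈ 0.17 across the
standard 200-row panel) comfortably exceeds the noise floor; with a weaker
signal the stated recovery bounds would be unreachable by any model.
The standard recovery experiment uses 40 sampled library members × 5
random 50-mer partner prefixes = 200 rows. Clipping to [0, 1] encodes that
negative expression is unphysical. Because titers are a noiseless function
of the *same seven features* the model consumes, recovery tests certify the
fitting machinery, not biological predictivity; real titer variance has
sequence-order effects (e.g. H-domain residue arrangement) these features
cannot see.

## Numerical choices and degenerate inputs

* Distance, enumeration and selection tie-breaks are lexicographic
  throughout, so results are platform-independent.
* Min–max scaling of a constant column yields 0; inverting restores the
  constant.
* `sample_sequences` rejects requests larger than the space; dense requests
  on small spaces use a permutation draw to avoid rejection-sampling stalls.
* Decomposition requires length ≥ 10 (1 + 6 + 3) and an M start; absent any
  qualifying window it reports "no H-domain found" rather than guessing.
* Tiering requires ≥ 3 constructs and substitutes next-nearest candidates
  on tier collisions rather than returning duplicates.
* The ambiguous X10 panel entry (printed with a two-residue alternative
  suffix) is stored verbatim with an ambiguity flag and two concrete
  readings; computations needing one sequence use the first reading only
  when explicitly resolved.

## Known limitations

* Multi-chain titer prediction is out of scope by design: chain-pair
  feature averaging is provided, but HC/LC stoichiometry and assembly
  kinetics make forward prediction unreliable, so the two-chain workflow
  reduces the screen rather than replacing it.
* The seven features ignore residue order; sequences with identical
  composition are indistinguishable to the model.
* The naive scorer is a rule check, not a predictor; externally scored
  tables should be used whenever available.
* Problem sizes in the shipped tests and the acceptance script (200-row
  recovery panel, 100-record decomposition database, reduced end-to-end
  samples) are the package's standard desk-scale conditions; all scale up
  by parameter.
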