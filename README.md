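# sigpepkit

A Python toolkit for engineering the **signal peptides** that control ER
translocation of secreted recombinant proteins in mammalian (CHO) expression
systems. Signal-peptide choice is strongly product-specific: the same leader
can double the secreted titer of one protein and silence another. This
package implements an in-silico workflow for choosing product-specific
signal peptides, for vector engineers and expression scientists who want to
shrink a combinatorial wet-lab screen to a handful of constructs.

## What it does

* **Tripartite decomposition** — split a signal peptide into its N-
  (basic, starts at the initiator Met), H- (hydrophobic core) and C-
  (polar, ends at the cleavage site) regions with a sliding 6-residue
  window (a window qualifies when ≥ 4 of its residues are in
  {F, I, W, L, V, M, A, Y, C}), and validate the split against design
  rules: |N| ≤ 10, 6 ≤ |H| ≤ 12 with every 6-block ≥ 4 hydrophobic, and
  3 ≤ |C| ≤ 10.
* **Combinatorial synthetic library** — per-position residue alphabets for
  a 22-mer synthetic signal peptide (5 + 12 + 5); the Cartesian products
  give 2401 N-, 354,294 H- and 1440 C-domains (≈ 1.2 × 10¹² assemblies),
  with streaming enumeration, membership checking and seeded sampling that
  never materialises the space.
* **Diversity down-selection** — keep the most mutually different 1% of a
  domain set by Levenshtein distance (24 / 3542 / 14 domains per region):
  exact maximin subsets on small instances, farthest-point greedy at scale.
* **Sequence features** — seven physicochemical parameters (pI, instability
  index, flexibility, aliphatic index, GRAVY, membrane-insertion ΔG, and
  signal-peptide G+P%) for a signal peptide alone or concatenated with the
  first 50 residues of its partner protein, with invertible min–max scaling.
* **Titer model** — a scikit-learn-compatible XGBoost regressor
  (`TiterRegressor`) predicting normalised titer from features, with
  repeated 5×10 K-fold CV, TreeSHAP attributions and 95th-percentile
  top-*k* candidate selection.
* **Two-chain screen design** — fold-change normalisation against a control
  construct, high/medium/low strength tiering, full (P²) vs fractional
  (3P) factorial enumeration for mAb LC/HC pairs (1369 → 111 at P = 37),
  and chain-pair feature averaging.
* **Predictor adapters** — parsers for SignalP-style short output tables
  and the 0.7 probability cut-off; a clearly-labelled naive heuristic
  scorer keeps the pipeline runnable fully offline.
* **Synthetic fixtures** — seed-deterministic generators for structured
  signal-peptide databases (planted N/H/C boundaries) and titer tables
  with known feature dependence, so every stage is testable with no
  external data.

## Worked example

```python
>>> import sigpepkit as sk

>>> part = sk.decompose("MGWSCIILFLVATATGVHS")   # the murine Ig HC leader (ISC)
>>> part.n_region, part.h_region, part.c_region
('MG', 'WSCIILFLVATA', 'TGVHS')
>>> part.violations
()

>>> fv = sk.featurize_pair("MGWSCIILFLVATATGVHS", "")
>>> round(fv.pi, 3), round(fv.gravy, 3), round(fv.gp_percent, 2)
(6.488, 1.468, 10.53)

>>> counts = sk.library_counts(sk.default_library_spec())
>>> counts.n_count, counts.h_count, counts.c_count
(2401, 354294, 1440)
```

The decomposition shows the ISC's 12-residue hydrophobic core flanked by a
2-residue N-region and a 5-residue C-region, breaching none of the design
rules. The feature vector says the leader is near-neutral (pI 6.5), strongly
hydrophobic (GRAVY 1.47) and 10.5% glycine/proline — the inputs the titer
model consumes. The library counts are the per-region sizes of the synthetic
design space before diversity down-selection.

A shell session covering the same ground:

```bash
sigpep sample --n 40000 --seed 7 --out sample.fasta
sigpep check-membership --fasta sample.fasta
sigpep featurize --pairs pairs.tsv --mode concat7 --out features.tsv
sigpep train --features features.tsv --targets titers.tsv --seed 1 --out model/
sigpep select --predictions predictions.tsv --percentile 95 --k 3
```

## Layout

```
src/sigpepkit/
  records.py     sequence records + FASTA I/O
  reference.py   packaged 41-element reference panel
  decompose.py   N/H/C decomposition and design rules
  library.py     combinatorial synthetic library
  diversity.py   Levenshtein maximin selection
  features.py    physicochemical parameters + scaling
  model.py       TiterRegressor, CV, attribution, selection
  screen.py      normalisation, tiering, factorial designs
  predictor.py   external-predictor adapters + naive scorer
  fixtures.py    synthetic data generators
  pipeline.py    end-to-end selection workflow
  cli.py         the `sigpep` command line
docs/methods.md  model and design notes
```
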