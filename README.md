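# phenotax

Chemotaxonomic identification of plant species — above all the shrub
*Erica*, whose former altitudinal extent matters for palaeovegetation
reconstruction — from the phenolic monomers released by mild alkaline CuO
oxidation of leaf and twig material and quantified by GC–MS.

The package is aimed at biogeochemists and palaeoecologists who have a
table of per-sample phenol contents (sixteen canonical compounds, in
g kg⁻¹ TOC) with species labels, and want the full analysis chain:

- **Group sums.** The sixteen compounds aggregate into six diagnostic
  families: *p*-hydroxy phenols, vanillyl (V), syringyl (S), coumaryl (C),
  benzoic acids, and hydroxy-benzoic acids. 4-hydroxybenzoic acid belongs
  to two families, so the six sums exceed the plain total by exactly that
  compound's content.
- **Source proxies and diversity.** The classical lignin ratios S/V and
  C/V, and the Shannon–Wiener diversity H = −Σ pᵢ ln pᵢ of each sample's
  16-compound composition (bounded by ln 16 ≈ 2.77).
- **An explicit biomarker rule.** A sample is flagged as *Erica* when its
  relative coumaryl contribution exceeds 0.20 (strictly) **and** its
  relative benzoic-acid contribution lies in [0.05, 0.12].
- **Ordination and clustering.** Z-score normalization, Ward/Euclidean
  hierarchical clustering with an auditable merge history, and PCA.
- **Tree models, from scratch.** CART decision trees (Gini impurity,
  midpoint thresholds, deterministic tie-breaks), a bagged random forest
  with mean-decrease-in-Gini feature importance and representative-tree
  extraction, and a replicated train/test + cross-validation evaluation
  harness (accuracy and F1, positive class *Erica*).
- **A synthetic-data generator.** Dirichlet compositions around
  species-level means, log-normal totals and simulated internal-standard
  recovery, shaped like the study design this analysis serves (47 samples
  over six species; per-species totals 18, 16, 22, 6, 22 and 51 g kg⁻¹
  TOC for Alchemilla, Erica, Helichrysum, Kniphofia, Lobelia and
  Festuca).

## Worked example

```sh
phenotax simulate --seed 11 -o samples.csv
phenotax features samples.csv -o features.csv
```

The feature table carries, per sample, the six group contents, the six
relative abundances, the total, S/V, C/V and H:

```text
sample_id species  total_phenols  rel_coumaryl  rel_benzoic  s_over_v  c_over_v  shannon_h
Erica_001   Erica         14.339         0.263        0.073     0.474     0.952      2.565
Erica_002   Erica         15.126         0.301        0.083     0.427     1.171      2.539
Erica_003   Erica         16.047         0.271        0.094     0.405     1.033      2.563
```

Erica sits above the 0.20 coumaryl threshold with benzoic acids inside
the 0.05–0.12 window, so the rule classifier flags it:

```sh
phenotax classify features.csv -o rule.csv      # is_erica per sample
phenotax cluster samples.csv -k 6 -o clusters.csv
phenotax train features.csv --n-trees 500 --seed 2 -o forest.json
phenotax importance forest.json -o importance.csv
phenotax evaluate features.csv --seed 3 -o eval.csv
```

Species means on the same simulated dataset show the intended contrasts —
Festuca coumaryl-rich (0.323) but benzoic-poor (0.021), Kniphofia and
Lobelia benzoic-rich (0.18, 0.17), and only Erica inside both rule
windows:

```text
             total_phenols  rel_coumaryl  rel_benzoic  shannon_h
Alchemilla          18.083         0.121        0.094      2.631
Erica               15.885         0.275        0.086      2.563
Festuca             49.767         0.323        0.021      2.393
Helichrysum         22.706         0.105        0.107      2.701
Kniphofia            5.693         0.135        0.183      2.758
Lobelia             22.449         0.098        0.172      2.648
```

All of this is equally available as a library (`phenotax.group_sums`,
`phenotax.classify_erica_rule`, `phenotax.grow_forest`, …); the CLI is a
thin wrapper.

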