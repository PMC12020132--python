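# termshift

Text-mining pipeline for measuring how documentation practice shifts after a
hospital intervention. Given a corpus of short clinical free-text records
split into a pre- and a post-intervention period, `termshift`:

1. selects the records containing a **seed term** (e.g. *antimicrobial* and
   its variants *antibiotic*, *antibacterial*, *anti-infective*);
2. runs the preprocessing chain — pluggable tokenization with
   part-of-speech tags, POS filtering, proper-noun anonymization, compound
   term extraction (FLR scoring), and synonym/exclusion standardization;
3. builds a per-period co-occurrence network centred on the seed term using
   the **Dice coefficient** over record sets,
   `dice(a, b) = 2|A∩B| / (|A| + |B|)`, keeping edges with `dice ≥ θ`
   (default θ = 0.3), with Louvain communities, a maximum-weight spanning
   tree and GraphML export;
4. clusters the union of network terms by **Ward's method** on `1 − dice`
   and cross-tabulates each cluster between periods, reporting the post/pre
   odds ratio `OR = ad/(bc)` with a Wald 95% CI and a two-sided **Fisher
   exact** p-value.

Because the seed term is present in every selected record, its Dice
coefficient with any term of record frequency `f` in a period of `n` records
reduces to `2f / (n + f)` — a useful closed form for validation.

A synthetic corpus generator (`termshift.simulate`) emits two-period
tokenized corpora with planted term clusters, planted period odds ratios and
a ground-truth manifest, so every stage is testable without clinical data.

## Worked example

```python
import termshift as ts

# a two-period synthetic corpus with three planted clusters
corpus, truth = ts.generate_corpus(ts.GeneratorConfig(
    n_pre=400, n_post=900, rng_seed=7,
))

cfg = ts.PipelineConfig(out_dir="out", rng_seed=3)
results = ts.run_pipeline(cfg, corpus=corpus)
for row in results["associations"]:
    print(row["name"], row["cells"], round(row["odds_ratio"], 2),
          round(row["p_value"], 4))
```

prints (cells are post-with / post-without / pre-with / pre-without):

```
cluster_1 {'a': 349, 'b': 551, 'c': 220, 'd': 180} 0.52 0.0
cluster_2 {'a': 851, 'b': 49, 'c': 384, 'd': 16} 0.72 0.3344
```

Cluster 1 captures the planted cluster whose prevalence was generated to
*fall* after the intervention (planted OR 0.47, realized cells in
`truth.cluster_cells`): the pipeline estimates OR 0.52 with a vanishing
Fisher p, i.e. a significant decrease. Cluster 2 pools high-prevalence terms
whose shift is not distinguishable from noise at this corpus size (p 0.33).
The `out/` directory holds the per-period seed co-occurrence tables, GraphML
networks with community labels, the spanning-tree backbone, cluster
membership lists, the association report and a run manifest with artifact
hashes.

The same stages are exposed as a CLI:

```sh
termshift simulate --seed 11 --out sim/
termshift run --corpus sim/corpus.jsonl --seed 2 --out run/
termshift sensitivity --corpus sim/corpus.jsonl --seed 2 --out run-early/
```

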