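# arraymeta

Cross-study extraction, merging and meta-statistics for gene expression
data.

Public repositories hold thousands of normalized microarray datasets, and
a common "bench scientist" question is not a genome-wide analysis but a
focused one: *for my list of genes, what happens across all published
studies of this disease?*  `arraymeta` answers it offline, from plain
text files.  Given a directory tree of studies — each a normalized
probes × samples expression matrix with a gene→probe annotation and a
sample-to-group design — it:

1. **extracts** the matrix rows for a user-defined gene list in every
   study, reporting per study which genes were found, which are missing
   from the array annotation, and which are annotated but absent from the
   data;
2. **refines** each study: resolves the intensity scale (automatic log2
   detection or a `NOLOG` folder token), collapses multi-probe genes to a
   single probe by an ordered suffix whitelist (e.g. `_at` before
   `_s_at`) with the brightest control-group probe breaking ties, and
   computes per-group log2 fold changes against the study's control
   group;
3. **merges** all studies into one spreadsheet (genes × group-vs-control
   comparisons, with group names and sample sizes), which can be
   hand-edited — rows sorted, genes or whole studies deleted — without
   breaking the next step;
4. **combines significance** per gene across studies: a pooled-variance
   one-tailed Student's *t*-test per (study, group), then either
   **Stouffer's Z-transform**

   Z_i = Φ⁻¹(1 − p_i)·s_i,   Z_s = Σ Z_i / √N,   p_s = 2(1 − Φ(|Z_s|))

   where s_i = ±1 is the observed direction of regulation (an unweighted
   plain-average Σ Z_i / N variant is available), or **Fisher's method**

   χ²_{2k} = −2 Σ ln p_i

   with 2k degrees of freedom and a majority-vote consensus sign.
   Stouffer's signed construction makes opposite-direction evidence
   cancel, which in practice makes it the more conservative choice for
   "consistently regulated" calls.

Optional filters reproduce standard meta-analysis hygiene: drop
comparisons with group N < 5, genes covered by fewer than 5 studies, and
genes where less than 75 % of studies agree on the direction.

The package also ships a synthetic-data generator (`arraymeta.synth`)
that writes complete study trees with known injected effects, so every
stage — and your own modifications — can be validated end to end.

## Worked example

```sh
python examples/combine_pvalues.py
```

```
Stouffer, both up:   Z_s = 2.3262, p_s = 0.0200
Fisher,   both up:   chi2 = 11.983 (dof 4), p = 0.0175
Stouffer, up+down:   Z_s = 0.0000, p_s = 1.0000
Fisher,   up+down:   chi2 = 11.983 (dof 4), p = 0.0175
```

Two studies, each with one-tailed p = 0.05 in the same direction, combine
to p ≈ 0.02 under either method; if the directions disagree, Stouffer's
signed Z-scores cancel (p = 1) while sign-blind Fisher is unchanged.

`examples/run_full_pipeline.py` runs the whole pipeline on a generated
6-study tree with two injected effects (+1.5 and −2.0 log2 units):

```
gene       combined Z   combined p   sign   mean log2 ratio
GENE0010      -8.142     3.89e-16   -      -1.99
GENE0005       6.550     5.74e-11   +       1.51
GENE0025       2.116       0.0344   +       0.44
```

The two injected genes dominate, with the correct signs and mean merged
ratios close to the injected effects; all other genes are null.
`examples/probe_selection.py` and `examples/filter_merged_table.py`
demonstrate probe collapsing and the hygiene filters.

## Command line

The same workflow is available as a thin CLI:

```sh
arraymeta generate --out tree --seed 1 --studies 6 --genes 50 --effect GENE0005=1.5
arraymeta run --root tree --method stouffer --center mean
arraymeta stats --root tree --method fisher    # re-combine an edited Merged.txt
arraymeta validate --root tree
```

`run` writes `Extracted Data/`, `Refined Data/`, `Merged.txt` and
`stats_summary.txt` under the tree root and never overwrites existing
outputs unless `--force` is given.

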