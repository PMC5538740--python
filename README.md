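# islephylo

Temporal community phylogenetics for island floras: how much have local
extinctions and exotic-plant introductions changed the phylogenetic
diversity of island species assemblages?

The package compares each island's flora between two time slices — the
**pre-European** flora (all natives, including later-extinct species) and
the **current** flora (surviving natives plus naturalized exotics) — on a
single age-calibrated regional phylogeny, and asks whether the changes
exceed what tip-label randomization would produce by chance.

It computes, per assemblage *S* on a chronogram:

* **Faith's PD** = Σ branch lengths of the minimal subtree connecting *S*
  and the root (My);
* **MPD** = mean patristic distance over pairs in *S* ("deep" diversity);
* **MNTD** = mean nearest-taxon distance ("terminal" diversity);
* **SES** = (observed − mean_null)/sd_null over 999 tip-label shuffles,
  with NRI = −SES(MPD) and NTI = −SES(MNTD), classification at |SES| > 1.96;
* **phylo-β-diversity** = 1 − PhyloSor, PhyloSor = 2·BL_shared/(PD₁+PD₂),
  with a matrix-preserving shuffle null (SES_PhyloSor), per-island temporal
  comparisons, among-island spatial matrices, and Mantel tests against
  great-circle distance;
* the contrast layer: per-island percent changes, one-sample t vs μ = 0,
  paired t between periods — and **BLADJ** node-age calibration to build
  the chronogram, plus a seeded synthetic-data generator of whole
  six-island two-period systems.

## Worked example

```python
import islephylo as ip

tree = ip.parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")

print(ip.faith_pd(tree, {"A", "B"}))          # 3.0
print(ip.mpd(tree, {"A", "B", "C"}))          # 3.3333333333333335
print(ip.mntd(tree, {"A", "B", "C"}))         # 2.6666666666666665
print(ip.phylosor(tree, {"A", "B"}, {"A", "C"}))  # 0.5714285714285714
print(ip.phylo_beta(tree, {"A", "B"}, {"C", "D"}))  # 1.0
```

PD of {A, B} is the two tip edges plus their 1-My stem (root edge has
length 0). The two cherries share no branch length, so their beta
diversity is 1 (complete turnover); {A,B} vs {A,C} share 2 of the 3+4 My
spanned, giving PhyloSor 4/7.

A full synthetic analysis, from generator to report tables:

```python
config = ip.SimConfig(rng_seed=42)            # six-island study conditions
tree, matrix = ip.simulate_system(config)
report = ip.run_analysis(tree, matrix, ip.PipelineConfig(n_rand=99, rng_seed=7))
tb = report.summaries["temporal_beta"]["complete"]
print([round(v, 3) for v in tb.values])
# [0.156, 0.119, 0.692, 0.477, 0.542, 0.325]
print(round(tb.mean, 3), round(tb.ttest.t, 2))
# 0.385 4.18
ip.write_report(report, "report/")
```

Each island's current flora has turned over 12–69% of its branch length
relative to its pre-European flora (mean 0.385, significantly above 0) —
driven by the heavy exotic introductions in the default configuration.

The same steps are available from the shell:

```sh
islephylo simulate --seed 42 --out system/
islephylo calibrate --tree system/tree.nwk --ages ages.csv --out chronogram.nwk
islephylo run --tree system/tree.nwk --matrix system/flora.csv \
    --islands system/islands.csv --nrand 999 --seed 7 --out report/
```

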