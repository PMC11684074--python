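# rabnet

Network-resilience analysis and candidate-gene prioritization for
protein–protein interaction (PPI) networks, with a full differential-
expression follow-through for cancer-metastasis studies.

The package is aimed at systems biologists who study a gene family (for
example the Rab GTPases and their interactome) as an undirected PPI network
and want to (i) choose an *optimally sized* network by measuring how its
robustness to random protein failure saturates during serial expansion,
(ii) characterise its topology and hubs, (iii) prioritize candidate genes
around a disease-gene seed set (such as experimentally verified EMT genes),
and (iv) test whether those candidates are differentially expressed between
primary and metastatic tumour cohorts.

## The resilience score

A network of size `N` is dismantled at failure rates `f ∈ [0, 1]` (the
fraction of nodes removed uniformly at random).  The disorder of the
fragmented network is measured by a modified Shannon diversity index over
its component sizes `C_i`, counting every removed node as a singleton
component:

    H(f) = − Σ_i (C_i / N) · log_N (C_i / N)

The base-`N` logarithm pins the endpoints: an intact connected network has
`H = 0` and a fully defragmented one (`N` singletons) has `H = 1`.  `H` is
averaged over 500 random-removal iterations per failure rate, the curve is
integrated over `f` by the trapezoidal rule to give the accumulated entropy
`H_msh` (area under the curve), and

    resilience = 1 − H_msh

so robust networks score near 1 and fragile ones near 0.  Across a series
of serially expanded networks, min–max-normalized resilience is scanned for
a plateau (successive changes < 7%) and the smallest network inside the
plateau is selected as the optimal one.

Around that network, the toolkit provides: topological metrics (density,
mean degree, clustering, characteristic path length in intermediate-node
units), a log–log OLS power-law fit of the degree distribution
(`p(k) ∝ k^−γ`), kneedle elbow detection of hubs on the rank-vs-degree
curve, an adapted MaxLink candidate screen (seed labelling → immediate
neighbours → Disease-Ontology cancer-term filter → robust-loess
connectivity filter), and TNM-staged cohort differential expression
(fold change + Kruskal–Wallis, stratified into high/medium/low
significance tiers; primary→metastatic high/medium genes are *hits*).

A seeded synthetic-data generator produces every input the pipeline
consumes (edge tables, seed lists, DOID maps, FPKM matrices with TNM
metadata) with planted ground truth, so the entire toolkit is testable
without any external download.

## Worked example

```python
from rabnet import (SynthConfig, generate_all, resilience_curve,
                    topology_summary, run_maxlink, build_cohorts, call_hits)

bundle = generate_all(SynthConfig(seed=7))        # 200-node synthetic PPI net
net = bundle.net

curve = resilience_curve(net, n_bins=100, iterations=500, seed=7)
print(f"h_msh={curve.h_msh:.4f} resilience={curve.resilience:.4f}")

summ = topology_summary(net)
print(f"density={summ.density:.4f} clustering={summ.clustering:.4f} "
      f"cpl={summ.cpl:.4f} gamma={summ.gamma:.3f} hubs={len(summ.hubs)}")

cands = run_maxlink(net, bundle.seeds, bundle.doid_map)
print(cands.status.value_counts().to_dict())

study = build_cohorts(bundle.matrix, bundle.meta)
hits = call_hits(cands, study)
print(sorted(hits.loc[hits.is_hit, "gene"]))
```

prints

```
h_msh=0.5653 resilience=0.4347
density=0.0441 clustering=0.1185 cpl=1.5474 gamma=1.735 hubs=12
{'removed_connectivity': 75, 'removed_annotation': 41, 'final': 13}
['G0073', 'G0083', 'G0095', 'G0097', 'G0119', 'G0136', 'G0144', 'G0167', 'G0186', 'G0197']
```

Reading the output: this 200-node network accumulates entropy area 0.5653
under random failure, i.e. resilience 0.43 — moderate robustness, typical
for a sparse heavy-tailed graph of this size.  Its degree distribution is
weakly scale-free (γ ≈ 1.7) with 12 hubs above the degree-curve elbow.  Of
129 candidate genes neighbouring the seed set, 41 are removed for prior
cancer annotations and 75 for degree-explained seed connectivity, leaving
13 finalists; the 10 recovered hits are exactly the generator's 10 planted
genes (log2 fold change 3 in the metastatic cohort), each reaching the
high-significance tier (|log2FC| > 2, P < 0.001).

The same steps are available from a shell:

```sh
rabnet simulate --seed 7 --outdir fixtures/
rabnet build --edges fixtures/net.tsv --min-score 0.6 --out net.tsv
rabnet resilience --net fixtures/net.tsv --bins 100 --iterations 500 --seed 7 \
       --out curve.tsv --summary summary.json
rabnet topology --net fixtures/net.tsv --out topo.json
rabnet maxlink --net fixtures/net.tsv --seeds fixtures/seeds.txt \
       --doid fixtures/doid.tsv --out candidates.tsv
rabnet diffexpr --expr fixtures/fpkm.tsv --meta fixtures/meta.tsv \
       --candidates candidates.tsv --out hits.tsv
```

All commands are deterministic for a fixed `--seed`.

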