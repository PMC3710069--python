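# mnalign — probabilistic multiple alignment of PPI networks

`mnalign` aligns two or more protein–protein interaction (PPI) networks:
it groups proteins from different species into *equivalence classes* of
putative orthologs, using both node similarity (e.g. BLAST bit scores)
and the similarity of interaction neighbourhoods.  It is built for
comparative systems biology — predicting conserved complexes and
transferring functional annotation across species — and scales to tens
of networks with thousands of nodes on a single core.

## Method

Given networks 𝒢ᵤ = (Vᵤ, Eᵤ, w) and sparse node-similarity scores
h(x, y) for each network pair, the pipeline has four stages:

1. **Semi-Markov random-walk (SMRW) correspondence scores.**  A
   simultaneous random walk on two networks is a walk on their product
   graph; giving product state (x, y) the mean holding time h(x, y),
   the long-run occupancy factorises into a closed form over the sparse
   support,
   c(x, y) ∝ π_a(x) · π_b(y) · h(x, y),
   where π is the weighted-degree stationary law of the reversible walk
   on each network.  The dense product graph is never built.
2. **Pairwise alignment probabilities.**  Correspondence scores are
   balanced across each node's competing candidates,
   P(x ∼ y) = ½ [ c(x,y)/Σ_{y′} c(x,y′) + c(x,y)/Σ_{x′} c(x′,y) ],
   which is symmetric in the two networks and lies in [0, 1].
3. **Probabilistic consistency transformations.**  An *intra-network*
   pass mixes each pair with its neighbourhood through the transition
   matrices, Q = α P + (1 − α) T_a P T_bᵀ (orthologs tend to be
   conserved as connected complexes), and a *cross-network* pass
   propagates through every third network z as an intermediate,
   weighting z by the homology weights Pr(𝒢_a ∼ 𝒢_z) estimated from
   maximum-weight bipartite matchings of the probability matrices.
   Both passes keep only entries in the original support or the top 1 %
   of transformed values.
4. **Greedy maximum-expected-accuracy (MEA) construction.**  Candidate
   pairs are inserted in decreasing probability; a node joining a class
   that already holds nodes from its own network must pass a coherence
   test (its mean probability against the class must reach γ times the
   incumbents' average), and each class holds at most ℓ nodes per
   network.  Defaults follow the method's published settings:
   α = 0.9, γ = 0.8, ℓ = 10.

A synthetic-family generator (duplication-based DMC/DMR/CG growth from
a common ancestor, bias-separated gamma score distributions, and a
hub-seeded subnetwork resampler) provides ground-truth orthology for
end-to-end validation, and the evaluation module implements the
standard measures: specificity (SPE), correct nodes (CN), mean
normalized entropy (MNE), conserved (orthologous) interactions
(CI/COI), coverage histograms, sensitivity and pair accuracy.

## Worked example

Generate a 3-species family with known orthology, align it, and score
the result:

```sh
mnalign simulate --model dmc --ancestor 50 --sizes 100,120,140 \
    --bias 500 --seed 42 -o fam
mnalign align -n fam/net0.tsv -n fam/net1.tsv -n fam/net2.tsv \
    -s fam/net0__net1.tsv -s fam/net0__net2.tsv -s fam/net1__net2.tsv \
    -o pred.clusters
mnalign evaluate -a pred.clusters \
    -n fam/net0.tsv -n fam/net1.tsv -n fam/net2.tsv \
    -g net0,fam/net0.annotations.tsv -g net1,fam/net1.annotations.tsv \
    -g net2,fam/net2.annotations.tsv \
    -t fam/truth.clusters --report report.json
```

`report.json` then contains (this exact run):

```json
{
    "spe": 92.73, "cn": 319, "mne_x100": 6.29, "sensitivity": 95.80,
    "ci": 870, "coi": 867, "n_classes": 55,
    "pair_accuracy": 0.770
}
```

92.7 % of predicted equivalence classes are pure (all members share one
ancestral gene family), 319 of the aligned proteins sit in pure classes,
the label mixtures have very low entropy, and 867 of the 870 conserved
interactions connect orthologous classes.  Each line of
`pred.clusters` is one equivalence class of `network::node` tokens.

The same pipeline is available as a library:

```python
from mnalign import grow_family, simulate_scores, ScoreModel, \
    align_networks, RunConfig, pair_accuracy

fam = grow_family("DMC", 100, [200, 250, 300], seed=0)
sims = simulate_scores(fam, ScoreModel(bias=1000.0), seed=1)
result = align_networks(fam.networks, sims, RunConfig())
print(pair_accuracy(result.alignment, fam.truth))
```

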