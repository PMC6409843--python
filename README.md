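# ssecluster

Clustering cells from single-cell RNA-seq expression matrices without a
preset cluster number, by combining **multikernel similarity learning**
with **two-dimensional structure-entropy minimization** on the resulting
weighted cell network, followed by mean-based marker-gene ranking and
NMI/ARI evaluation against reference labels.

The package is aimed at anyone clustering scRNA-seq data where the number
of cell subpopulations is unknown: the cluster count is an *output* of the
entropy minimization, not an input.

## Method

Given a nonnegative cells × genes matrix `X` (optionally log2(x+1)
transformed), three stages run in order:

1. **Similarity.** A bank of Gaussian kernels, one per parameter pair
   (k, σ) over a grid of neighbourhood sizes and bandwidth multipliers,
   is combined by alternating minimization of

   ```
   min_{S, L, w}  Σ_l w_l ⟨D_l, S⟩ + β‖S‖²_F
                  + γ tr(Lᵀ(I − (S+Sᵀ)/2)L) + ρ Σ_l w_l log w_l
   s.t.  S rows on the simplex,  LᵀL = I_C,  w on the simplex
   ```

   where `D_l` is the distance induced by kernel *l* and `L` is an n × C
   rank-enforcing factor pushing the similarity toward C blocks (C comes
   from an eigengap estimate unless overridden). The per-row simplex
   projection leaves most entries of `S` exactly zero, so the similarity
   is sparse by construction.

2. **Graph + entropy.** Every positive entry of `(S+Sᵀ)/2` becomes an
   edge of a weighted cell network G — no k-nearest-neighbour cutoff is
   applied. For a partition P = {X₁…X_L} with community volumes `Vol_l`
   (sum of member degrees), boundary weights `e_l` and total volume `2e`,
   the two-dimensional structure entropy is

   ```
   Hᴾ(G) = − Σ_l (Vol_l/2e) Σ_{i∈X_l} (dᵢ/Vol_l) log2(dᵢ/Vol_l)
           − Σ_l (e_l/2e) log2(Vol_l/2e)
   ```

   the expected number of bits to encode a random walker's position under
   a two-level community code. The partition minimizing Hᴾ(G) — found by
   deterministic greedy agglomeration with a Kernighan–Lin-style
   relocation refinement — is the reported clustering.

3. **Markers + metrics.** Each gene is assigned to the community with the
   highest mean expression and ranked within it; predicted partitions are
   scored against reference labels with NMI (base-2) and ARI.

## Worked example

```python
import ssecluster as sc

# 60 cells in 3 planted clusters of 20, 500 genes, ~50% dropout
ds = sc.generate_planted_expression(sc.SyntheticConfig(seed=1))
res = sc.cluster_cells(ds.X, true_labels=ds.true_labels)

print(f"communities: {res.n_communities}")
print(f"structure entropy: {res.entropy.total_bits:.4f} bits")
print(f"NMI = {res.metrics['nmi']:.3f}, ARI = {res.metrics['ari']:.3f}")
print("top markers of community 0:", res.markers.per_community_rankings[0][:5])
```

prints

```
communities: 3
structure entropy: 5.2442 bits
NMI = 0.939, ARI = 0.950
top markers of community 0: ['gene_0025', 'gene_0049', 'gene_0008', 'gene_0024', 'gene_0036']
```

The three planted subpopulations are recovered without the cluster number
ever being supplied: encoding the cell graph with this 3-community
partition costs 5.24 bits per random-walk step versus 5.90 bits with no
community structure, and the recovered labels agree with the planted ones
at ARI 0.95. The top-ranked markers of community 0 all lie in its planted
marker block (genes 0–49).

The same pipeline is available from the shell:

```sh
sse simulate --seed 1 --out expr.csv
sse run --input expr.csv --labels expr_labels.tsv --outdir out --seed 1
sse entropy --graph edges.tsv --partition clusters.tsv   # standalone Hᴾ(G)
```

## Layout

- `src/ssecluster/similarity.py` — kernels, rank estimate, S/L/w optimizer
- `src/ssecluster/graph.py` — weighted cell network
- `src/ssecluster/entropy.py` — structure entropy, minimizer, exact oracle
- `src/ssecluster/markers_metrics.py` — marker ranking, NMI/ARI
- `src/ssecluster/synthetic.py` — planted-cluster generator, toy graphs
- `src/ssecluster/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
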