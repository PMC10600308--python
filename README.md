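# pasl — pathway activity score learning

Unsupervised dimensionality reduction for gene-expression matrices whose
latent dimensions are biologically interpretable. Instead of free-form
principal components, the learned dictionary `D = [D1; D2]` contains
*inference atoms* (rows of `D1`) whose support is constrained to one known
geneset each — KEGG/Reactome/Biocarta pathways from a GMT file, or any
other membership structure — plus unconstrained sparse *discovery atoms*
(`D2`) that soak up structured variance no known geneset explains. For
standardized data `X_z` the model is

    X_z = L · D + η,        L = X_z · D⁺,

so each column of the score matrix `L` is a **pathway activity score**: one
number per sample summarizing the collective expression of one geneset.
Atoms are built greedily by restricted PCA with deflation; candidate
genesets are ranked by explained variance divided by the Box-Cox transform
`(|g|^λ − 1)/λ` of the geneset size (λ = 1/3 by default), which removes the
mechanical advantage of large genesets. A threshold `t` (default 0.9) on
the actual-to-expected variance ratio controls how often the ranking is
recomputed (static `t = 0` … dynamic `t = 1`). Scores can feed a
permutation-based **differential activation analysis** (per-atom Welch
t-tests), the geneset-level analog of differential expression.

Intended users: computational biologists who want compressed, interpretable
representations of bulk or single-cell expression matrices, and a
geneset-level two-group test that operates on covariance-aware scores
rather than gene-level statistics.

## Worked example

Everything below is generated — no downloads. The planted-model generator
draws genesets with sizes in {30, 50, 100, 200}, a ground-truth dictionary
supported on 20 of them, and scores/coefficients uniform on
[−1.5, −0.5] ∪ [0.5, 1.5]:

```python
import pasl

spec = pasl.SyntheticSpec(seed=7)              # 400 samples x 500 features
X, truth = pasl.simulate(spec)
train = pasl.ExpressionMatrix(X.values[:300], X.sample_ids[:300], X.feature_ids)
valid = pasl.ExpressionMatrix(X.values[300:], X.sample_ids[300:], X.feature_ids)

model = pasl.fit(train, truth.G_true, a1=20, a2=5, nz=100, seed=7)
scores = pasl.transform(valid, model)          # 100 x 25 activity scores

ev = pasl.explained_variance(valid, model, scope="inference_only")
base = pasl.permuted_baseline(valid, model, seed=0, scope="inference_only")
print(f"held-out explained variance (D1): {ev:.3f}")
print(f"column-permuted baseline:         {base:.3f}")
```

prints

```
held-out explained variance (D1): 0.974
column-permuted baseline:         0.039
```

The 20 geneset-constrained atoms reconstruct 97.4% of the held-out
standardized variance, while a random sub-space projection of the same
sparsity (obtained by permuting the validation columns) retains only 3.9% —
the dictionary generalizes and is far from a random projection. Atom names
(`GS:<geneset>#<k>` for inference scores, `DISC#<k>` for discovery scores)
become the column headers of the score matrix. A two-group comparison on
the scores:

```python
labels = ["A"] * 50 + ["B"] * 50               # arbitrary split: a null
res = pasl.differential_activation(scores, labels, n_perm=999, seed=0)
print(res.table.head(3).to_string(index=False))
```

```
      atom        t     p  rank
    DISC#5 2.698499 0.008     1
GS:GS013#1 2.491170 0.013     2
GS:GS010#1 1.970221 0.057     3
```

With labels unrelated to the data, the best of 25 atoms reaching p ≈ 0.008
is unremarkable (add-one permutation p-values, no multiplicity correction;
pass `fdr=True` for Benjamini–Hochberg q-values).

The same pipeline is available from the shell:

```sh
pasl simulate --seed 1 --out-dir data/
pasl fit --expr data/expression.tsv --gmt data/genesets.gmt \
         --a1 20 --a2 5 --nz 100 --seed 1 --out model.json
pasl transform --model model.json --expr data/expression.tsv --out scores.tsv
pasl daa --scores scores.tsv --labels labels.tsv --nperm 10000 --seed 1 --out daa.tsv
pasl evaluate --model model.json --expr data/expression.tsv --seed 1
```

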