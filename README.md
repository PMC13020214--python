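# sapling-trees

Backbone-tree summarization of tumor phylogeny solution spaces from bulk
DNA sequencing read counts.

## The problem

Bulk DNA sequencing of a tumor yields, for each somatic mutation *i* and
each sample *p*, a variant read count `a[p,i]` and a total read count
`d[p,i]`. Under the infinite sites assumption the mutations are related by
a rooted *mutation tree* `T`: each node is a mutation, and a cell carries a
mutation exactly when it carries every mutation on the path from the root.
Writing `f[p,i]` for the (unknown) fraction of cells in sample `p` that
carry mutation `i`, any valid tree must satisfy the **sum condition**:

```
f[p,i] >= sum over children j of i of f[p,j]    for every sample p
```

Reads are modeled binomially, giving a tree log-likelihood

```
L(A, D | T) = max over F satisfying (SC) of
              sum over p, i of [ a log f + (d - a) log (1 - f) ]
```

(binomial coefficients omitted; they do not depend on `F` or `T`).

At realistic depths many trees explain the data almost equally well. This
package therefore works with the **ρ-solution space** `T(ρ)`: all trees
whose likelihood is within a factor ρ of the maximum. Instead of reporting
one arbitrary tree, it finds a small *backbone*: a subset `S` of mutations
such that the projections `T[S]` of the solution-space trees onto `S`
(contracting every node outside `S` while preserving ancestry) collapse to
few distinct trees. The backbone summarizes what all near-optimal trees
agree on.

Two selection modes are provided:

* **ℓ-constrained** — pick `|S| = ℓ` mutations, greedily in decreasing
  total naive frequency, and enumerate the retained backbone trees per
  round (`fast_backbone_enumeration`).
* **τ-constrained** — grow `S` until the number of retained backbone trees
  would exceed a budget τ, and return the largest prefix that stays within
  budget (`backbone_by_tau`).

A beam search (`beam_enumeration`) infers full-size trees, and a
brute-force oracle (`solution_space`, small n only) certifies optimality.

## Worked example

Input is a long-format TSV with one row per (mutation, sample) cell:

```bash
cat > counts.tsv <<'EOF'
mutation_id	sample_id	var_reads	total_reads
TP53	s1	90	100
KRAS	s1	40	100
PTEN	s1	40	100
TP53	s2	88	100
KRAS	s2	60	100
PTEN	s2	25	100
EOF

sapling backbone --long counts.tsv --ell 3 --rho 0.9 --out out
```

which prints (to stderr):

```
INFO iteration 2: 2 candidates, 1 retained (0.012s)
INFO iteration 3: 4 candidates, 2 retained (0.013s)
S=['TP53', 'KRAS', 'PTEN'] trees=2 history=[1, 1, 2]
```

and writes `out/backbone.json`:

```json
{
  "S": ["TP53", "KRAS", "PTEN"],
  "ell": 3,
  "history": [1, 1, 2],
  "rho": 0.9,
  "trees": [
    {
      "loglik": -327.33781103107356,
      "parent": {"KRAS": "TP53", "PTEN": "KRAS"},
      "root": "TP53"
    },
    {
      "loglik": -327.33781103107356,
      "parent": {"KRAS": "TP53", "PTEN": "TP53"},
      "root": "TP53"
    }
  ]
}
```

The data cannot distinguish whether PTEN descends from KRAS or sits beside
it — both trees fit exactly equally well — but both agree that TP53 is the
root and the parent of KRAS. The brute-force oracle confirms this is the
whole ρ=0.9 space, and that under a budget of τ=1 backbone tree the best
subset is {TP53, KRAS}:

```bash
sapling oracle --long counts.tsv --rho 0.9 --tau 1 --out oracle.json
```

```
|space| = 2
```

with `oracle.json` containing

```json
"optimal_tau": {"S": ["TP53", "KRAS"], "n_backbones": 1}
```

Other subcommands: `sapling simulate` (synthetic instances with known
ground truth), `sapling fulltree` (beam search), `sapling evaluate`
(parent–child, ancestor–descendant, CASet and DISC distances). Wide-matrix
CSV input (`--var`/`--total`) and mutation-cluster aggregation
(`--clusters`) are supported everywhere; see `sapling COMMAND --help`.

## Python API

```python
import sapling as sp

inst = sp.simulate_instance(sp.SimulationConfig(n=6, m=2, seed=1))
res = sp.fast_backbone_enumeration(inst.data, sp.EnumerationConfig(rho=0.9, ell=4))
space = sp.solution_space(inst.data, 0.9)          # brute force, small n
recall = sp.backbone_recall(res.trees, space, res.S)
```

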