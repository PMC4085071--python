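# funchill

Distance-based functional diversity of Hill-number type, for community
ecologists (and anyone with a symmetric distance matrix — microbiome,
trait, or nucleotide-difference data alike) who want diversity and
between-assemblage differentiation measures that behave like effective
numbers.

## The measures

For an assemblage with species relative abundances *p₁, …, p_S* and a
symmetric pairwise functional distance matrix [*d_ij*] (e.g. a Gower
distance computed from traits), Rao's quadratic entropy

  *Q* = Σ_ij *d_ij p_i p_j*

is the mean distance between two randomly sampled individuals.  The
**functional Hill number** of order *q* ≥ 0,

  *ᵠD(Q)* = [ Σ_ij (*d_ij*/*Q*) (*p_i p_j*)ᵠ ] ^ 1/(2(1−q)),

is the effective number of equally abundant and equally distinct species
(constant pairwise distance *Q*); *q* tunes the weight given to abundant
species, with the *q* = 1 case defined by its limit.  Two companions carry
distance units: the **mean functional diversity** *ᵠMD* = *Q·ᵠD* and the
**total functional diversity** *ᵠFD* = *Q·(ᵠD)²*, the effective total
distance between species.  At *q* = 0, *FD* reduces to *FAD* (the plain sum
of pairwise distances); with a constant distance matrix, *ᵠD* reduces to
the ordinary Hill number; and both *ᵠD* and *ᵠMD* obey the replication
principle (pooling *N* equally diverse, completely distinct assemblages
multiplies them by *N*, and *ᵠFD* by *N²*).

Over *N* assemblages each measure decomposes multiplicatively into
gamma/alpha/beta with *FD_β* = *FD_γ*/*FD_α* ∈ [1, *N²*], which transforms
onto [0, 1] as four normalized overlap families: local *C\*_qN*
(func-Sørensen / Horn / Morisita-Horn at *q* = 0, 1, 2), regional *U\*_qN*
(func-Jaccard at *q* = 0), homogeneity *S\*_qN*, and the turnover
complement *V\*_qN*.  Differentiation is always 1 − similarity.  The
abundance-only *C_qN*/*U_qN* from partitioned Hill numbers, and the legacy
quadratic-entropy measures (additive excess, and the two normalizations of
the maximum-distance effective number 1/(1 − *Q*/*d_max*)), are included
for comparison — the latter are only trustworthy on ultrametric matrices,
which `funchill validate --ultrametric` diagnoses.

## Worked example

Four species in two completely distinct assemblages — {a, b} and {c, d},
each pair equally common — with the bundled non-ultrametric matrix whose
cross-assemblage distances (0.9, 0.8, 0.2, 0.2) exceed the
within-assemblage distances (0.1):

```python
from funchill import fd_beta, functional_triple, legacy_differentiation, local_overlap, pool
from funchill.datasets import example2_matrices

_, dm, Z = example2_matrices()          # non-ultrametric case
p = pool(Z)                             # pooled relative abundances
for q in (0, 1, 2):
    t = functional_triple(p, dm, q)
    beta = fd_beta(Z, dm, q).beta
    print(q, t.Q, t.D, t.FD, beta, 1 - local_overlap(beta, 2, q))
```

prints (rounded)

```
0 0.2875 4.0 4.6 4.0 1.0
1 0.2875 4.0 4.6 4.0 1.0
2 0.2875 4.0 4.6 4.0 1.0
```

Read: the pooled assemblage has mean pairwise distance *Q* = 0.2875, an
effective 4 equally distinct species, and total functional diversity 4.6
(= *FAD*, since abundances are equal).  The functional beta diversity hits
its maximum *N²* = 4, so the local differentiation 1 − *C\** is 1 at every
order — the two assemblages share no species and no distances.  The legacy
quadratic-entropy measures on the same input give 0.826, 0.559 and 0.388:
`legacy_differentiation(Z, dm)` shows how they understate differentiation
on non-ultrametric matrices (on the ultrametric variant they correctly
return 1).

The same computations run from the shell:

```sh
funchill fixtures --name example2 -o fx/
funchill diversity  --abundance fx/example2_abundance.csv --distance fx/example2_caseI.csv --q 0,1,2
funchill similarity --abundance fx/example2_abundance.csv --distance fx/example2_caseII.csv --class local --q 0,1,2
funchill validate   --distance fx/example2_caseII.csv --ultrametric
```

the last of which reports `ultrametric: no` with the violating species
triples.  `funchill gower` builds a distance matrix from a mixed
quantitative/categorical trait table, and `funchill profile` writes
plot-ready diversity profiles over a *q* grid.

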