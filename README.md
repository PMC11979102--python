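# quarnet

Reconstruction of binary, triangle-free, semi-directed **level-1 phylogenetic
networks** from dense sets of weighted four-leaf networks (*tf-quarnets*), with
a fast distance-based heuristic to infer such quarnet sets directly from
multiple sequence alignments, plus the simulation machinery (random network
generator, quarnet perturbation, K2P sequence simulation along displayed
trees) used to validate the method.

A tf-quarnet is either a **quartet tree** (one nontrivial split) or a
**4-cycle** (a cyclic ordering of the four leaves plus the leaf below the
reticulation).  A *dense* set contains exactly one tf-quarnet per 4-subset of
the taxa.  Reconstruction proceeds in three stages:

1. **Candidate blobtrees** — the most-refined tree fully confirmed by the
   input quartet trees is resolved further by a QuartetJoining-style
   agglomeration, then progressively coarsened by contracting the least
   split-supported edges, giving n−3 candidate trees.
2. **Cycle expansion** — every multifurcation is replaced by a cycle: dense
   *representative* quarnets are voted per 4-subset of neighbor components,
   pairwise distances derived from their topologies feed a traveling-salesman
   solver (exact Held–Karp up to 13 components, seeded simulated annealing
   above), and the reticulation is placed by a ranking, backing off until the
   partial network stays rootable.
3. **Scoring** — every candidate network is scored by weighted quarnet
   consistency against the input; the best candidate is returned.

The pipeline is *combinatorially consistent*: applied to the full unit-weight
quarnet set induced by a triangle-free semi-directed level-1 network (with
exact TSP), it returns that network. The test suite verifies this on 200
random networks.

## CLI

```sh
# reconstruct from a quarnet file, rooting at an outgroup
quarnet infer --quarnets data.tfq --outgroup O --seed 1

# reconstruct straight from an alignment (delta-heuristic, lambda = 0.3)
quarnet infer --alignment msa.fasta --outgroup O --tsp auto

# alignment -> dense weighted quarnet set
quarnet quarnets --alignment msa.fasta --out msa.tfq

# simulation fixtures
quarnet simulate network -n 15 --seed 7
quarnet simulate quarnets -n 10 --epsilon 0.5 --seed 7 --out noisy.tfq
quarnet simulate alignment -n 10 -k 10000 --seed 7 --out sim.fasta

# compare two networks (C and S), or a network against quarnets (C')
quarnet score --net a.enwk --net b.enwk
quarnet score --net a.enwk --quarnets data.tfq
```

Networks are written as eNewick (`#H` hybrid tags); rooted at the outgroup if
one is given, otherwise at an arbitrary valid edge.

### Quarnet text format

One record per 4-subset, whitespace-separated, `#` comments, and a
`taxa: ...` header:

```
taxa: a b c d e
T a b c d a,b|c,d 1.0        # quartet tree ab|cd, weight 1
C a b c e a,b,c,e a 0.571    # 4-cycle (a,b,c,e), reticulation below a
```

The weight column is optional (default 1.0).

## Layout

```
src/quarnet/
  quarnets.py   tf-quarnet values, dense sets, consistency scores, file I/O
  networks.py   semi-directed/rooted networks, restriction, rooting, eNewick
  blobtree.py   candidate blobtree sequence (stages A1-A3)
  cycles.py     representative voting, tau distances, TSP, cycle expansion
  driver.py     end-to-end reconstruction driver
  delta.py      alignment -> weighted tf-quarnets (delta-heuristic)
  simulate.py   random networks, perturbation, K2P alignment simulation
  cli.py        command-line interface
```
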