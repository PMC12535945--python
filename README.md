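# bmlp

Boolean-matrix reachability over metabolic networks, and cost-aware active
learning that recovers masked gene-function annotations (including
isoenzyme / digenic annotations) from auxotrophic-growth experiments.

A metabolic network is a list of directed reactions (reactant set → product
set) gated by gene–reaction boolean rules (OR = isoenzymes, AND = enzyme
complexes). The engine encodes the network as two Boolean matrices and
computes the fixpoint of producible metabolites from a growth medium using
only Boolean ADD / MUL / EQ kernels. On top of that sit:

- an MDL-style compression score and base-2 softmax posterior over a finite
  set of candidate annotation hypotheses;
- an |H| × |T| prediction matrix (hypothesis × knockout-experiment
  phenotype), computed via the engine with mask memoization;
- an expected-cost experiment-selection heuristic (reagent cost plus
  cost-weighted residual entropy of the two outcome branches), version-space
  pruning, and a random-selection baseline;
- a seeded synthetic-GEM generator (layered networks, isoenzyme targets,
  nutrient costs, oracle labeller) so everything is testable offline;
- sample-complexity ratio diagnostics comparing active vs random selection.

## Layout

```
src/bmlp/
  network.py    network model, GPR rules, TSV/BiGG-JSON parsing, encodings
  engine.py     Boolean kernels, transitive closure, fixpoint, naive oracle
  scoring.py    hypotheses, compression / prior / posterior / entropy
  active.py     prediction matrix, selection, learning loops, diagnostics
  synthetic.py  ground-truth gem generator, masking, enumeration, oracle
  cli.py        command-line interface
```

## CLI

```sh
bmlp closure FACTS.pl                      # pathway/2 closure of reaction/2 facts
bmlp reach NETWORK.tsv --medium MEDIUM.txt [--delete GENE ...] [--mask-json H.json]
bmlp predict NETWORK.tsv --medium MEDIUM.txt --essential ESS.txt [--delete GENE ...]
bmlp gen --params PARAMS.yaml --seed 7 --out gemdir/
bmlp learn --gem gemdir/ --strategy active --budget 50 --seed 1 --out rundir/
bmlp simulate --params PARAMS.yaml --gems 20 --repeats 10 --out benchdir/
```

Network TSV: one reaction per line,
`id <TAB> reactants,comma,separated <TAB> products <TAB> rule`, where the
rule grammar is `gene`, `a and b`, `a or b`, parentheses, `""`
(spontaneous) or `?` (masked catalysis). BiGG-style GEM JSON can be
imported programmatically via `bmlp.network.import_bigg_json`.

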