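# drugscout

Predict a drug's biological effects from its chemical structure, and
cross-check the prediction against gene expression.

`drugscout` is for computational pharmacologists and systems biologists who
want a transparent, fully scriptable version of the classic two-arm
drug-effect workflow:

1. **Structure arm** — from a compound's SMILES, predict human metabolites
   with empirical biotransformation rules; run a Tanimoto similarity search
   (fragment fingerprints, threshold T ≥ 0.7) of parent + metabolites against
   a compound–target knowledge base; collect the annotated protein targets of
   every hit ("possible targets"); expand them by their first-step physical
   protein–protein interaction partners; partition the target sets of several
   drugs into **common / similar (pairwise) / unique** classes; and rank
   ontology categories by hypergeometric over-representation,

   p(k) = Σ_{i≥k} C(K,i)·C(N−K,n−i) / C(N,n),

   for overlap k between an n-member query and a K-member category in an
   N-member universe (BH-adjusted p reported alongside).
2. **Expression arm** — from a normalized expression matrix, call
   differentially expressed genes per drug with a conservative cascade
   (per-gene Student's t-test p < 0.01, BH FDR < 5%, t-test p < 0.01,
   |log2 ratio| ≥ 1.1 i.e. ≥ 2.1-fold), then run the same enrichment on the
   DEG lists.
3. **Concordance** — because the two arms share no inputs, agreement between
   their category rankings (top-k Jaccard, Spearman ρ over shared categories,
   categories significant in both) is independent evidence for a predicted
   effect.

A seeded synthetic-study generator produces every input the pipeline needs —
compound libraries with planted similarity clusters, target blocks, a PPI
graph, ontologies with a planted category, expression matrices with planted
DEGs — together with ground-truth files, so the whole pipeline is testable
end to end without any proprietary database.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Predict metabolites of fenofibrate with the shipped rules:

```
$ drugscout metabolize --smiles "CC(C)OC(=O)C(C)(C)Oc1ccc(cc1)C(=O)c1ccc(Cl)cc1" --id fenofibrate
CC(C)(Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1)C(=O)O	fenofibrate::M01	ester_hydrolysis
CC(C)O	fenofibrate::M02	ester_hydrolysis
CC(C)OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)c(O)c2)cc1	fenofibrate::M03	aromatic_hydroxylation
...
```

The first product of ester hydrolysis is fenofibric acid — fenofibrate's
known active metabolite.

Generate a synthetic three-drug study (drugs DRG1 and DRG2 are planted in one
structural cluster, DRG3 in another) and run the full pipeline:

```
$ drugscout fixtures --out-dir demo --seed 17
$ drugscout run --config demo/config.json --out-dir demo_run
$ cat demo_run/partition_targets.json
{
  "common": 35,
  "similar": {"DRG1|DRG2": 62, "DRG1|DRG3": 0, "DRG2|DRG3": 0},
  "unique": {"DRG1": 0, "DRG2": 0, "DRG3": 58},
  "multi": {}
}
```

The partition recovers the planted structure: the two cluster-mates share 62
expanded targets with each other and none exclusively with the outlier drug.
The structure arm's enrichment for DRG1 puts the planted category first:

```
category          N    K   n   k   p_value   p_adjusted  rank
PLANTED_RESPONSE  197  10  67  10  1.3e-05   2.6e-04     1
CAT_004           197  12  67   7  6.7e-02   6.7e-01     2
```

and the concordance report for DRG1
(`demo_run/concordance_DRG1_ontology.json`) shows the two arms agreeing:
top-10 Jaccard 0.538, Spearman ρ 0.532 over 20 shared categories, with
`PLANTED_RESPONSE` significant in both arms — the planted effect is
recovered independently by structure and by expression.

Every run writes a `manifest.json` (input hashes, parameters, seed, version);
identical config and inputs reproduce byte-identical outputs.

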