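# contactfold

Residue–residue contact maps under parameterized definitions, pair
similarity by the fraction of common contacts (FCC), and fold-retrieval
evaluation with fold-averaged ROC/AUC — plus a synthetic
structure/alignment generator so the whole pipeline is testable without
downloads.

## What it does

- **Contact maps** from PDB coordinates under any (base, cutoff)
  definition: Cα, Cβ (Cα substituted for glycine), or minimum heavy-atom
  distance; 15 canonical cutoffs from 4.5 to 100 Å; contacts only between
  residues at least 3 apart in sequence. Occupancy and
  sequence-separation binning (5–10, 11–23, >23) included.
- **FCC scoring**: a query contact is *common* when its two residues are
  aligned to template residues that are also in contact; FCC = (query
  residues in ≥1 common contact) / (aligned residues). Optional ±1
  relaxed matching of template contacts.
- **Alignments**: aligned-FASTA and TM-align text readers; sensitivity of
  a test alignment against a gold standard, exact or within ±k residues.
- **Retrieval evaluation**: per-fold positives (within-fold pairs) vs
  negatives (fold representative vs foreign structures), ROC with
  Mann–Whitney tie handling, pointwise TPR averaging across folds,
  per-fold best-definition counting (AUC ≥ 0.7 filter, ties all count),
  occupancy–AUC profiles and best-TM-score-by-rank curves.
- **Synthetic data**: ideal helices, pleated antiparallel sheets, fold
  families with coordinate noise and loop indels, gold alignments, and
  threading-like corrupted alignments with block shifts.

## CLI

```sh
contactfold synth --seed 7 --out bench            # synthetic benchmark
contactfold build-maps --data bench               # contact-map TSVs
contactfold evaluate --data bench                 # AUC/ROC/report TSVs
contactfold fcc --maps-dir bench/maps/CB_6.5 \
    --align-dir bench/alignments --pairs pairs.tsv --out scores.tsv
```

All subcommands accept `--config cfg.yaml` (keys mirror
`contactfold.cli.ExperimentConfig`; flags override). Reports are plain
TSV; a fixed config and seed reproduce them byte for byte.

## Layout

| module                    | contents                                          |
|---------------------------|---------------------------------------------------|
| `contactfold.structure_io`| PDB chain reader/writer, per-residue contact bases|
| `contactfold.contact_maps`| definitions, map construction, occupancy, binning |
| `contactfold.alignments`  | pairwise alignments, readers, sensitivity         |
| `contactfold.fcc`         | common contacts, FCC, batch scoring               |
| `contactfold.retrieval`   | pair sets, ROC/AUC, fold averaging, reports       |
| `contactfold.synthetic`   | helices, sheets, fold families, corruption        |
| `contactfold.cli`         | `contactfold` command-line workbench              |
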