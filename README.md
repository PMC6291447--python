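# sasdiag

Structural annotation and rule-based effect diagnosis of single amino
acid substitutions (SAS) on protein structures.

Most missense-variant predictors return a pathogenicity score without
saying *why* a substitution should be damaging. When crystal structures
of the protein exist, the reason is often readable directly from the
structure: the residue touches a ligand or a catalytic site, sits in a
protein–protein interface, or is packed in the hydrophobic core where a
destabilising substitution prevents folding. `sasdiag` computes those
per-residue structural labels, combines them with a folding
free-energy change and sequence-level propensities, and classifies each
variant with a transparent nine-label decision tree — for clinicians,
biochemists and geneticists who need an interpretable call rather than a
black-box score.

## The method

For every crystal form of the target protein, each residue is labelled:

* **Exposure** — sidechain solvent-accessible surface area
  (Shrake–Rupley, probe 1.4 Å, 960 deterministic sphere points per atom)
  as a percentage of the residue type's maximal sidechain SASA;
  strictly above 50 % is *exposed*, otherwise *buried*. Glycine has no
  sidechain and is never partitioned.
* **Interface** — a heavy atom strictly closer than 5 Å to a heavy atom
  of another polymer chain.
* **Binding** — contact (< 5 Å) with a non-solvent ligand, plus every
  residue of any pocket with druggability > 0.5 and/or a ligand inside.
* **Catalytic** — membership in a catalytic-site catalog.
* **ΔΔG** — folding free-energy change (mutant − wild type, kcal/mol),
  ingested from empirical force-field output; strictly more than
  2 kcal/mol is a *high ΔΔG variation*.
* **Aggregation / switch propensity** — per-residue sequence scores,
  ingested from external predictor files or computed by documented
  surrogates.

Variants (one-letter `G12V`, HGVS `p.Gly12Val`, or curated/clinical
tables) are mapped onto author-numbered residues by global sequence
alignment. The decision tree then reads the flag vector left to right —
active site (binding ∪ catalytic), interface, buried, high
aggregation/switch propensity — with the ΔΔG tier choosing between
"Disrupt …" and "Potential disruption …"; no flag and low ΔΔG gives
"Likely non pathogenic mutation". Across crystal forms the flags are
OR-combined (a label earned in any crystal is kept) and ΔΔG is reduced
to the most destabilising value.

## Worked example

`examples/02_diagnose_variants.py` generates two crystal forms of a
synthetic protein (one GNP-bound, one apo), four variants and their
ΔΔG table, and runs the full pipeline:

```
structures analysed:
  demo_holo  resolution 1.8 Å  ligands: GNP
  demo_apo  resolution 2.3 Å  ligands: -

variant  ddG    label                              category
A10V      3.0  Disrupt protein function           Active site + Binding
A22V      3.0  Disrupt protein interface          Protein-protein interaction
A30V      3.0  Disrupt protein folding            Folding
A5V       0.1  Likely non pathogenic mutation     None
```

A10V touches the ligand only in the holo crystal, yet keeps the
active-site call after aggregation; A22V sits in the chain A/B contact
patch; A30V is a sealed core residue whose destabilisation prevents
folding; A5V is an exposed surface residue with negligible ΔΔG. The
other scripts in `examples/` demonstrate per-residue annotation,
conservation/propensity scoring, and ΔΔG ingestion.

A thin CLI wraps the same library:

```sh
sasdiag fixtures --out demo          # write the synthetic input suite
sasdiag annotate demo/demo_holo.pdb --out holo.tsv
sasdiag diagnose --ref-seq demo/demo_ref_seq.fasta \
    --structure demo/demo_holo.pdb --structure demo/demo_apo.pdb \
    --variants demo/demo_variants.tsv \
    --foldx demo_holo demo/demo_holo.dif.fxout \
    --foldx demo_apo demo/demo_apo.dif.fxout --out run/
```

## Layout

```
src/sasdiag/        structure_io, residue_annotation, sequence_scores,
                    stability, diagnosis, fixtures, tables, cli
tests/              unit + property + acceptance tests
examples/           one narrative script per capability
docs/methods.md     model, parameters, surrogates, limitations
```
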