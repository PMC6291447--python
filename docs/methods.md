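# Methods

## Scope and model

`sasdiag` diagnoses the structural effect of single amino acid
substitutions (SAS). It does not predict a pathogenicity probability;
it assembles per-residue structural evidence into a boolean flag vector
and classifies it with a fixed decision table. The underlying
assumptions are the standard ones of structure-based variant analysis:
the crystal conformations on hand are representative of the functional
states; a residue's role (catalysis, binding, interface, core packing)
is legible from geometry; and strong destabilisation of the fold
(ΔΔG > 2 kcal/mol) is damaging regardless of mechanism.

External programs are ingested, never re-implemented: folding
free-energy changes come from empirical force-field output files,
pockets from pocket-detection output, catalytic residues from a curated
catalog, and aggregation/switch scores from per-residue predictor files
when available. The package's own computations are the geometry
(SASA, contacts, interfaces), the sequence surrogates, the conservation
measure, and the diagnosis logic.

## Structure handling

PDB files are parsed with author residue numbering and insertion codes
kept verbatim. Het-groups are classified as polymer (the 20 standard
amino acids), solvent (a configurable code list; water, common buffers
and cryoprotectants, and monoatomic ions by default), or ligand
(everything else, including unknown codes — an unrecognised compound
should still be able to confer binding labels). Modified residues
recorded as HETATM are treated as ligands in this version.

Candidate structures are filtered and ranked as a protein-wide set:
candidates covering fewer than 20 reference residues are dropped;
survivors are ranked by coverage (descending) then resolution
(ascending). Candidates with the same covered segment are all kept when
their ligand sets or protein partners differ — liganded, apo and
complexed forms carry different information — but exact duplicates
(same segment, ligands and partners) collapse to the best-resolution
one.

Variants are numbered on a reference sequence, so each chain is mapped
by global pairwise alignment (match +1, mismatch −1, gap open −5, gap
extend −1; Needleman–Wunsch via Biopython). Gapped columns stay
unmapped; an identity below 0.95 (configurable) is an error rather than
a silent mis-mapping.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-section-spiral point lattice
(default 960 points per atom, probe 1.4 Å, Bondi-style radii from a
bundled table; unknown elements are a configuration error). There is no
RNG anywhere in the geometry path, so results are bit-identical across
runs. Solvent molecules are stripped before the computation; polymer
and ligand heavy atoms contribute. Neighbour search uses a k-d tree but
is contractually identical to the all-pairs rule, which the tests
enforce.

Sidechain exposure is the residue's in-context sidechain SASA divided
by a per-residue-type maximal sidechain SASA (extended Gly-X-Gly
reference, bundled), capped at 100 %. The paper-style rule is strict:
exposure > 50 % ⇒ exposed, otherwise buried. Glycine has no sidechain
and is reported as undefined, never buried nor exposed — the diagnosis
therefore can never reach the folding row through a glycine's burial.

The 960-point default keeps the total within a small fraction of a
percent of a 10,000-point evaluation on the synthetic structures used
here (measured by the acceptance script), far inside the 2 % the tests
require.

## Contacts, pockets, catalytic and informational labels

* Interface: heavy-atom pair across two polymer chains strictly closer
  than 5 Å; both partners are labelled. Hydrogens are ignored for
  reproducibility across structures solved with and without them.
* Ligand contact: heavy atom strictly closer than 5 Å to a ligand-kind
  heavy atom. The distance is not fixed by the published rule set; 5 Å
  is chosen for symmetry with the interface rule and is configurable.
* Binding: ligand contacts plus all residues of every pocket with
  druggability strictly above 0.5 and/or a ligand inside the pocket
  envelope, even pocket members not touching the ligand.
* Catalytic: catalog rows matched against the structure; rows naming
  absent residues are reported, not dropped silently.
* Domain-interface (3did-style) lists set an informational flag only:
  they never set the geometric interface flag and never enter the
  decision tree.
* Relative B-factor: residue mean heavy-atom B over the protein-wide
  median of per-residue means; informational only. An all-zero column
  degenerates to the neutral ratio 1.0.

## Sequence scores

Conservation is the sequence-logo letter height: for the column
assigned to a reference position, `p(wt) × IC` with
`IC = log2 20 − H` over gap-free frequencies, no small-sample
correction. Positions outside the family-assigned region are reported
as not-assigned (`None`), not zero. It is informational in the report
and does not gate any decision row.

The aggregation surrogate scores each residue as the maximum over
length-5 windows containing it of the window mean of a bundled 0–1
propensity scale (hydrophobicity blended with β-sheet preference). The
mutation flag compares mutant and wild-type profiles at the site with a
strict delta threshold of 0.2. A consequence worth knowing: with a
max-of-means profile every window containing the site shifts by exactly
Δscale/window, so on a 0–1 scale with window 5 the site delta never
exceeds 0.2 and the default threshold can only be crossed via external
score files, a custom scale, or a narrower window. The defaults are
kept as stated configuration; users with a real aggregation predictor
should supply its per-residue output, which is the first-class path.

The switch surrogate flags helix-to-sheet-prone substitutions: over the
window centred on the site, the wild-type context must favour helix
(mean Chou–Fasman helix propensity above sheet propensity) and the
mutation must raise the window's sheet-minus-helix balance by strictly
more than 0.2. An external file of switch-prone positions overrides the
surrogate entirely. Both surrogates are pure functions of (sequence,
tables, thresholds) and the report records which source produced each
score.

## Stability

ΔΔG = mutant − wild-type folding free energy, kcal/mol. Two ingestion
dialects: a difference table (one row per mutation tag, energy in the
first numeric column) and paired per-structure energy files. The high
flag is strict: ΔΔG > 2 kcal/mol. There is deliberately no built-in
ΔΔG estimator — inventing an uncitable surrogate force field would be
worse than requiring the input — so variants without any ΔΔG are
diagnosed on the low-ΔΔG ("Potential …") tier and carry an explicit
`stability-unknown` caveat.

## Diagnosis

The decision table is evaluated left to right: active site
(binding ∪ catalytic) → interface → buried → high aggregation or
switch propensity; the ΔΔG tier selects "Disrupt …" versus "Potential
disruption …", and an all-false vector with low ΔΔG is "Likely non
pathogenic mutation". Two genuinely open points were resolved as
follows:

* The structure-disruption row fires on *either* high aggregability or
  high switchability, and the non-pathogenic row requires both false.
* A high-ΔΔG variant with no positional or sequence flag is labelled
  "Disrupt protein folding": destabilisation that strong prevents
  folding wherever the residue sits, which keeps the table total over
  the flag space and matches the folding-tier diagnostic meaning.

Labels map to effect categories — function → "Active site + Binding",
interface → "Protein-protein interaction", folding and structure →
"Folding", non-pathogenic → "None" — and the fired row index is
reported. Localisation effects have no structural signal in this
framework and are not emitted.

Aggregation across crystal forms OR-combines the boolean flags (the
published convention: an active-site call in one crystal stands even if
other crystals are apo) and reduces ΔΔG to the maximum — the most
destabilising pose — with `mean` and `min` available; all per-structure
values and per-flag provenance stay in the report so conflicting
crystal forms can be weighed by the user.

## Synthetic fixtures

The generators build idealised chains: rigid five-atom residue
templates (N, CA, C, O, CB; glycine without CB) spaced 3.8 Å along the
x axis, with chain separations, contact patches, planted ligands and a
sealing atom shell controlling each label exactly. Interface ground
truth is derived analytically from the template offsets, independently
of the neighbour-search code. The four-variant demo plants one variant
per outcome class across a holo and an apo crystal form.

What the fixtures deliberately do not emulate: real backbone dihedrals
and sidechain rotamers, crystallographic disorder (altlocs, partial
occupancy), hydrogens, or realistic packing densities. Passing tests
therefore certify the *rules* — thresholds, strictness, set semantics,
aggregation, determinism — on exact geometry, not the biological
accuracy of any one annotation on a real crystal; on real structures
the fidelity of inputs (ΔΔG runs, pocket detection, alignments)
dominates.

## Numerical choices and edge cases

* All thresholds are strict inequalities, matching the published
  wording ("more than", "less than", "greater than"); boundary values
  (ΔΔG 2.0, exposure 50.0 %, distance 5.0 Å, druggability 0.5) never
  qualify. Coverage is inclusive ("at least 20").
* Exposure is capped at 100 % (an isolated sidechain can exceed the
  tripeptide reference).
* Sphere points, window means and alignments are deterministic;
  pipeline reruns produce byte-identical reports.
* Structure selection ties (equal coverage and resolution) break on
  structure id for determinism; unknown resolutions sort last.
* Variant-table rows that fail to parse are collected with their line
  numbers and returned alongside the parsed variants.

## Problem sizes

The bundled demo analyses two crystal forms of ~560 heavy atoms each;
the oracle-equivalence checks run 100 random 50+50-residue dimers; the
SASA convergence check compares 960 against 10,000 points on one such
dimer; aggregation semantics are sampled over 1,000 random flag
groups. These sizes make the whole suite and the acceptance script run
in well under a minute while exercising every rule at its boundary.

## Known limitations

* PDB input only in this version; mmCIF belongs behind the same reader
  interface later. First model only for multi-model files.
* Modified polymer residues (e.g. selenomethionine) are classed as
  ligands, which can create spurious binding labels on their
  neighbours; curate such structures or extend the polymer table.
* The exposure denominator and ligand-contact distance are conventions
  (documented above), not published constants.
* The aggregation/switch surrogates are deliberately simple local
  propensity measures for pipeline testability; for real analyses use
  the external-file ingestion path with a dedicated predictor.
* Conservation and relative B-factor are informational; they gate no
  decision row.
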