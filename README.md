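# ptmgraft

Graft common post-translational modifications (PTMs) onto existing
protein/peptide structures in PDB format.

Ten modification classes are supported — acetylation, carbamylation,
citrullination, cysteine oxidation, malondialdehyde (MDA) adducts,
methionine oxidation, methylation, nitration, proline hydroxylation and
phosphorylation — with:

- **per-atom solvent-accessibility pre-selection**: Shrake–Rupley
  accessible surface area on a deterministic Fibonacci lattice, with an
  Å² cutoff applied to each modification's target atom (e.g. the lysine
  ε-amine NZ);
- **stereochemical variant control**: R/S diastereomers for methionine
  sulfoxide, cysteine-S-dioxide and the FAAB malondialdehyde fragment,
  4R (default) / 4S hydroxyproline, verified by signed-volume
  chirality assignment with catalog-declared CIP priorities;
- **local van-der-Waals strain minimization**: quadratic-overlap strain
  scored per residue, minimized by exhaustive torsion grid scans
  (levels 1–4 trade torsion count and step size for cost), with an
  optional baseline probe that skips scanning when grafting added no
  strain. Alternative placements — the two nitrotyrosine ortho
  positions, R/S "racemic choice" — are built and the lower-strain one
  kept.

Modified residues are renamed to chemical-component-dictionary codes
where they exist (ALY, CIR, CSO/CSD/OCS, SME, MLZ/MLY/M3L, NIY, HYP,
SEP/TPO/PTR) and to documented bespoke codes otherwise (HCL for
homocitrulline; MM1/MM2/MM3 for the MAA ring, FAAB and N-propenal MDA
adducts). Provenance is carried in `REMARK 999` lines and a JSON
sidecar report.

## Layout

| module | role |
| --- | --- |
| `structure_io` | PDB v3.3 read/write, bond inference, selection mini-language |
| `geometry_core` | NeRF atom placement, torsion measurement/rotation, R/S assignment |
| `ptm_catalog` | declarative recipes for all classes/variants (`data/catalog.yaml`) |
| `surface_selection` | per-atom Shrake–Rupley SASA + cutoff filter |
| `strain_optimizer` | clash enumeration, strain scoring, torsion-grid minimization |
| `modifier_engine` | candidate discovery → grafting → renaming → reporting |
| `fixtures` | deterministic ideal-geometry peptides and occlusion cages for tests |
| `cli` | the `ptmgraft` command |

## CLI

```sh
# list classes, variants and defaults
ptmgraft --list-ptms

# nitrate all tyrosines
ptmgraft --in model.pdb --ptm nitration --out model_niy.pdb

# MAA adducts on surface-exposed lysine amines, with optimization
ptmgraft --in bsa.pdb --ptm mda_adduct --surface-cutoff 25 --optimize 3 \
         --out bsa_maa.pdb --report bsa_maa.json

# restrict by selection; force the other nitro ortho position
ptmgraft --in model.pdb --ptm nitration --select "chain A and resi 190-210" \
         --position 2 --out out.pdb

# clash report only, no modification
ptmgraft --in model.pdb --clashes-only
```

Exit codes: 0 success, 1 processing error, 2 usage error. Runs are
deterministic: identical inputs and flags give byte-identical outputs,
and the input file is never touched.

Library use mirrors the CLI:

```python
from ptmgraft import ModificationOptions, modify, read_pdb, write_pdb

s = read_pdb("bsa.pdb")
report = modify(s, ModificationOptions(
    ptm_class="mda_adduct", surface_cutoff=25.0, optimization_level=3))
write_pdb(s, "bsa_maa.pdb")
print(report.totals())
```

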