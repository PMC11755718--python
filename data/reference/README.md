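# Reference data (fetched, not bundled)

This directory holds published reference inputs used by the
reference-number tests in `tests/test_acceptance.py`:

- `4rhw.pdb` — PDB entry 4RHW (Apaf-1 CARD / caspase-9 CARD assembly),
  used for the type I / type II buried-interface areas.
- `c9card.fasta`, `rdcard.fasta` — caspase-9 CARD (4RHW chain E) and RAIDD
  CARD (3CRD chain A) sequences, used for the global-alignment identity.
- `zenodo/native_md{1,2,3}.pdb` — optional: deposited MD trajectories
  (Zenodo record 13736242) converted to multi-model PDB, used for the
  trajectory RMSD checks.

Populate with `python scripts/fetch_reference.py` (network required; the
Zenodo tier is a manual download). Nothing here is redistributed with the
package.
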