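# Deposited coordinate files

Place PDB-format coordinate files for the deposited crystal structures here
to enable the structure-dependent acceptance tests and targets:

- `8AHS.pdb` — hCaM–melittin complex
- `8AHT.pdb` — pfCaM–melittin complexes (4 copies in the asymmetric unit)

For example:

```sh
curl -O https://files.rcsb.org/download/8AHS.pdb
curl -O https://files.rcsb.org/download/8AHT.pdb
```

This directory ships empty because the build environment has no access to
the PDB.
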