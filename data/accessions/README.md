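# Deposited coordinate files

The accession-dependent tests in `tests/test_acceptance.py` analyse deposited
crystal structures (9ibe, 8qzb, 8qza, 7q3x, 1doi and related entries).  The
coordinate files are multi-megabyte and are not distributed with the package;
place them here as `<id>.cif` (or `.pdb`), e.g. via

    python scripts/fetch_accessions.py

which downloads them from the PDB (network required).  Without the files
those tests fail with a message naming the missing accession.
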