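# Deposited coordinate files

The printed-value tests in `tests/test_acceptance.py` reproduce published
interface metrics for two deposited hIAPP spine structures.  Place the
published PDB entries here as:

    data/deposited/5KNZ.pdb   # hIAPP 19-29 S20G spine segment
    data/deposited/5KO0.pdb   # hIAPP 15-25 WT spine segment

for example with:

    curl -o data/deposited/5KNZ.pdb https://files.rcsb.org/download/5KNZ.pdb
    curl -o data/deposited/5KO0.pdb https://files.rcsb.org/download/5KO0.pdb

These files are not distributed with the package; without them the
printed-value tests fail with a message pointing here, and the rest of
the suite is unaffected.
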