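Reference coordinate files for the Glt_Ph comparisons are not
redistributed with the package. Download them once:

    curl -O https://files.rcsb.org/download/3KBC.pdb
    curl -O https://files.rcsb.org/download/1XFH.pdb

into this directory. The crystal-structure tests in
tests/test_acceptance.py and the optional quantities in
scripts/acceptance.py pick them up automatically.
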