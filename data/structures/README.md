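Deposited coordinate files (7qb9/7qa8/7qbc/7qbi/7ad3 as .pdb) go here.
They are not redistributed; fetch them with:

    python scripts/fetch_structures.py
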