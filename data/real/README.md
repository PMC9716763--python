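# Real annotated mitogenomes (user-supplied)

Place GenBank flat files for the deposited accessions here, one per file,
named `<accession>.gb` (e.g. `ON861815.gb`). No network fetch is performed
by the package; download the records yourself, e.g. with NCBI efetch:

    efetch -db nuccore -id ON861815 -format gb > data/real/ON861815.gb

`tests/test_acceptance.py::test_real_accession_reproduction` uses
ON861815, ON861817, ON861819, ON861821 and ON861823 to check genome
lengths, AT% and the published IGS-I lengths against the pipeline.
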