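# data/

Placeholder for the deposited 17-allele exon-2 FASTA
(`deposited_exon2.fasta`, GenBank accessions HQ902164–HQ902180).

The file is not shipped (it requires a network fetch). Populate it once
with:

    python scripts/fetch_deposited.py --email you@example.org

With the file present, the deposited-data acceptance tests in
`tests/test_acceptance.py` and targets t1–t8/t10 of
`scripts/acceptance.py` run; without it they fail / are omitted with an
explanatory message.
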