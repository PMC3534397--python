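# Worked FCC example inputs

`scripts/acceptance.py` and the `external_data` tests in
`tests/test_acceptance.py` consume three PDB domain pairs from this
directory.  The coordinates and alignments are real experimental data
that cannot be regenerated offline, so they are not shipped; to prepare
them you need network access and a TM-align binary
(`micromamba install -c bioconda tmalign` or an equivalent build).

For each pair create a directory

    data/fcc_pairs/<queryid>__<templateid>/
        query.pdb       # the query domain (single chain, ATOM records)
        template.pdb    # the template domain
        alignment.afa   # TM-align alignment of query vs template,
                        # converted to two-record aligned FASTA

The three pairs (ids end in the chain letter; extract the SCOP 1.73
domain extents of each chain):

| directory        | query         | template      |
|------------------|---------------|---------------|
| `1xsiC__2c8nA`   | 1xsi chain C  | 2c8n chain A  |
| `1amxA__1ayoA`   | 1amx chain A  | 1ayo chain A  |
| `1uc8B__1auvA`   | 1uc8 chain B  | 1auv chain A  |

Recipe per pair:

```sh
curl -O https://files.rcsb.org/download/1XSI.pdb   # and the partner entry
# carve the chain/domain, e.g. with pdb-tools or a few lines of biotite
TMalign query.pdb template.pdb > tmalign.txt
# the three-line alignment block of tmalign.txt is read directly:
python -c "
from contactfold import read_alignment, write_alignment_fasta
a = read_alignment('tmalign.txt', format='tmalign', query_id='1xsiC', template_id='2c8nA')
write_alignment_fasta(a, 'alignment.afa')
"
```
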