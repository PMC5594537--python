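# Supplementary sequence data (user-supplied)

Two acceptance tests compare against the original study's supplementary
sequences, which are not redistributable here. To run them, add:

- `loci/<locus>.fasta` — one aligned FASTA per pre-miRNA locus with the ten
  Oryza rows (e.g. `loci/premir172d.fasta`); and
- `mir1861_clusters.fasta` — the nine rice miR1861 cluster sequences.

Until these files exist the corresponding tests fail with a message naming
the missing path.
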