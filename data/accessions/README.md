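# Accession FASTA drop-in directory

Place `MZ476247.fasta` and `MZ476248.fasta` (the yak MMP-2 / MMP-9 coding
sequences from GenBank) here to enable the accession-based acceptance
checks. They are not redistributed with the package and cannot be fetched
in offline environments. See the top-level README for an `efetch` recipe.
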