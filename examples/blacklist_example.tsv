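# Example artifact blacklist for `panelseq triage --blacklist`.
# One normalized variant key per row (chrom:pos:ref>alt, left-aligned,
# shared prefix/suffix trimmed). The shipped default blacklist is empty:
# recurrent aligner/caller artifacts are site-specific and must be curated
# per laboratory from recurrently miscalled positions. The key below is a
# synthetic placeholder, not a real artifact.
key
chr_DEMO:123:CA>C
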