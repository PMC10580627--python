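# sha256 manifest for packaged worked-example resources
f2af6305b690d7e492893a0c94466733d2e5b810fd9881c32559142be823a5c9  a37_modules.gmt
a8d573b8d9836b435b1b25011f67294cfbc616fa38de77b0b27db5ccd8e45a04  example_sentences.txt
c4cfd6cffca150b0659f1d1c2bfbe70bb5a6f3eaa455c28389e091ca84b55298  gpx4_record.txt
765393813769754e4383b92ea35042180e7e7933588dd5024e59c0263f0f5e8d  pmid_lookup_synthetic.tsv
f26fed1f33a444eb19beed6733f322d977afc31ae452b5451ff246fbb0716416  prompts.yaml
9b7e28d1de8c5476eb28bc8124fb84e715bef62eb0a478f3fa0b42478c3800a1  selection_transcripts.yaml
f317f52232fa7b64d0186659b3bbf99b333176c61c047ad92c7f698ce4d932b1  step5_summaries.yaml
7b72c715957058e349cfac9eebee0cb244ac5892dea1187900928b5a9f47901c  theme_table.yaml
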