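In Human Whole blood, RNA sequencing detected BCL2L1 RNA at a count of 280
In Human Basophils, Microarrays detected BCL2L1 RNA at a signal intensity unit of 267
In Human Whole blood, the abundance of BCL2L1 RNA measured by Microarrays differed in patients with acute influenza infection compared to controls by a Log2 fold change of -0.3697682
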