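organism_id	superkingdom	phylum	genome_size_mb	gc_percent	habitat	oxygen	temperature
orgA	Bacteria	Proteobacteria	3.0	30.0	aquatic	aerobic	mesophile
orgB	Bacteria	Firmicutes	5.0	50.0	terrestrial	anaerobic	mesophile
orgC	Bacteria	Proteobacteria	4.0	50.0	multiple	facultative	mesophile
orgD	Archaea	Euryarchaeota	2.0	50.0	specialized	anaerobic	thermophile
orgE	Archaea	Crenarchaeota	2.5	70.0	aquatic	anaerobic	hyperthermophile
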