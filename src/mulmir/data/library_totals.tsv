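tissue	raw_reads	clean_reads
leaf	11752747	10992174
bark	11491921	11273911
male_flower	10513612	10134148
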