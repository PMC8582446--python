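type	chrom	start	end
amp	chr3	174000002	198022430
amp	chr8	125000002	146364022
amp	chr12	24000002	27000000
amp	chr19	31000002	59128983
del	chr9	1	27000000
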