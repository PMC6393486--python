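# Saccharomyces cerevisiae 16-chromosome reference layout (R64-style lengths,
# centromere midpoints) with the rDNA array interval on chrXII.
# columns: chrom	length	centromere_mid	rdna_start	rdna_end
chrI	230218	151523
chrII	813184	238265
chrIII	316620	114443
chrIV	1531933	449766
chrV	576874	152045
chrVI	270161	148568
chrVII	1090940	496979
chrVIII	562643	105644
chrIX	439888	355687
chrX	745751	436366
chrXI	666816	440187
chrXII	1078177	150887	451000	471000
chrXIII	924431	268090
chrXIV	784333	628816
chrXV	1091291	326643
chrXVI	948066	556015
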