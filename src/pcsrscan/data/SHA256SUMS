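e8e7e5c9fe8de667ffd8b2e1a19cdf09445faa0b05a0528610baaa1cc8f4ca47  common_mrnas.tsv
68113fa7addb4f7ccee37e82c4fccef55daf6a55e35b68859078e3c2035d3a4c  common_mirnas.tsv
619156ece77803e00145708350a36e089f42ed3b5ead8c96f874f0a371e92746  ddx5_edges.tsv
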