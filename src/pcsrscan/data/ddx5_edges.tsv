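source	effect	target
hsa-mir-20b	negative	DDX5
hsa-mir-141	negative	DDX5
DDX5	regulation	hsa-mir-21
DDX5	regulation	hsa-mir-182
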