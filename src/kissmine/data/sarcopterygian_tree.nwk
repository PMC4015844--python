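(amphibian,(mammal,(squamate,(chelonian,(crocodilian,bird)archosauria)archelosauria)sauropsida)amniota)tetrapoda;
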