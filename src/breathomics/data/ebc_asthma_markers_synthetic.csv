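name,class,monoisotopic_mass_da,polarity_hint
9-amino-nonanoic acid,omega-amino fatty acids,173.140476,negative
12-amino-dodecanoic acid,omega-amino fatty acids,215.189689,positive
lactone of PGF-MUM,prostaglandins,296.161576,negative
N-linoleoyl taurine,N-acyl amides,387.247273,positive
17-phenoxy trinor PGF2alpha ethyl amide,prostaglandins,431.273873,positive
"lysoPC(18:2(9Z,12Z))",mono glycerophospholipids,536.353473,positive
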