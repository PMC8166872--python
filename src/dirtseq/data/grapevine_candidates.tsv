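trna_id	gene_id	tissue
tRNA-Phe-GAA-1-4	VIT_07s0005g02200	Leaf
tRNA-Ala-AGC-1-7	VIT_14s0066g02600	Leaf
tRNA-Pro-CGG-2-2	VIT_14s0060g01370	Leaf
tRNA-Arg-TCG-2-2	VIT_09s0002g04750	Leaf
tRNA-Gly-GCC-1-1	VIT_02s0154g00160	Leaf
tRNA-Gly-GCC-1-5	VIT_07s0005g02990	Leaf
tRNA-Gly-GCC-1-6	VIT_08s0058g00460	Leaf
tRNA-Val-CAC-1-7	VIT_15s0046g02860	Leaf
tRNA-Asn-GTT-2-2	VIT_18s0001g12620	Leaf
tRNA-Met-CAT-1-3	VIT_07s0129g00230	Leaf
tRNA-His-GTG-8-1	VIT_17s0000g06990	Leaf and Berry
tRNA-Gly-TCC-1-6	VIT_13s0064g00200	Leaf and Berry
tRNA-Thr-AGT-1-4	VIT_00s0322g00020	Leaf and Berry
tRNA-Ile-AAT-3-1	VIT_04s0023g03700	Leaf and Berry
tRNA-Pro-TGG-2-9	VIT_18s0001g09050	Leaf and Berry
tRNA-Phe-GAA-1-4	VIT_07s0005g02210	Leaf and Berry
tRNA-Leu-TAA-2-3	VIT_08s0007g03950	Berry
tRNA-Gly-CCC-1-3	VIT_19s0177g00220	Berry
tRNA-Thr-AGT-2-1	VIT_05s0077g01490	Berry
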