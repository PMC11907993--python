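construct_id	series	expected_bmp	expected_tgfb
spacing_a2_b2	spacing	nonresponsive	nonresponsive
spacing_a2_b3	spacing	nonresponsive	nonresponsive
spacing_a2_b4	spacing	nonresponsive	nonresponsive
spacing_a2_b5	spacing	BMP_responsive	nonresponsive
spacing_a2_b6	spacing	nonresponsive	nonresponsive
spacing_a2_b10	spacing	nonresponsive	nonresponsive
spacing_a2_b20	spacing	nonresponsive	nonresponsive
spacing_a3_b2	spacing	nonresponsive	nonresponsive
spacing_a3_b3	spacing	nonresponsive	nonresponsive
spacing_a3_b4	spacing	nonresponsive	nonresponsive
spacing_a3_b5	spacing	BMP_responsive	nonresponsive
spacing_a3_b6	spacing	nonresponsive	nonresponsive
spacing_a3_b10	spacing	nonresponsive	nonresponsive
spacing_a3_b20	spacing	nonresponsive	nonresponsive
spacing_a4_b2	spacing	nonresponsive	nonresponsive
spacing_a4_b3	spacing	nonresponsive	nonresponsive
spacing_a4_b4	spacing	nonresponsive	nonresponsive
spacing_a4_b5	spacing	BMP_responsive	nonresponsive
spacing_a4_b6	spacing	nonresponsive	nonresponsive
spacing_a4_b10	spacing	nonresponsive	nonresponsive
spacing_a4_b20	spacing	nonresponsive	nonresponsive
spacing_a5_b2	spacing	BMP_responsive	nonresponsive
spacing_a5_b3	spacing	BMP_responsive	nonresponsive
spacing_a5_b4	spacing	BMP_responsive	nonresponsive
spacing_a5_b5	spacing	BMP_responsive	nonresponsive
spacing_a5_b6	spacing	BMP_responsive	nonresponsive
spacing_a5_b10	spacing	BMP_responsive	nonresponsive
spacing_a5_b20	spacing	BMP_responsive	nonresponsive
spacing_a6_b2	spacing	nonresponsive	nonresponsive
spacing_a6_b3	spacing	nonresponsive	nonresponsive
spacing_a6_b4	spacing	nonresponsive	nonresponsive
spacing_a6_b5	spacing	BMP_responsive	nonresponsive
spacing_a6_b6	spacing	nonresponsive	nonresponsive
spacing_a6_b10	spacing	nonresponsive	nonresponsive
spacing_a6_b20	spacing	nonresponsive	nonresponsive
spacing_a10_b2	spacing	nonresponsive	nonresponsive
spacing_a10_b3	spacing	nonresponsive	nonresponsive
spacing_a10_b4	spacing	nonresponsive	nonresponsive
spacing_a10_b5	spacing	BMP_responsive	nonresponsive
spacing_a10_b6	spacing	nonresponsive	nonresponsive
spacing_a10_b10	spacing	nonresponsive	nonresponsive
spacing_a10_b20	spacing	nonresponsive	nonresponsive
spacing_a20_b2	spacing	nonresponsive	nonresponsive
spacing_a20_b3	spacing	nonresponsive	nonresponsive
spacing_a20_b4	spacing	nonresponsive	nonresponsive
spacing_a20_b5	spacing	BMP_responsive	nonresponsive
spacing_a20_b6	spacing	nonresponsive	nonresponsive
spacing_a20_b10	spacing	nonresponsive	nonresponsive
spacing_a20_b20	spacing	nonresponsive	nonresponsive
orient_npGC_SBE_FF	orientation	nonresponsive	nonresponsive
orient_npGC_SBE_FR	orientation	nonresponsive	nonresponsive
orient_npGC_SBE_RF	orientation	nonresponsive	nonresponsive
orient_npGC_SBE_RR	orientation	nonresponsive	nonresponsive
orient_SBE_FF	orientation	nonresponsive	nonresponsive
orient_SBE_FR	orientation	nonresponsive	nonresponsive
orient_SBE_RF	orientation	nonresponsive	nonresponsive
orient_SBE_RR	orientation	nonresponsive	nonresponsive
orient_pSBE_FF	orientation	nonresponsive	TGFB_responsive
copy_pGC_x1	copy_number	nonresponsive	nonresponsive
copy_pGC_x2	copy_number	BMP_responsive	nonresponsive
copy_pGC_x3	copy_number	BMP_responsive	nonresponsive
copy_pGC_x4	copy_number	BMP_responsive	nonresponsive
copy_pGC_x5	copy_number	BMP_responsive	nonresponsive
copy_pGC_x6	copy_number	BMP_responsive	nonresponsive
idlinker_ID1	id_linker	BMP_responsive	nonresponsive
idlinker_ID2	id_linker	BMP_responsive	nonresponsive
idlinker_ID3	id_linker	BMP_responsive	nonresponsive
idlinker_CTRL	id_linker	BMP_responsive	nonresponsive
hetero_sense	hetero_orientation	BMP_responsive	nonresponsive
hetero_sbe_antisense	hetero_orientation	nonresponsive	nonresponsive
hetero_full_antisense	hetero_orientation	BMP_responsive_weak	nonresponsive
perm_p1A	permutation	nonresponsive	nonresponsive
perm_p1C	permutation	nonresponsive	nonresponsive
perm_p1T	permutation	nonresponsive	nonresponsive
perm_p2A	permutation	nonresponsive	nonresponsive
perm_p2C	permutation	nonresponsive	nonresponsive
perm_p2T	permutation	nonresponsive	nonresponsive
perm_p3A	permutation	nonresponsive	nonresponsive
perm_p3G	permutation	nonresponsive	nonresponsive
perm_p3T	permutation	nonresponsive	nonresponsive
perm_p4A	permutation	nonresponsive	nonresponsive
perm_p4C	permutation	nonresponsive	nonresponsive
perm_p4T	permutation	nonresponsive	nonresponsive
perm_p5A	permutation	nonresponsive	nonresponsive
perm_p5G	permutation	nonresponsive	nonresponsive
perm_p5T	permutation	nonresponsive	nonresponsive
perm_p6A	permutation	nonresponsive	nonresponsive
perm_p6G	permutation	nonresponsive	nonresponsive
perm_p6T	permutation	nonresponsive	nonresponsive
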