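# CGN labels for the C-terminal alpha5 helix / wavy hook of human G-alpha-i1.
# Columns: chain	seq_number	label	scheme   (chain "*" = any chain).
# Note: published work is inconsistent about H5.24, attaching it variously to
# G352 or L353; the canonical common-G-alpha-numbering assignment for G-alpha-i1
# is C351=H5.23, G352=H5.24, L353=H5.25, F354=H5.26, used here throughout.
*	340	H5.12	CGN
*	341	H5.13	CGN
*	342	H5.14	CGN
*	343	H5.15	CGN
*	344	H5.16	CGN
*	345	H5.17	CGN
*	346	H5.18	CGN
*	347	H5.19	CGN
*	348	H5.20	CGN
*	349	H5.21	CGN
*	350	H5.22	CGN
*	351	H5.23	CGN
*	352	H5.24	CGN
*	353	H5.25	CGN
*	354	H5.26	CGN
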