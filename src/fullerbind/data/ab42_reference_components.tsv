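system	dE_vdw	dE_elec	dE_MM	dG_polar	dG_nonpolar	dG_solv	dG_bind
Abeta42-C60	-24.44	0	-24.44	0	-3.92	-3.92	-28.36
Abeta42-C60(OH)6	-24.02	-5.16	-29.18	15.27	-3.61	11.66	-17.52
Abeta42-C60(OH)12	-18.20	-14.60	-32.80	27.06	-3.30	23.77	-9.03
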