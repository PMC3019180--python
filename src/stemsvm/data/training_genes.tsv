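gene_id	label
Bmp4	MSMG
Cdyl	MSMG
Cdyl2	MSMG
Dmrt1	MSMG
Dppa4	MSMG
Dppa5a	MSMG
Esrrb	MSMG
Etv4	MSMG
Etv5	MSMG
Fgf4	MSMG
Foxd3	MSMG
Foxh1	MSMG
Gbx2	MSMG
Grhl2	MSMG
Jarid2	MSMG
Klf2	MSMG
Klf5	MSMG
Lefty2	MSMG
Lin28	MSMG
Mkrn1	MSMG
Mycn	MSMG
Nanog	MSMG
Nodal	MSMG
Nr0b1	MSMG
Nr5a2	MSMG
Phc1	MSMG
Phf17	MSMG
Pou4f2	MSMG
Pou5f1	MSMG
Rif1	MSMG
Sall1	MSMG
Sall4	MSMG
Sgk1	MSMG
Slc27a2	MSMG
Socs3	MSMG
Sox2	MSMG
Spp1	MSMG
Tcf15	MSMG
Tcfap2c	MSMG
Tcfcp2l1	MSMG
Tcl1	MSMG
Tle4	MSMG
Trp53	MSMG
Utf1	MSMG
Zfp296	MSMG
Zfp42	MSMG
Afp	non-MSMG
Arid3a	non-MSMG
Arid3b	non-MSMG
Ascl1	non-MSMG
Ascl2	non-MSMG
Bat1a	non-MSMG
Bmp2	non-MSMG
Bmp5	non-MSMG
Bmper	non-MSMG
Ccnd2	non-MSMG
Cdh2	non-MSMG
Cebpa	non-MSMG
Cited1	non-MSMG
Dach1	non-MSMG
Dlx1	non-MSMG
Dlx4	non-MSMG
Dlx6	non-MSMG
Ednra	non-MSMG
En1	non-MSMG
Eomes	non-MSMG
Ets2	non-MSMG
Eya2	non-MSMG
Fgf5	non-MSMG
Foxb1	non-MSMG
Gata1	non-MSMG
Gata3	non-MSMG
Gata4	non-MSMG
Gata5	non-MSMG
Gata6	non-MSMG
Gfap	non-MSMG
Gli3	non-MSMG
Gsc	non-MSMG
Hand1	non-MSMG
Hand2	non-MSMG
Insm1	non-MSMG
Isl1	non-MSMG
Lbx1	non-MSMG
Lhx2	non-MSMG
Lhx5	non-MSMG
Lmx1a	non-MSMG
Mbd2	non-MSMG
Meis1	non-MSMG
Mixl1	non-MSMG
Myf5	non-MSMG
Neurog1	non-MSMG
Nfia	non-MSMG
Npas3	non-MSMG
Nr2f1	non-MSMG
Nr2f2	non-MSMG
Nrp1	non-MSMG
Nrp2	non-MSMG
Olig3	non-MSMG
Otp	non-MSMG
Otx1	non-MSMG
Pax3	non-MSMG
Pdx1	non-MSMG
Peg3	non-MSMG
Phox2b	non-MSMG
Prl3d1	non-MSMG
Prox1	non-MSMG
Rybp	non-MSMG
Shh	non-MSMG
Sox1	non-MSMG
Sox18	non-MSMG
Sox3	non-MSMG
Sox5	non-MSMG
Sox9	non-MSMG
Stra13	non-MSMG
Syp	non-MSMG
Tcf4	non-MSMG
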