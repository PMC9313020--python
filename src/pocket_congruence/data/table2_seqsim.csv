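# Pairwise flexible/rigid structural comparison of the human GPCRs binding
# the eight studied ligands: alignment RMSD (Angstrom) and sequence
# similarity (%) per alignment mode, one row per compared receptor pair.
ligand,uniprot_pair,pdb_pair,rmsd_flex,rmsd_rigid,sim_flex,sim_rigid
AJLF,P16473.A|P43220.B,3G04.C|7LCK.R,2.92,4.87,19,17
DTZD,P43220.B|Q14831.C,7LCK.R|3MQ4.A,3.63,10.53,20,16
DTZD,P43220.B|P21728.A,7LCK.R|7LJC.R,3.19,3.19,33,33
DTZD,Q14831.C|P21728.A,3MQ4.A|7LJC.R,3.88,10.72,19,15
CLQV,P21453.A|P43220.B,3V2W.A|7LCK.R,2.84,4.94,27,21
CLQV,P21453.A|Q14833.C,3V2W.A|7E9H.A,3.99,4.51,24,25
CLQV,Q14833.C|P43220.B,7E9H.A|7LCK.R,4.37,6.44,24,24
IKSH,P16473.A|Q03431.B,3G04.C|6FJ3.A,2.98,4.66,18,22
NKOP,P43220.B|Q13255.C,7LCK.R|3KS9.A,4.47,8.08,18,17
USZP,P16473.A|P43220.B,3G04.C|7LCK.R,2.92,4.87,19,17
USZP,P16473.A|P41594.C,3G04.C|6N52.A,3.06,6.23,15,18
USZP,P43220.B|P41594.C,7LCK.R|6N52.A,3.83,9.67,25,20
XLWJ,P16473.A|P43220.B,3G04.C|7LCK.R,2.92,4.87,19,17
XLWJ,P16473.A|Q03431.B,3G04.C|6FJ3.A,2.98,4.66,18,22
XLWJ,P16473.A|P21728.A,3G04.C|7LJC.R,3.81,3.81,23,23
XLWJ,P43220.B|Q03431.B,7LCK.R|6FJ3.A,2.53,3.85,45,50
XLWJ,P43220.B|P21728.A,7LCK.R|7LJC.R,3.19,3.19,33,33
XLWJ,Q03431.B|P21728.A,6FJ3.A|7LJC.R,3.86,3.03,27,30
XLWJ,O75899.C|P16473.A,6W2X.B|3G04.C,3.16,6.04,16,22
XLWJ,O75899.C|P43220.B,6W2X.B|7LCK.R,2.92,5.69,24,22
XLWJ,O75899.C|Q03431.B,6W2X.B|6FJ3.A,3.20,4.60,24,22
XLWJ,O75899.C|P21728.A,6W2X.B|7LJC.R,3.03,3.15,25,26
YKMS,P35462.A|Q14416.C,3PBL.A|5KZN.A,5.38,11.06,17,17
YKMS,P35462.A|P21917.A,3PBL.A|5WIV.A,1.96,3.95,52,53
YKMS,P35462.A|P14416.A,3PBL.A|6CM4.A,2.15,9.63,88,64
YKMS,P35462.A|P43220.B,3PBL.A|7LCK.R,6.28,4.44,17,21
YKMS,Q14416.C|P21917.A,5KZN.A|5WIV.A,5.42,6.76,19,19
YKMS,Q14416.C|P14416.A,5KZN.A|6CM4.A,5.23,14.95,17,25
YKMS,Q14416.C|P43220.B,5KZN.A|7LCK.R,5.64,9.41,15,23
YKMS,P21917.A|P14416.A,5WIV.A|6CM4.A,2.72,8.72,52,50
YKMS,P21917.A|P43220.B,5WIV.A|7LCK.R,3.01,4.88,21,23
YKMS,P14416.A|P43220.B,6CM4.A|7LCK.R,3.49,4.44,32,31
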