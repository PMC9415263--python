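# Stable-isotope exact masses (Da) and relative abundances, NIST/IUPAC.
# element	mass_number	exact_mass	abundance
H	1	1.0078250319	0.999885
H	2	2.0141017780	0.000115
C	12	12.0000000000	0.9893
C	13	13.0033548378	0.0107
N	14	14.0030740052	0.99636
N	15	15.0001088984	0.00364
O	16	15.9949146221	0.99757
O	17	16.9991315000	0.00038
O	18	17.9991604000	0.00205
P	31	30.9737615100	1.0
S	32	31.9720706900	0.9493
S	33	32.9714585000	0.0076
S	34	33.9678668300	0.0429
S	36	35.9670808800	0.0002
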