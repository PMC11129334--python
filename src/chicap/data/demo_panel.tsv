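# 20-gene demonstration panel (approximate hg19 gene footprints).
# The production panel (e.g. a 189-gene childhood cancer predisposition list)
# is user-supplied in the same format.
symbol	chrom	start	end	inheritance	adult_onset_dominant_exception	tumor_suppressor
NF1	17	29421945	29709134	AD	False	True
TP53	17	7571720	7590868	AD	False	True
RB1	13	48877887	49056122	AD	False	True
WT1	11	32409322	32457081	AD	False	True
MSH2	2	47630206	47710367	AD	False	True
MSH6	2	48010221	48034092	AD	False	True
MLH1	3	37034841	37092337	AD	False	True
PMS2	7	6012870	6048756	AR	True	True
POLE	12	133200348	133263951	AD	False	False
DICER1	14	95552565	95624347	AD	False	True
SMARCB1	22	24129150	24176703	AD	False	True
SH2D1A	X	123480118	123507038	XL	False	True
ATM	11	108093211	108239829	AR	True	True
ERCC5	13	103498194	103528345	AR	False	True
FANCM	14	45605110	45670093	AR	False	False
FBXW7	4	153242410	153456185	AD	False	True
PRKAR1A	17	66508110	66547460	AD	False	True
BRCA2	13	32889611	32973805	AR	True	True
NBEA	13	35516424	36247120	AD	False	False
VHL	3	10183319	10195354	AD	False	True
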