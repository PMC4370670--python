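host_gene	mirna	is_ht	utr_change
CHM	hsa-miR-361-5p	yes	shorter
CHM	hsa-miR-361-3p	no	shorter
DKC1	hsa-miR-644b-5p	no	shorter
DKC1	hsa-miR-644b-3p	yes	shorter
GPC1	hsa-miR-149-5p	yes	shorter
GPC1	hsa-miR-149-3p	yes	shorter
HNRNPK	hsa-miR-7-5p	no	shorter
HNRNPK	hsa-miR-7-1-3p	yes	shorter
TNPO1	hsa-miR-4804-5p	no	shorter
TNPO1	hsa-miR-4804-3p	yes	shorter
LPP	hsa-miR-28-5p	no	shorter
LPP	hsa-miR-28-3p	yes	shorter
MLLT6	hsa-miR-4726-5p	yes	shorter
MLLT6	hsa-miR-4726-3p	no	shorter
NHS	hsa-miR-4768-3p	no	shorter
NHS	hsa-miR-4768-5p	yes	shorter
SREBF1	hsa-miR-33b-5p	yes	shorter
SREBF1	hsa-miR-33b-3p	no	shorter
PPFIA1	hsa-miR-548k	yes	shorter
ALDH4A1	hsa-miR-4695-5p	yes	shorter
ALDH4A1	hsa-miR-1290	no	shorter
ALDH4A1	hsa-miR-4695-3p	yes	shorter
CTDSP2	hsa-miR-26a-5p	yes	shorter
CTDSP2	hsa-miR-26a-2-3p	no	shorter
COPZ1	hsa-miR-148b-3p	yes	shorter
COPZ1	hsa-miR-148b-5p	yes	shorter
DPY19L1	hsa-miR-548n	yes	shorter
ZFR	hsa-miR-579	yes	shorter
GALNT7	hsa-miR-548t-5p	yes	shorter
GALNT7	hsa-miR-548t-3p	no	shorter
RBM47	hsa-miR-4802-3p	yes	shorter
RBM47	hsa-miR-4802-5p	no	shorter
GALNT10	hsa-miR-1294	yes	shorter
C9orf3	hsa-miR-23b-3p	no	shorter
C9orf3	hsa-miR-24-3p	no	shorter
C9orf3	hsa-miR-24-1-5p	yes	shorter
C9orf3	hsa-miR-27b-5p	no	shorter
C9orf3	hsa-miR-2278	yes	shorter
C9orf3	hsa-miR-23b-5p	no	shorter
C9orf3	hsa-miR-27b-3p	no	shorter
LASS6	hsa-miR-4774-3p	yes	shorter
LASS6	hsa-miR-4774-5p	no	shorter
ADCY6	hsa-miR-4701-3p	yes	longer
ADCY6	hsa-miR-4701-5p	no	longer
CD58	hsa-miR-548ac	yes	longer
NFYC	hsa-miR-30c-5p	no	longer
NFYC	hsa-miR-30c-1-3p	yes	longer
NFYC	hsa-miR-30e-3p	no	longer
NFYC	hsa-miR-30e-5p	no	longer
SCP2	hsa-miR-1273g-3p	yes	longer
SCP2	hsa-miR-1273g-5p	no	longer
SCP2	hsa-miR-5095	no	longer
SCP2	hsa-miR-1273f	yes	longer
ZRANB2	hsa-miR-186-5p	yes	longer
ZRANB2	hsa-miR-186-3p	yes	longer
BRE	hsa-miR-4263	yes	longer
ARHGEF11	hsa-miR-765	yes	longer
AP3S2	hsa-miR-5094	yes	longer
AP3S2	hsa-miR-5009-3p	yes	longer
AP3S2	hsa-miR-5009-5p	yes	longer
IGF2BP2	hsa-miR-548aq-3p	yes	longer
IGF2BP2	hsa-miR-548aq-5p	no	longer
HBS1L	hsa-miR-3662	yes	longer
C9orf5	hsa-miR-32-3p	yes	longer
C9orf5	hsa-miR-32-5p	no	longer
PITPNC1	hsa-miR-548aa	yes	longer
ATAD2	hsa-miR-548d-5p	yes	longer
ATAD2	hsa-miR-548d-3p	yes	longer
FBXW7	hsa-miR-3140-5p	no	longer
FBXW7	hsa-miR-3140-3p	yes	longer
NMNAT1	hsa-miR-5697	yes	longer
RASSF3	hsa-miR-548c-5p	no	longer
RASSF3	hsa-miR-548c-3p	yes	longer
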