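# Diploid human karyotype (46,XX), chromosome sizes and centromere positions
# in Mbp (GRCh38 cytogenetic scale, rounded).
name,length_mbp,centromere_mbp,copies
chr1,248.96,123.40,2
chr2,242.19,93.90,2
chr3,198.30,90.90,2
chr4,190.21,50.00,2
chr5,181.54,48.80,2
chr6,170.81,59.80,2
chr7,159.35,60.10,2
chr8,145.14,45.20,2
chr9,138.39,43.00,2
chr10,133.80,39.80,2
chr11,135.09,53.40,2
chr12,133.28,35.50,2
chr13,114.36,17.70,2
chr14,107.04,17.20,2
chr15,101.99,19.00,2
chr16,90.34,36.80,2
chr17,83.26,25.10,2
chr18,80.37,18.50,2
chr19,58.62,26.20,2
chr20,64.44,28.10,2
chr21,46.71,12.00,2
chr22,50.82,15.00,2
chrX,156.04,60.60,2
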