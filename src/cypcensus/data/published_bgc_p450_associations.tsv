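species_name	cluster_number	cluster_type	p450_name
Bacillus subtilis subsp. subtilis 168	4	Nrps-Transatpks-Otherks	CYP134A1
Bacillus subtilis subsp. subtilis 168	10	Other	CYP134A1
Bacillus subtilis subsp. subtilis RO-NN-1	3	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis subsp. subtilis BSP1	8	Transatpks-Otherks-Nrps	CYP107K1
Bacillus subtilis subsp. subtilis 6051-HGW	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis subsp. subtilis 6051-HGW	10	Other	CYP107K1
Bacillus subtilis subsp. subtilis BAB-1	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis subsp. subtilis AG1839	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis subsp. subtilis AG1839	10	Other	CYP107K1
Bacillus subtilis subsp. subtilis JH642	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis subsp. subtilis JH642	10	Other	CYP134A1
Bacillus subtilis subsp. subtilis OH 131.1	1	Lantipeptide	CYP152A1
Bacillus subtilis subsp. subtilis OH 131.1	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis subsp. subtilis OH 131.1	9	Other	CYP134A1
Bacillus subtilis subsp. spizizenii W23	1	Phosphonate	CYP152A1
Bacillus subtilis subsp. spizizenii W23	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis subsp. spizizenii W23	10	Other	CYP134A1
Bacillus subtilis subsp. spizizenii TU-B-10	3	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis subsp. spizizenii TU-B-10	9	Other	CYP134A1
Bacillus subtilis BSn5	4	Other	CYP102A48
Bacillus subtilis BSn5	8	Lantipeptide	CYP152A1
Bacillus subtilis BSn5	11	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis QB928	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis QB928	10	Other	CYP134A1
Bacillus subtilis XF-1	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis PY79	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus subtilis PY79	9	Other	CYP134A1
Bacillus licheniformis ATCC 14580	7	Other	CYP134A5
Bacillus licheniformis DSM 13 = ATCC 14580	7	Other	CYP134A5
Bacillus paralicheniformis	10	Other	CYP134A5
Bacillus velezensis FZB42	5	Transatpks-Nrps	CYP107K3
Bacillus velezensis FZB42	6	Transatpks-Nrps	CYP107H4
Bacillus velezensis FZB42	9	Transatpks	CYP113L1
Bacillus velezensis CAU B946	5	Transatpks-Nrps	CYP107K3
Bacillus velezensis CAU B946	6	Transatpks-Nrps	CYP107H4
Bacillus velezensis CAU B946	9	Transatpks	CYP113L1
Bacillus velezensis YAU B9601-Y2	5	Transatpks	CYP107K3
Bacillus velezensis YAU B9601-Y2	6	Transatpks-Nrps	CYP107K3
Bacillus velezensis YAU B9601-Y2	7	Transatpks-Nrps	CYP107H4
Bacillus velezensis YAU B9601-Y2	10	Transatpks	CYP113L1
Bacillus velezensis AS43.3	6	Transatpks	CYP107K3
Bacillus velezensis AS43.3	7	Transatpks-Nrps	CYP113L1
Bacillus velezensis AS43.3	10	Transatpks	CYP113L1
Bacillus velezensis UCMB5036	5	Transatpks-Nrps	CYP107K3
Bacillus velezensis UCMB5036	6	Transatpks-Nrps	CYP107H4
Bacillus velezensis UCMB5036	9	Bacteriocin-Nrps	CYP113L1
Bacillus velezensis UCMB5033	6	Transatpks-Nrps	CYP107K3
Bacillus velezensis UCMB5033	7	Transatpks-Nrps	CYP107H4
Bacillus velezensis UCMB5033	10	Transatpks	CYP113L1
Bacillus velezensis UCMB5113	7	Transatpks-Nrps	CYP107K3
Bacillus velezensis UCMB5113	8	Transatpks-Nrps	CYP107H4
Bacillus velezensis UCMB5113	11	Transatpks	CYP113L1
Bacillus velezensis NAU-B3	3	Transatpks	CYP113L1
Bacillus velezensis NAU-B3	6	Transatpks-Nrps	CYP107H4
Bacillus velezensis NAU-B3	7	Transatpks-Nrps	CYP107K3
Bacillus velezensis TrigoCor1448	5	Transatpks-Nrps	CYP107K3
Bacillus velezensis TrigoCor1448	6	Transatpks-Nrps	CYP107H4
Bacillus velezensis SQR9	6	Transatpks-Nrps	CYP107K3
Bacillus velezensis SQR9	7	Transatpks-Nrps	CYP107H4
Bacillus velezensis SQR9	10	Transatpks	CYP113L1
Bacillus velezensis	6	Transatpks-Nrps	CYP107K3
Bacillus velezensis	7	Transatpks-Nrps	CYP107H4
Bacillus velezensis	10	Transatpks	CYP113L1
Bacillus amyloliquefaciens DSM 7	5	Transatpks-Nrps	CYP107K3
Bacillus amyloliquefaciens DSM 7	6	Transatpks-Nrps	CYP107H2
Bacillus amyloliquefaciens TA208	7	Transatpks-Nrps	CYP107H2
Bacillus amyloliquefaciens TA208	8	Transatpks-Nrps	CYP107K3
Bacillus amyloliquefaciens LL3	5	Transatpks-Nrps	CYP107K3
Bacillus amyloliquefaciens LL3	6	Transatpks-Nrps	CYP107H2
Bacillus amyloliquefaciens XH7	7	Transatpks-Nrps	CYP107H2
Bacillus amyloliquefaciens XH7	8	Transatpks-Nrps	CYP107K3
Bacillus amyloliquefaciens Y2	6	Transatpks-Nrps	CYP107K3
Bacillus amyloliquefaciens Y2	7	Transatpks-Nrps	CYP107H4
Bacillus amyloliquefaciens Y2	10	Transatpks	CYP113L1
Bacillus amyloliquefaciens IT-45	3	Transatpks	CYP113L1
Bacillus amyloliquefaciens IT-45	6	Transatpks-Nrps	CYP107H4
Bacillus amyloliquefaciens IT-45	7	Transatpks-Nrps	CYP107K3
Bacillus amyloliquefaciens CC178	6	Transatpks-Nrps	CYP107H4
Bacillus amyloliquefaciens CC178	9	Transatpks	CYP113L1
Bacillus amyloliquefaciens LFB112	7	Transatpks-Nrps	CYP107K3
Bacillus amyloliquefaciens LFB112	8	Transatpks-Nrps	CYP107H4
Bacillus amyloliquefaciens LFB112	11	Transatpks	CYP113L1
Bacillus atrophaeus 1942	3	Nrps-Transatpks-Otherks	CYP107K2
Bacillus atrophaeus 1942	10	Nrps	CYP152A9
Bacillus atrophaeus NRS 1221A	3	Nrps-Transatpks-Otherks	CYP107K2
Bacillus atrophaeus NRS 1221A	10	Nrps	CYP152A9
Bacillus vallismortis	6	Transatpks-Nrps	CYP107K3
Bacillus vallismortis	7	Transatpks-Nrps	CYP107H4
Bacillus vallismortis	10	Transatpks	CYP113L1
Bacillus pumilus SH-B9	8	Nrps	CYP109B6
Bacillus sp. JS	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus sp. Pc3	1	Bacteriocin-Transatpks-Nrps	CYP107H4
Bacillus sp. Pc3	2	Transatpks-Nrps	CYP107K3
Bacillus sp. Pc3	10	Transatpks	CYP113L1
Bacillus sp. BH072	8	Transatpks-Nrps	CYP107K3
Bacillus sp. BH072	9	Transatpks-Nrps	CYP107H4
Bacillus sp. BH072	12	Transatpks	CYP107H4
Bacillus sp. YP1	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus sp. BS34A	4	Nrps-Transatpks-Otherks	CYP107K1
Bacillus sp. BS34A	10	Other	CYP134A1
Bacillus sp. LM 4-2	3	Nrps-Transatpks-Otherks	CYP107K1
Bacillus sp. LM 4-2	7	Other	CYP102A48
Bacillus sp. LM 4-2	9	Other	CYP134A1
Bacillus gibsonii	1	Nrps-Transatpks-Otherks	CYP107K1
Bacillus gibsonii	6	Other	CYP134A1
Bacillus gibsonii	9	Lantipeptide	CYP152A1
Bacillus xiamenensis	2	Nrps	CYP1179A4
Bacillus altitudinis	2	Nrps	CYP1179A4
Bacillus altitudinis	8	Nrps	CYP109B5
Bacillus sp. SDLI1	3	Transatpks-Nrps	CYP107H4
Bacillus sp. SDLI1	4	Transatpks-Nrps	CYP107K3
Bacillus sp. SDLI1	11	Transatpks	CYP113L1
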