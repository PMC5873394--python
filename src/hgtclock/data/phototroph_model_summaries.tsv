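# Published median and 95% HPD divergence-date estimates (Ma) for the
# phototroph models: A (no HGT constraints) and D (SahH + BchH), each under
# a 1.2 Ga or 1.6 Ga akinete minimum-age calibration.
# model<TAB>akinete_Ma<TAB>node<TAB>median_Ma<TAB>hpd_lower_Ma<TAB>hpd_upper_Ma
A	1200	Root age	3591	3323	3837
D	1200	Root age	3624	3483	3884
A	1600	Root age	3692	3408	3968
D	1600	Root age	3692	3569	3920
A	1200	Stem Cyanobacteria	2825	2570	3195
D	1200	Stem Cyanobacteria	2776	2396	2934
A	1600	Stem Cyanobacteria	3158	2886	3486
D	1600	Stem Cyanobacteria	2836	2724	2936
A	1200	Crown Cyanobacteria	2305	2026	2601
D	1200	Crown Cyanobacteria	2244	1912	2419
A	1600	Crown Cyanobacteria	2677	2426	2972
D	1600	Crown Cyanobacteria	2515	2382	2593
A	1200	Crown Cyanobacteria excl. Gloeobacter	1943	1723	2188
D	1200	Crown Cyanobacteria excl. Gloeobacter	1902	1713	2096
A	1600	Crown Cyanobacteria excl. Gloeobacter	2328	2098	2564
D	1600	Crown Cyanobacteria excl. Gloeobacter	2234	2087	2360
A	1200	Stem GNS	2099	1584	2674
D	1200	Stem GNS	2861	2498	3004
A	1600	Stem GNS	2253	1597	2785
D	1600	Stem GNS	2922	2759	2950
A	1200	Crown GNS	1041	624	1542
D	1200	Crown GNS	1986	1682	2433
A	1600	Crown GNS	1111	618	1714
D	1600	Crown GNS	2109	1810	2438
A	1200	Stem GSB	2640	2298	2977
D	1200	Stem GSB	2561	2263	2853
A	1600	Stem GSB	2602	2265	2981
D	1600	Stem GSB	2737	2423	2902
A	1200	Crown GSB	1798	1641	2112
D	1200	Crown GSB	1716	1645	1950
A	1600	Crown GSB	1793	1640	2112
D	1600	Crown GSB	1719	1660	2173
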