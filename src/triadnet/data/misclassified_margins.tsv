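#substrate	enzyme	product	dist_pos	dist_neg	difference
C00002	YIL139C	C06397	0.24	0.19125	0.04875
C00002	YPL271W	C00008	0.25	0.22125	0.02875
C00002	YPR033C	C00020	0.1	0.03375	0.06625
C00003	YKR066C	C00004	0.25	0.225	0.025
C00003	YPR167C	C00004	0.25	0.177831	0.072169
C00010	YER090W	C00024	0.25	0.1125	0.1375
C00010	YER178W	C00024	0.189188	0.1425	0.046688
C00024	YAL054C	C00033	0.21	0.199626	0.010374
C00024	YCL030C	C06548	0.25	0.0975	0.1525
C00024	YLR153C	C00033	0.21	0.199626	0.010374
C00025	YHR037W	C03912	0.375	0.202643	0.172357
C00026	YIR034C	C00449	0.271688	0.25	0.021688
C00035	YGL047W	C00096	0.1875	0.165	0.0225
C00037	YOL049W	C00051	0.48375	0.25	0.23375
C00047	YPL096W	C12989	0.25	0.225	0.025
C00055	YBL013W	C04121	0.177831	0.12375	0.054081
C00055	YDR410C	C04121	0.25	0.22125	0.02875
C00055	YKR069W	C04121	0.25	0.19125	0.05875
C00065	YBR263W	C00143	0.375	0.25	0.125
C00065	YLR058C	C00143	0.375	0.25	0.125
C00083	YPL231W	C12647	0.073223	0.02625	0.046973
C00085	YKL104C	C00352	0.25	0.2325	0.0175
C00086	YIR029W	C00499	0.4525	0.375	0.0775
C00096	YBR252W	C00144	0.25	0.12	0.13
C00096	YGR036C	C00636	0.25	0.24375	0.00625
C00108	YDR354W	C04302	0.375	0.2325	0.1425
C00109	YCL018W	C06032	0.383376	0.36625	0.017126
C00118	YGL026C	C03506	0.375	0.37375	0.00125
C00143	YGL125W	C00440	0.3025	0.28375	0.01875
C00155	YNL256W	C01118	0.25	0.22125	0.02875
C00167	YJR131W	C00191	0.25	0.21	0.04
C00191	YOR065W	C05787	0.25	0.19875	0.05125
C00223	YDR062W	C12096	0.0825	0.082244	0.000256
C00223	YMR296C	C12096	0.0825	0.04875	0.03375
C00234	YDR408C	C04376	0.36625	0.32125	0.045
C00333	YJR153W	C00470	0.375	0.12375	0.25125
C00448	YDL205C	C16144	0.225	0.19125	0.03375
C00582	YHL003C	C05598	0.25	0.1875	0.0625
C00582	YKL008C	C05598	0.25	0.1875	0.0625
C00632	YDR120C	C05831	0.25	0.15	0.1
C00652	YML086C	C06316	0.565	0.36625	0.19875
C00842	YDR127W	C06017	0.1125	0.09	0.0225
C00864	YDR531W	C03492	0.25125	0.25	0.00125
C00931	YDL205C	C01024	0.59625	0.375	0.22125
C01063	YBL015W	C09813	0.1275	0.1125	0.015
C01079	YDR044W	C03263	0.41875	0.25	0.16875
C01096	YCL030C	C02888	0.25	0.22875	0.02125
C01100	YIL116W	C01267	0.375	0.25	0.125
C01902	YML008C	C08830	0.375	0.25	0.125
C02411	YGR155W	C03058	0.09	0.075	0.015
C02909	YHR007C	C14098	0.25	0.195	0.055
C03012	YDR402C	C11713	0.36375	0.2575	0.10625
C03598	YPR167C	C04297	0.25	0.1875	0.0625
C04751	YAR015W	C04823	0.34	0.32875	0.01125
C04874	YDR452W	C05925	0.16875	0.125	0.04375
C06102	YLR231C	C06105	0.535	0.25	0.285
C06397	YBR029C	C07838	0.18375	0.17625	0.0075
C06599	YNL202W	C06600	0.147938	0.113376	0.034562
C06714	YDR127W	C06723	0.0975	0.08625	0.01125
C07649	YDR402C	C12673	0.55	0.3625	0.1875
C07732	YGR234W	C07733	0.3075	0.25	0.0575
C09811	YGL063W	C09812	0.1125	0.10125	0.01125
C11907	YPR118W	C11908	0.25	0.22875	0.02125
C11923	YFR015C	C12384	0.25	0.03	0.22
C11923	YLR258W	C12384	0.25	0.03	0.22
C14082	YHR007C	C14089	0.25	0.195	0.055
C15786	YGR060W	C15797	0.09375	0.08625	0.0075
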