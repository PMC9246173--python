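rsid	position	a1	a2	beta	se	pvalue	trait
rs2107595	7:19049388	A	G	0.0752	0.0073	1.25e-24	CAD,stroke,AAC
rs57301765	7:19052733	A	G	0.0722	0.0073	2.81e-23	CAD
rs2023936	7:19039067	C	G	-0.0624	0.0068	6.84e-20	CAD,AAC
rs28688791	7:19039605	T	C	-0.0614	0.0068	2.18e-19	CAD,AAC
rs2074633	7:19035920	T	C	-0.0599	0.0067	4.70e-19	CAD
rs7798197	7:19037661	A	G	-0.0609	0.0068	6.29e-19	CAD,AAC
rs7788833	7:19034191	T	C	-0.0586	0.0067	1.83e-18	CAD
rs7788972	7:19034280	A	T	0.0586	0.0067	1.96e-18	CAD
rs2526620	7:19045397	A	G	-0.0579	0.0069	3.63e-17	CAD,AAC
rs10227612	7:19034579	T	G	-0.0493	0.0063	4.11e-15	CAD
rs2023938	7:19036775	T	C	-0.0638	0.0084	3.27e-14	CAD
rs11984041	7:19031935	T	C	0.0632	0.0085	1.20e-13	CAD,stroke
rs2023937	7:19037051	A	T	-0.0616	0.0093	4.15e-11	CAD
rs10245779	7:19042749	C	G	0.0588	0.0093	2.30e-10	CAD
rs10241964	7:19042114	A	G	0.0585	0.0093	2.87e-10	CAD
rs28727433	7:19042484	A	G	0.0583	0.0093	3.34e-10	CAD
rs7784712	7:19059890	T	C	0.0615	0.0098	3.79e-10	CAD
rs10255384	7:19055703	A	C	0.0601	0.0097	6.68e-10	CAD
rs7792656	7:19040331	T	C	-0.0558	0.009	6.82e-10	CAD
rs7783974	7:19059427	T	C	0.0594	0.0098	1.12e-9	CAD
rs59111453	7:19060333	C	G	-0.0596	0.0098	1.18e-9	CAD
rs12530920	7:19055797	A	C	-0.0543	0.0095	1.08e-8	CAD
rs2717334	7:19057996	C	G	0.051	0.0091	2.10e-8	CAD
rs2526630	7:19036578	T	C	0.0295	0.0057	2.11e-7	CAD
rs10260515	7:19051512	C	G	-0.0288	0.0057	3.81e-7	CAD
rs2526619	7:19046946	A	G	-0.0454	0.009	4.07e-7	CAD
rs1029510	7:19049507	A	T	0.0288	0.0057	4.64e-7	CAD
rs7812296	7:19036738	T	C	-0.0285	0.0057	5.24e-7	CAD
rs1548577	7:19049162	A	G	0.0283	0.0057	6.76e-7	CAD
rs2892912	7:19051715	A	T	-0.028	0.0057	7.33e-7	CAD
rs7791226	7:19039351	T	C	0.028	0.0057	7.87e-7	CAD
rs7807970	7:19039381	C	G	0.0276	0.0057	1.16e-6	CAD
rs433	7:19038319	A	G	0.0275	0.0057	1.30e-6	CAD
rs2526629	7:19038678	A	G	-0.0263	0.0057	3.62e-6	CAD
rs2717368	7:19051700	T	C	-0.0262	0.0057	4.30e-6	CAD
rs12670036	7:19032243	A	G	-0.0351	0.0079	8.21e-6	CAD
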