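rsID	chrom	pos	ref	alt	significance	condition
rs12913832	15	28365618	A	G	association	eye color (blue/brown)
rs16891982	5	33951693	C	G	association	skin/hair pigmentation (SLC45A2)
rs1426654	15	48426484	G	A	association	skin pigmentation (SLC24A5)
rs1805007	16	89986117	C	T	association	red hair (MC1R)
rs1805008	16	89986144	C	T	association	red hair (MC1R)
rs1805009	16	89986546	G	C	association	red hair (MC1R)
rs1042602	11	88911696	C	A	association	skin pigmentation (TYR)
rs12203592	6	396321	C	T	association	hair color/freckling (IRF4)
rs1393350	11	89011046	G	A	association	eye color (TYR)
rs12896399	14	92773663	G	T	association	hair color (SLC24A4)
rs683	9	12709305	C	A	association	hair color (TYRP1)
rs2378249	20	33218090	A	G	association	hair color (PIGU/ASIP region)
rsSIM1000	1	15000000	A	C	association	pigmentation (synthetic demo site)
rsSIM1001	2	15137000	C	T	association	pigmentation (synthetic demo site)
rsSIM1002	3	15274000	G	C	association	pigmentation (synthetic demo site)
rsSIM1003	4	15411000	T	A	association	pigmentation (synthetic demo site)
rsSIM1004	5	15548000	A	G	association	pigmentation (synthetic demo site)
rsSIM1005	6	15685000	C	A	association	pigmentation (synthetic demo site)
rsSIM1006	7	15822000	G	T	association	pigmentation (synthetic demo site)
rsSIM1007	8	15959000	T	C	association	pigmentation (synthetic demo site)
rsSIM1008	9	16096000	A	T	association	pigmentation (synthetic demo site)
rsSIM1009	10	16233000	C	G	association	pigmentation (synthetic demo site)
rsSIM1010	11	16370000	G	A	association	pigmentation (synthetic demo site)
rsSIM1011	12	16507000	T	G	association	pigmentation (synthetic demo site)
rsSIM1012	13	16644000	A	C	association	pigmentation (synthetic demo site)
rsSIM1013	14	16781000	C	T	association	pigmentation (synthetic demo site)
rsSIM1014	15	16918000	G	C	association	pigmentation (synthetic demo site)
rsSIM1015	16	17055000	T	A	association	pigmentation (synthetic demo site)
rsSIM1016	17	17192000	A	G	association	pigmentation (synthetic demo site)
rsSIM1017	18	17329000	C	A	association	pigmentation (synthetic demo site)
rsSIM1018	19	17466000	G	T	association	pigmentation (synthetic demo site)
rsSIM1019	20	17603000	T	C	association	pigmentation (synthetic demo site)
rsSIM1020	21	17740000	A	T	association	pigmentation (synthetic demo site)
rsSIM1021	22	17877000	C	G	association	pigmentation (synthetic demo site)
rsSIM1022	1	18014000	G	A	association	pigmentation (synthetic demo site)
rsSIM1023	2	18151000	T	G	association	pigmentation (synthetic demo site)
rsSIM1024	3	18288000	A	C	association	pigmentation (synthetic demo site)
rsSIM1025	4	18425000	C	T	association	pigmentation (synthetic demo site)
rsSIM1026	5	18562000	G	C	association	pigmentation (synthetic demo site)
rsSIM1027	6	18699000	T	A	association	pigmentation (synthetic demo site)
rsSIM1028	7	18836000	A	G	association	pigmentation (synthetic demo site)
rsSIM1029	8	18973000	C	A	association	pigmentation (synthetic demo site)
rsSIM1030	9	19110000	G	T	association	pigmentation (synthetic demo site)
rsSIM1031	10	19247000	T	C	association	pigmentation (synthetic demo site)
rsSIM1032	11	19384000	A	T	association	pigmentation (synthetic demo site)
rsSIM1033	12	19521000	C	G	association	pigmentation (synthetic demo site)
rsSIM1034	13	19658000	G	A	association	pigmentation (synthetic demo site)
rsSIM1035	14	19795000	T	G	association	pigmentation (synthetic demo site)
rsSIM1036	15	19932000	A	C	association	pigmentation (synthetic demo site)
rsSIM1037	16	20069000	C	T	association	pigmentation (synthetic demo site)
rsSIM1038	17	20206000	G	C	association	pigmentation (synthetic demo site)
rsSIM1039	18	20343000	T	A	association	pigmentation (synthetic demo site)
rsSIM1040	19	20480000	A	G	association	pigmentation (synthetic demo site)
rsSIM1041	20	20617000	C	A	association	pigmentation (synthetic demo site)
rsSIM1042	21	20754000	G	T	association	pigmentation (synthetic demo site)
rsSIM1043	22	20891000	T	C	association	pigmentation (synthetic demo site)
rsSIM1044	1	21028000	A	T	association	pigmentation (synthetic demo site)
rsSIM1045	2	21165000	C	G	association	pigmentation (synthetic demo site)
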