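# synthetic miRBase-style aliases table (representative subset)
MI0000060	hsa-let-7a-1;
MIMAT0000062	hsa-let-7a;hsa-let-7a-5p;
MIMAT0004481	hsa-let-7a*;hsa-let-7a-3p;
MI0000063	hsa-let-7b;
MIMAT0000063	hsa-let-7b;hsa-let-7b-5p;
MI0000064	hsa-let-7c;
MIMAT0000064	hsa-let-7c;hsa-let-7c-5p;
MI0000077	hsa-mir-21;
MIMAT0000076	hsa-miR-21;hsa-miR-21-5p;
MIMAT0004494	hsa-miR-21*;hsa-miR-21-3p;
MI0000268	hsa-mir-34a;
MIMAT0000255	hsa-miR-34a;hsa-miR-34a-5p;
MIMAT0004557	hsa-miR-34a*;hsa-miR-34a-3p;
MI0000742	hsa-mir-34b;
MIMAT0000685	hsa-miR-34b;hsa-miR-34b-5p;
MI0000743	hsa-mir-34c;
MIMAT0000686	hsa-miR-34c;hsa-miR-34c-5p;
MI0000489	hsa-mir-195;
MIMAT0000461	hsa-miR-195;hsa-miR-195-5p;
MIMAT0004615	hsa-miR-195*;hsa-miR-195-3p;
MI0000651	hsa-mir-1-1;
MIMAT0000416	hsa-miR-1;hsa-miR-1-3p;
MI0000071	hsa-mir-17;
MIMAT0000070	hsa-miR-17;hsa-miR-17-5p;
MIMAT0000071	hsa-miR-17*;hsa-miR-17-3p;
MI0000073	hsa-mir-19a;
MIMAT0000073	hsa-miR-19a;hsa-miR-19a-3p;
MI0000074	hsa-mir-19b-1;
MIMAT0000074	hsa-miR-19b;hsa-miR-19b-3p;
MI0000085	hsa-mir-27a;
MIMAT0000084	hsa-miR-27a;hsa-miR-27a-3p;
MIMAT0004501	hsa-miR-27a*;hsa-miR-27a-5p;
MI0000105	hsa-mir-29b-1;
MIMAT0000100	hsa-miR-29b;hsa-miR-29b-3p;
MI0000821	hsa-mir-133b;
MIMAT0000770	hsa-miR-133b;
MI0000810	hsa-mir-135b;
MIMAT0000758	hsa-miR-135b;hsa-miR-135b-5p;
MI0000476	hsa-mir-138-1;
MIMAT0000430	hsa-miR-138;hsa-miR-138-5p;
MI0000253	hsa-mir-148a;
MIMAT0000243	hsa-miR-148a;hsa-miR-148a-3p;
MI0000289	hsa-mir-181a-1;
MIMAT0000256	hsa-miR-181a;hsa-miR-181a-5p;
MI0000238	hsa-mir-196a-1;
MIMAT0000226	hsa-miR-196a;hsa-miR-196a-5p;
MI0000650	hsa-mir-200c;
MIMAT0000617	hsa-miR-200c;hsa-miR-200c-3p;
MI0000252	hsa-mir-129-1;
MIMAT0000242	hsa-miR-129;hsa-miR-129-5p;
MI0000805	hsa-mir-342;
MIMAT0000753	hsa-miR-342;hsa-miR-342-3p;
MI0000764	hsa-mir-363;
MIMAT0000707	hsa-miR-363;hsa-miR-363-3p;
MI0000814	hsa-mir-338;
MIMAT0000763	hsa-miR-338;hsa-miR-338-3p;
MI0003162	hsa-mir-519d;
MIMAT0002853	hsa-miR-519d;hsa-miR-519d-3p;
MI0005756	hsa-mir-934;
MIMAT0004977	hsa-miR-934;
MI0000093	hsa-mir-92a-1;
MIMAT0000092	hsa-miR-92a;hsa-miR-92a-3p;
MI0000681	hsa-mir-155;
MIMAT0000646	hsa-miR-155;hsa-miR-155-5p;
MI0000089	hsa-mir-31;
MIMAT0000089	hsa-miR-31;hsa-miR-31-5p;
MI0000459	hsa-mir-143;
MIMAT0000435	hsa-miR-143;hsa-miR-143-3p;
MI0000461	hsa-mir-145;
MIMAT0000437	hsa-miR-145;hsa-miR-145-5p;
MI0000471	hsa-mir-126;
MIMAT0000445	hsa-miR-126;hsa-miR-126-3p;
MI0000298	hsa-mir-221;
MIMAT0000278	hsa-miR-221;hsa-miR-221-3p;
MI0000299	hsa-mir-222;
MIMAT0000279	hsa-miR-222;hsa-miR-222-3p;
MI0000069	hsa-mir-15a;
MIMAT0000068	hsa-miR-15a;hsa-miR-15a-5p;
MI0000070	hsa-mir-16-1;
MIMAT0000069	hsa-miR-16;hsa-miR-16-5p;
MI0000267	hsa-mir-10b;
MIMAT0000254	hsa-miR-10b;hsa-miR-10b-5p;
MI0000113	hsa-mir-106a;
MIMAT0000103	hsa-miR-106a;hsa-miR-106a-5p;
MI0000082	hsa-mir-25;
MIMAT0000081	hsa-miR-25;hsa-miR-25-3p;
MI0000098	hsa-mir-96;
MIMAT0000095	hsa-miR-96;hsa-miR-96-5p;
MI0000263	hsa-mir-7-1;
MIMAT0000252	hsa-miR-7;hsa-miR-7-5p;
MI0000283	hsa-mir-203;hsa-mir-203a;
MIMAT0000264	hsa-miR-203;hsa-miR-203a;hsa-miR-203a-3p;
MI0016748	hsa-mir-3607;
MIMAT0017984	hsa-miR-3607-3p;
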