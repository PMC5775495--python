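tested_group	D	p_raw	p_bonferroni	h1	h2	h3	h4
BAR Hybrids	0.273886	0	0	Wild NA H. annuus	Domestic H. annuus	BAR Hybrids	H. maximiliani
BAR H. petiolaris	0.126935	0.001319	0.019785	Wild NA H. annuus	Domestic H. annuus	BAR H. petiolaris	H. maximiliani
CAT Hybrids	0.369036	0	0	Wild NA H. annuus	Domestic H. annuus	CAT Hybrids	H. maximiliani
CAT H. petiolaris	0.180477	0.000002	0.00003	Wild NA H. annuus	Domestic H. annuus	CAT H. petiolaris	H. maximiliani
CHU Hybrids	0.270556	0	0	Wild NA H. annuus	Domestic H. annuus	CHU Hybrids	H. maximiliani
CHU H. petiolaris	0.12798	0.000481	0.007215	Wild NA H. annuus	Domestic H. annuus	CHU H. petiolaris	H. maximiliani
CZ Hybrids	0.505836	0	0	Wild NA H. annuus	Domestic H. annuus	CZ Hybrids	H. maximiliani
CZ H. petiolaris	0.119033	0.00209	0.03135	Wild NA H. annuus	Domestic H. annuus	CZ H. petiolaris	H. maximiliani
HIL H. petiolaris	0.114042	0.023592	0.35388	Wild NA H. annuus	Domestic H. annuus	HIL H. petiolaris	H. maximiliani
SAL H. petiolaris	0.073794	0.110138	1	Wild NA H. annuus	Domestic H. annuus	SAL H. petiolaris	H. maximiliani
SAN H. petiolaris	0.073788	0.125875	1	Wild NA H. annuus	Domestic H. annuus	SAN H. petiolaris	H. maximiliani
UNI H. petiolaris	0.092248	0.043346	0.65019	Wild NA H. annuus	Domestic H. annuus	UNI H. petiolaris	H. maximiliani
WIN Hybrids	0.354193	0	0	Wild NA H. annuus	Domestic H. annuus	WIN Hybrids	H. maximiliani
WIN H. petiolaris	0.079686	0.064328	0.96492	Wild NA H. annuus	Domestic H. annuus	WIN H. petiolaris	H. maximiliani
NA H. petiolaris	0.104493	0.004149	0.062235	Wild NA H. annuus	Domestic H. annuus	North American H. petiolaris	H. maximiliani
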