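name	iupac	note
CBF1/CRT	TGGCCGAC
AtHB5	CAATNATTG
SURE1STPAT21	AATAGAAAA	spelling printed in the results table
SURE2STPAT21	AATACAAAA	spelling printed in the element list; same element as SURE1STPAT21
ABRE	ACGTGTC	labelled ABR in the results table; same element
RAV1-B	CACCTG
MYCATERD22	CACATG
WBBOXPCWRKY1	TTTGACY
GT1GMSCAM4	GAAAAA
MYCATERD1	CATGTG
RAV1AAT	CAACA
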