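replicon	kind	start	end	in_reference	in_HB27A	in_HB27E
HB27_chr	chromosome	259293	259789	NO	YES	YES
HB27_chr	chromosome	386772	389127	NO	YES	YES
HB27_chr	chromosome	562354	562716	NO	YES	YES
HB27_chr	chromosome	1082351	1082693	NO	NO	YES
HB27_chr	chromosome	1133885	1134345	NO	YES	YES
HB27_chr	chromosome	1370579	1371607	YES	YES	YES
HB27_chr	chromosome	1533343	1534271	YES	YES	YES
HB27_chr	chromosome	1550847	1551323	NO	YES	YES
HB27_chr	chromosome	1655564	1655957	NO	YES	YES
HB27_pTT27	megaplasmid	23402	23834	NO	NO	YES
HB27_pTT27	megaplasmid	57597	58625	YES	YES	YES
HB27_pTT27	megaplasmid	72589	73617	YES	YES	YES
HB27_pTT27	megaplasmid	85677	86705	YES	YES	YES
HB27_pTT27	megaplasmid	154975	155865	NO	YES	YES
HB27_pTT27	megaplasmid	159958	160986	YES	YES	YES
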