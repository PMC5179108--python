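# All 33 cohort families. 'secure' marks a secure genetic diagnosis (18 families).
# The five families in which no disease-causing candidate was found are not named
# in the source cohort; UNS1..UNS5 are synthetic placeholder ids for them.
family	secure
A10	1
64ORG	1
79ORG	1
77ORG	0
A18	0
55ORG	1
65ORG	0
67ORG	0
75ORG	0
80ORG	1
71ORG	1
2ORG	1
10NCE	1
68ORG	1
58ORG	1
69ORG	1
81ORG	1
E4	1
76ORG	1
82ORG	1
51ORG	1
73ORG	1
22ORG	0
39ORG	0
A3	1
56ORG	0
62ORG	0
66ORG	0
UNS1	0
UNS2	0
UNS3	0
UNS4	0
UNS5	0
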