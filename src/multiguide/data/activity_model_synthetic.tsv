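# SYNTHETIC coefficient table for the sgRNA activity logistic model.
# Stand-in weights with the published model's feature structure:
# position-specific mono- and dinucleotide indicators over the 30-nt
# context (4nt 5' flank + 20nt protospacer + 3nt PAM + 3nt 3' flank,
# 1-based positions) plus protospacer GC-count terms. Replace by a
# published table via configuration to reproduce a specific model.
# Columns: feature_name, weight.
intercept	-0.40
gc_low	-0.2026
gc_high	-0.1666
C1	-0.0187354
T1	0.6824457
A2	-0.0702041
G2	0.6319477
C3	0.3419377
G3	0.1426665
C4	-0.4024065
T4	0.1408217
A5	0.1741320
C6	0.6506903
T6	-0.2743911
A7	0.0004743
C7	0.2071493
A8	0.0100669
A9	0.0447477
T9	0.4682641
C10	-0.5805830
T12	-0.1364203
A14	-0.1220683
C14	-0.1224261
G14	-0.3292036
T15	0.2117709
G16	-0.0189842
A17	-0.3328112
G17	1.0116401
A18	0.0151056
G18	-0.3706292
C19	-0.2508753
T19	0.3044478
T21	0.1786889
C23	0.2576636
T25	0.7648411
A26	-0.5295445
C26	-0.1677037
A27	0.6949630
C27	-0.0522148
G27	0.2496953
G29	-0.2388392
T29	0.6402853
C30	0.0070610
AT1	-0.2945343
GT2	0.5954982
TT2	-0.7389970
TA4	-0.3197684
TT5	-0.0245347
AA6	0.4356343
AC7	-0.0606493
TC7	0.1065956
CC8	-0.8101463
TG10	0.4142173
AT13	0.1230723
CC14	0.0131480
CT14	0.3765778
GG14	-0.2292847
TT16	-0.2245201
CT17	-0.0562876
GT18	0.3929761
TC18	-0.1824107
TG23	0.1398124
TC24	-0.0447633
TT24	0.1980719
AA27	0.8292855
GC28	0.2468974
TT29	-0.2484142
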