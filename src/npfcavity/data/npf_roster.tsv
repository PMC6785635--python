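transporter	subclade
NPF1.1	1
NPF1.2	1
NPF1.3	1
NPF2.1	2
NPF2.2	2
NPF2.3	2
NPF2.4	2
NPF2.5	2
NPF2.6	2
NPF2.7	2
NPF2.8	2
NPF2.9	2
NPF2.10	2
NPF2.11	2
NPF2.12	2
NPF2.13	2
NPF2.14	2
NPF3.1	3
NPF4.1	4
NPF4.2	4
NPF4.3	4
NPF4.4	4
NPF4.5	4
NPF4.6	4
NPF4.7	4
NPF5.1	5
NPF5.2	5
NPF5.3	5
NPF5.4	5
NPF5.5	5
NPF5.6	5
NPF5.7	5
NPF5.8	5
NPF5.9	5
NPF5.10	5
NPF5.11	5
NPF5.12	5
NPF5.13	5
NPF5.14	5
NPF5.15	5
NPF5.16	5
NPF6.1	6
NPF6.2	6
NPF6.3	6
NPF6.4	6
NPF7.1	7
NPF7.2	7
NPF7.3	7
NPF8.1	8
NPF8.2	8
NPF8.3	8
NPF8.4	8
NPF8.5	8
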