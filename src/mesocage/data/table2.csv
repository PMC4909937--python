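animal_id,entries,head_fixes,days_tested,entries_per_day_printed,fixes_per_day_printed
AB0090,9944,145,90,110.5,1.6
AB0573,5335,143,90,59.3,1.6
AB0592,5738,233,90,63.8,2.6
EL0115,8772,1072,90,97.5,11.9
EL0159,8879,619,90,98.7,6.9
EL0245,11195,425,90,124.4,4.7
EL0300,6345,1076,90,70.5,12.0
EL0377,7018,2021,90,78.0,22.5
EP0139,7742,178,90,86.0,2.0
EP0202,4237,932,90,47.1,10.4
EP0238,5636,176,90,62.6,2.0
GU0074,10512,0,25,420.5,0.0
GU0092,3525,39,25,141.0,1.6
GU0149,2191,133,25,87.6,5.3
GU0203,4173,40,25,166.9,1.6
GU0285,5036,107,25,201.4,4.3
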