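subject,cohort,sex,age,HR,CO,PAWP,mPAP
1,Pre-cap,F,75,68,4.0,12,38
2,Pre-cap,F,70,71,3.4,12,26
3,Pre-cap,F,34,72,6.7,15,38
4,Pre-cap,M,67,60,4.8,11,40
5,Pre-cap,F,71,85,4.6,14,22
6,Ipc-PH,M,71,56,4.7,10,15
7,Ipc-PH,M,69,77,4.8,13,23
8,Ipc-PH,M,66,64,4.9,20,31
9,Ipc-PH,M,80,74,5.1,16,28
10,Ipc-PH,M,56,60,5.8,18,32
11,Ipc-PH,F,67,59,5.8,20,32
12,Ipc-PH,M,67,75,9.3,22,38
13,Ipc-PH,F,69,81,7.8,16,25
14,Ipc-PH,F,70,83,6.3,18,30
15,Ipc-PH,F,77,76,5.5,14,25
16,Ipc-PH,M,58,74,6.8,16,26
17,Ipc-PH,F,52,81,7.6,11,17
18,Cpc-PH,F,76,55,3.8,20,44
19,Cpc-PH,F,78,62,3.0,24,46
20,Cpc-PH,F,77,76,4.5,16,32
21,Cpc-PH,F,77,69,6.8,20,46
22,Cpc-PH,F,84,84,2.7,20,45
23,No PH,F,68,88,6.0,8,18
24,No PH,F,74,80,4.3,11,20
25,No PH,F,65,92,8.1,12,22
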