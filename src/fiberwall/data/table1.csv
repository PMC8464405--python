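id,age,sex,bmi,smoker,htn,dm,dyslipidemia,cad
1,12,F,,Never,No,No,No,No
2,25,F,28.4,Never,No,No,No,No
3,26,M,22.9,Never,No,No,No,No
4,28,M,28.2,Never,No,No,No,No
5,38,F,35.4,Never,Yes,Yes,No,No
6,47,F,46.6,Current,No,No,No,Yes
7,55,F,39.7,Current,Yes,No,No,No
8,57,M,31.6,Never,Yes,Yes,Yes,No
9,59,F,21.7,Current,Yes,No,No,No
10,61,F,40.2,Never,Yes,No,No,No
11,63,F,28.3,Never,No,No,No,No
12,65,M,35.2,Current,Yes,Yes,Yes,No
13,69,M,46.6,Former,Yes,No,Yes,No
14,70,M,28.3,Former,Yes,No,Yes,Yes
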