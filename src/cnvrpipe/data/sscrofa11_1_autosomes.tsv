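chrom	length	is_autosome
1	274330532	1
2	151935994	1
3	132848913	1
4	130910915	1
5	104526007	1
6	170843587	1
7	121844099	1
8	138966237	1
9	139512083	1
10	69359453	1
11	79169978	1
12	61602749	1
13	208334590	1
14	141755446	1
15	140412725	1
16	79944280	1
17	63494081	1
18	55982971	1
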