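width_mm,length_mm,location,shape,encounters,passages
6,8,side,rectangle,76,0
6,10,side,rectangle,53,0
6,25,side,rectangle,131,2
6,210,side,rectangle,100,2
11,11,side,rectangle,112,10
15,15,side,rectangle,26,6
15,85,side,rectangle,120,41
15,120,side,rectangle,53,20
15,210,side,rectangle,24,8
17,19,side,rectangle,43,12
20,32,side,rectangle,87,34
20,40,side,rectangle,71,34
20,113,side,rectangle,56,28
35,84,side,rectangle,102,56
35,152,side,rectangle,81,49
35,210,side,rectangle,77,49
60,82,side,rectangle,70,45
60,120,side,rectangle,69,50
60,210,side,rectangle,13,8
4,6,roof,rectangle,68,0
6,6,roof,rectangle,147,0
6,8,roof,rectangle,314,9
6,13,roof,rectangle,165,7
6,21,roof,rectangle,90,9
6,25,roof,rectangle,170,17
6,40,roof,rectangle,53,5
6,60,roof,rectangle,56,4
6,77,roof,rectangle,140,9
6,148,roof,rectangle,63,4
8,13,roof,rectangle,234,21
8,38,roof,rectangle,30,2
8,60,roof,rectangle,45,9
11,13,roof,rectangle,202,35
11,38,roof,rectangle,31,4
11,59,roof,rectangle,83,38
11,80,roof,rectangle,46,16
13,17,roof,rectangle,136,62
13,40,roof,rectangle,72,27
13,160,roof,rectangle,118,45
15,17,roof,rectangle,117,29
15,40,roof,rectangle,63,18
15,60,roof,rectangle,69,32
15,76,roof,rectangle,55,22
15,160,roof,rectangle,52,23
21,22,roof,rectangle,103,48
21,40,roof,rectangle,77,36
21,60,roof,rectangle,66,29
21,77,roof,rectangle,61,33
21,160,roof,rectangle,95,39
30,30,roof,rectangle,70,49
30,60,roof,rectangle,94,51
30,80,roof,rectangle,37,26
15,210,side,triangle,68,19
21,210,side,triangle,42,17
42,210,side,triangle,90,49
8,,side,circle,43,2
35,,side,circle,120,61
40,,side,circle,153,90
70,,side,circle,43,31
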