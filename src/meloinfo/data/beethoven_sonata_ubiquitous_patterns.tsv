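# Relative-interval patterns occurring in all 32 Beethoven piano sonatas, by Markov order.
# stated_count = the phrase count stated in the source analysis text (may disagree with
# the number of listed patterns; the discrepancy is preserved, not resolved).
order	pattern	stated_count
0	[-2]	20
0	[-1]
0	[1]
0	[0]
0	[2]
0	[-3]
0	[3]
0	[5]
0	[-4]
0	[4]
0	[-5]
0	[12]
0	[-7]
0	[7]
0	[9]
0	[-12]
0	[8]
0	[-6]
0	[6]
0	[-9]
1	[1,1]	37
1	[-1,2]
1	[-1,-1]
1	[1,-2]
1	[0,1]
1	[3,3]
1	[0,2]
1	[1,-4]
1	[0,3]
1	[0,5]
1	[1,-1]
1	[-2,2]
1	[-2,5]
2	[-2,-4,-5]	12
2	[0,0,0]
2	[-1,-3,-5]
2	[2,4,5]
2	[-2,-3,-5]
2	[1,3,5]
2	[2,3,5]
2	[2,0,-1]
2	[-2,-3,-2]
2	[-1,0,2]
2	[1,3,1]
2	[-1,0,-1]
3	[-2,-3,-5,-7]	3
3	[-2,-4,-5,-7]
3	[-1,-3,-5,-6]
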