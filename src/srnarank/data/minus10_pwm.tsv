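#threshold	6.0
#log2-odds of a soft TATAAT consensus (0.7 consensus / 0.1 other) vs uniform background
#base	pos1	pos2	pos3	pos4	pos5	pos6
A	-1.321928094887	1.485426827170	-1.321928094887	1.485426827170	1.485426827170	-1.321928094887
C	-1.321928094887	-1.321928094887	-1.321928094887	-1.321928094887	-1.321928094887	-1.321928094887
G	-1.321928094887	-1.321928094887	-1.321928094887	-1.321928094887	-1.321928094887	-1.321928094887
T	1.485426827170	-1.321928094887	1.485426827170	-1.321928094887	-1.321928094887	1.485426827170
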