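term,valence
good,1.9
great,3.1
love,3.2
amazing,2.8
excellent,2.7
happy,2.7
kind,2.4
helpful,1.8
wonderful,2.7
best,3.2
thankful,2.2
comfortable,1.5
friendly,2.2
clean,1.6
quick,1.3
relieved,1.6
gentle,1.7
smooth,1.5
awesome,3.1
perfect,2.7
bad,-2.5
terrible,-2.1
awful,-2.0
horrible,-2.5
worst,-3.1
painful,-2.0
sad,-2.1
angry,-2.3
rude,-2.6
dirty,-1.7
slow,-1.2
scared,-1.9
miserable,-2.3
useless,-1.8
nightmare,-2.6
disappointed,-2.0
frustrating,-2.1
cold,-0.8
broken,-1.4
crowded,-1.1
annoying,-1.9
hate,-2.7
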