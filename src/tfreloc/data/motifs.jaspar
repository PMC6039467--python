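>RUNX RUNX
A  [   5   1   1   1   1   1   5  10   5 ]
C  [   5   1   1   1   1   1   5  10   5 ]
G  [   5  97   1  97  97   1   5  10  85 ]
T  [  85   1  97   1   1  97  85  70   5 ]
>ETS ETS
A  [  70   5  85   1   1  97  97   5   5  10 ]
C  [  10  85   5   1   1   1   1   5   5  10 ]
G  [  10   5   5  97  97   1   1  85   5  70 ]
T  [  10   5   5   1   1   1   1   5  85  10 ]
>GATA GATA
A  [  10  85   1  97   1  97  97   5  70 ]
C  [  70   5   1   1   1   1   1   5  10 ]
G  [  10   5  97   1   1   1   1  85  10 ]
T  [  10   5   1   1  97   1   1   5  10 ]
>AP1 AP1
A  [   5   1  97   1   1   1  85  10  10 ]
C  [   5   1   1  97   1  97   5  10  70 ]
G  [   5  97   1   1   1   1   5  10  10 ]
T  [  85   1   1   1  97   1   5  70  10 ]
>TEAD TEAD
A  [  10   5   1  97  97   1   1   5  10 ]
C  [  10   5   1   1   1   1   1   5  10 ]
G  [  10  85  97   1   1   1  97   5  70 ]
T  [  70   5   1   1   1  97   1  85  10 ]
>ETS_RUNX ETS_RUNX
A  [  70   5  85   1   1  97  97   5   5  25  25   5   1   1   1   1   1   5 ]
C  [  10  85   5   1   1   1   1   5   5  25  25   5   1   1   1   1   1   5 ]
G  [  10   5   5  97  97   1   1  85   5  25  25   5  97   1  97  97   1   5 ]
T  [  10   5   5   1   1   1   1   5  85  25  25  85   1  97   1   1  97  85 ]
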