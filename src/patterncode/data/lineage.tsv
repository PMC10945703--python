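cell	parent	founder	stages
AB	P0	AB	2
ABa	AB	AB	4
ABal	ABa	AB	8
ABala	ABal	AB	15
ABalaa	ABala	AB	28
ABalaaa	ABalaa	AB	51
ABalaaaa	ABalaaa	AB	102
ABalaaap	ABalaaa	AB	102
ABalaap	ABalaa	AB	51
ABalaapa	ABalaap	AB	102
ABalaapp	ABalaap	AB	102
ABalap	ABala	AB	28
ABalapa	ABalap	AB	51
ABalapaa	ABalapa	AB	102
ABalapap	ABalapa	AB	102
ABalapp	ABalap	AB	51
ABalappa	ABalapp	AB	102
ABalappp	ABalapp	AB	102
ABalp	ABal	AB	15
ABalpa	ABalp	AB	28
ABalpaa	ABalpa	AB	51
ABalpaaa	ABalpaa	AB	102
ABalpaap	ABalpaa	AB	102
ABalpap	ABalpa	AB	51
ABalpapa	ABalpap	AB	102
ABalpapp	ABalpap	AB	102
ABalpp	ABalp	AB	28
ABalppa	ABalpp	AB	51
ABalppaa	ABalppa	AB	102
ABalppap	ABalppa	AB	102
ABalppp	ABalpp	AB	51
ABalpppa	ABalppp	AB	102
ABalpppp	ABalppp	AB	102
ABar	ABa	AB	8
ABara	ABar	AB	15
ABaraa	ABara	AB	28
ABaraaa	ABaraa	AB	51
ABaraaaa	ABaraaa	AB	102
ABaraaap	ABaraaa	AB	102
ABaraap	ABaraa	AB	51
ABaraapa	ABaraap	AB	102
ABaraapp	ABaraap	AB	102
ABarap	ABara	AB	28
ABarapa	ABarap	AB	51
ABarapaa	ABarapa	AB	102
ABarapap	ABarapa	AB	102
ABarapp	ABarap	AB	51
ABarappa	ABarapp	AB	102
ABarappp	ABarapp	AB	102
ABarp	ABar	AB	15
ABarpa	ABarp	AB	28
ABarpaa	ABarpa	AB	51
ABarpaaa	ABarpaa	AB	102
ABarpaap	ABarpaa	AB	102
ABarpap	ABarpa	AB	51
ABarpapa	ABarpap	AB	102
ABarpapp	ABarpap	AB	102
ABarpp	ABarp	AB	28
ABarppa	ABarpp	AB	51
ABarppaa	ABarppa	AB	102
ABarppap	ABarppa	AB	102
ABarppp	ABarpp	AB	51
ABarpppa	ABarppp	AB	102
ABarpppp	ABarppp	AB	102
ABp	AB	AB	4
ABpl	ABp	AB	8
ABpla	ABpl	AB	15
ABplaa	ABpla	AB	28
ABplaaa	ABplaa	AB	51
ABplaaaa	ABplaaa	AB	102
ABplaaap	ABplaaa	AB	102
ABplaap	ABplaa	AB	51
ABplaapa	ABplaap	AB	102
ABplaapp	ABplaap	AB	102
ABplap	ABpla	AB	28
ABplapa	ABplap	AB	51
ABplapaa	ABplapa	AB	102
ABplapap	ABplapa	AB	102
ABplapp	ABplap	AB	51
ABplappa	ABplapp	AB	102
ABplappp	ABplapp	AB	102
ABplp	ABpl	AB	15
ABplpa	ABplp	AB	28
ABplpaa	ABplpa	AB	51
ABplpaaa	ABplpaa	AB	102
ABplpaap	ABplpaa	AB	102
ABplpap	ABplpa	AB	51
ABplpapa	ABplpap	AB	102
ABplpapp	ABplpap	AB	102
ABplpp	ABplp	AB	28
ABplppa	ABplpp	AB	51
ABplppaa	ABplppa	AB	102
ABplppap	ABplppa	AB	102
ABplppp	ABplpp	AB	51
ABplpppa	ABplppp	AB	102
ABplpppp	ABplppp	AB	102
ABpr	ABp	AB	8
ABpra	ABpr	AB	15
ABpraa	ABpra	AB	28
ABpraaa	ABpraa	AB	51
ABpraaaa	ABpraaa	AB	102
ABpraaap	ABpraaa	AB	102
ABpraap	ABpraa	AB	51
ABpraapa	ABpraap	AB	102
ABpraapp	ABpraap	AB	102
ABprap	ABpra	AB	28
ABprapa	ABprap	AB	51
ABprapaa	ABprapa	AB	102
ABprapap	ABprapa	AB	102
ABprapp	ABprap	AB	51
ABprappa	ABprapp	AB	102
ABprappp	ABprapp	AB	102
ABprp	ABpr	AB	15
ABprpa	ABprp	AB	28
ABprpaa	ABprpa	AB	51
ABprpaaa	ABprpaa	AB	102
ABprpaap	ABprpaa	AB	102
ABprpap	ABprpa	AB	51
ABprpapa	ABprpap	AB	102
ABprpapp	ABprpap	AB	102
ABprpp	ABprp	AB	28
ABprppa	ABprpp	AB	51
ABprppaa	ABprppa	AB	102
ABprppap	ABprppa	AB	102
ABprppp	ABprpp	AB	51
ABprpppa	ABprppp	AB	102
ABprpppp	ABprppp	AB	102
C	P2	C	8
Ca	C	C	15
Caa	Ca	C	28;51
Caaa	Caa	C	102
Caap	Caa	C	102
Cap	Ca	C	28;51
Capa	Cap	C	102
Capp	Cap	C	102
Cp	C	C	15
Cpa	Cp	C	28;51
Cpaa	Cpa	C	102
Cpap	Cpa	C	102
Cpp	Cp	C	28;51
Cppa	Cpp	C	102
Cppp	Cpp	C	102
D	P3	D	28
Da	D	D	51
Daa	Da	D	102
Dap	Da	D	102
Dp	D	D	51
Dpa	Dp	D	102
Dpp	Dp	D	102
E	EMS	E	8
EMS	P1	P-line	4
Ea	E	E	15;28
Eal	Ea	E	51
Eala	Eal	E	102
Ealp	Eal	E	102
Ear	Ea	E	51
Eara	Ear	E	102
Earp	Ear	E	102
Ep	E	E	15;28
Epl	Ep	E	51
Epla	Epl	E	102
Eplp	Epl	E	102
Epr	Ep	E	51
Epra	Epr	E	102
Eprp	Epr	E	102
MS	EMS	MS	8
MSa	MS	MS	15
MSaa	MSa	MS	28
MSaaa	MSaa	MS	51
MSaaaa	MSaaa	MS	102
MSaaap	MSaaa	MS	102
MSaap	MSaa	MS	51
MSaapa	MSaap	MS	102
MSaapp	MSaap	MS	102
MSap	MSa	MS	28
MSapa	MSap	MS	51
MSapaa	MSapa	MS	102
MSapap	MSapa	MS	102
MSapp	MSap	MS	51
MSappa	MSapp	MS	102
MSappp	MSapp	MS	102
MSp	MS	MS	15
MSpa	MSp	MS	28
MSpaa	MSpa	MS	51
MSpaaa	MSpaa	MS	102
MSpaap	MSpaa	MS	102
MSpap	MSpa	MS	51
MSpapa	MSpap	MS	102
MSpapp	MSpap	MS	102
MSpp	MSp	MS	28
MSppa	MSpp	MS	51
MSppaa	MSppa	MS	102
MSppap	MSppa	MS	102
MSppp	MSpp	MS	51
MSpppa	MSppp	MS	102
MSpppp	MSppp	MS	102
P0		P-line	1
P1	P0	P-line	2
P2	P1	P-line	4
P3	P2	P-line	8;15
P4	P3	P4	28;51
Z2	P4	P4	102
Z3	P4	P4	102
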