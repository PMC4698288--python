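variant	locus
T9185C	MT-ATP6
T3931C	MT-ND1
G10573A	MT-ND4L
T9176C	MT-ATP6
G3392A	MT-ND1
G13042A	MT-ND5
T9176G	MT-ATP6
G3733A	MT-ND1
T12706C	MT-ND5
G8839A	MT-ATP6
T3949C	MT-ND1
T13540C	MT-ND5
T8993C	MT-ATP6
G3697A	MT-ND1
G13513A	MT-ND5
T8993G	MT-ATP6
T3679C	MT-ND1
A13514G	MT-ND5
C6567T	MT-CO1
G3922A	MT-ND1
G13178A	MT-ND5
T6210C	MT-CO1
G4831A	MT-ND2
T12797C	MT-ND5
T15843C	MT-CYB
G4975A	MT-ND2
T13847C	MT-ND5
T15813G	MT-CYB
T10158C	MT-ND3
T13271C	MT-ND5
T15209C	MT-CYB
T10191C	MT-ND3
C14568T	MT-ND6
G3700A	MT-ND1
G10197A	MT-ND3
C14482A	MT-ND6
C4171A	MT-ND1
G12056A	MT-ND4
C14482G	MT-ND6
G3460A	MT-ND1
T11613C	MT-ND4
T14484C	MT-ND6
T4222C	MT-ND1
C11777A	MT-ND4
A14495G	MT-ND6
G3635A	MT-ND1
G11778A	MT-ND4
G14459A	MT-ND6
G4148A	MT-ND1
G11475A	MT-ND4
T14487C	MT-ND6
G3890A	MT-ND1
T10663C	MT-ND4L
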