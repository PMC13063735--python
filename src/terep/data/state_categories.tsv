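state	category
TssA	cis-regulatory
TssFlnk	cis-regulatory
TssBiv	cis-regulatory
EnhA1	cis-regulatory
EnhA2	cis-regulatory
EnhWk	cis-regulatory
EnhG	cis-regulatory
EnhBiv	cis-regulatory
Tx	transcription
TxWk	transcription
ZNF_Rpts	other
Het	heterochromatin
ReprPC	heterochromatin
ReprPCWk	heterochromatin
Quies	quiescent/low
Low	quiescent/low
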