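# Activity motifs for c-di-GMP signaling domains.
# Essential residues are single letters or bracketed alternatives;
# x(n) is a spacer of exactly n residues, x(n,m) a spacer of n..m residues.
GGDEF	D x(7) N x(8) D x(21) R x(1) [GSA] G [DE] E F
EAL	E x(55,58) N x(31) E x(2) E x(26) D x(20) K x(35) E
PILZ	R x(3) R x(20,30) [DN] x(1) [SA] x(2) G
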