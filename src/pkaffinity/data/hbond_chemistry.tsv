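# Donor/acceptor roles for heavy atoms, matched by (residue_name, atom_name).
# residue_name and atom_name accept fnmatch wildcards; first matching row wins.
# role: donor | acceptor | both
residue_name	atom_name	role
*	OG	both
*	OG1	both
*	OH	both
*	OW	both
SER	O*	both
THR	O*	both
TYR	OH	both
*	N*	donor
*	O*	acceptor
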