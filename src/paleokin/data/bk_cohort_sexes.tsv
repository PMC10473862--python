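sample	group	sex
BAD002	Baden	M
S9	Bk-I	M
S1	Bk-II	M
S2	Bk-II	M
S4	Bk-II	M
S5	Bk-II	M
S6	Bk-II	M
S7	Bk-II	F
S8	Bk-II	M
S10	Bk-II	M
S11	Bk-II	M
S13	Bk-II	F
S45	Bk-II	M
S14	Bk-III	F
S15	Bk-III	M
S16	Bk-III	M
S17	Bk-III	M
S18	Bk-III	M
S19	Bk-III	M
S20	Bk-III	M
S21	Bk-III	F
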