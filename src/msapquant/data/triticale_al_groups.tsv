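sample	group
NT1	NT
NT2	NT
NT3	NT
NT4	NT
NT5	NT
T1	T
T2	T
T3	T
T4	T
T5	T
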