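# Core and core-associated clock genes excluded from "non-core-clock"
# signal comparisons.  One gene symbol per line; edit freely.
Per1
Per2
Cry2
Dbp
Nr1d1
Nr1d2
Tef
Hlf
Gm129
Rorc
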