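# Mini is-a hierarchy: child_code<TAB>parent_code<TAB>system
282825002	49436004	SCT
426749004	49436004	SCT
440059007	49436004	SCT
312442005	5370000	SCT
79619009	368009	SCT
60573004	368009	SCT
426263006	368009	SCT
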