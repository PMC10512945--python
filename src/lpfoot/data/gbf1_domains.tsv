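# Domain/linker tiling for human GBF1 (1859 aa).  The HDS3 span (1532-1721)
# is from the primary description of the domain; other boundaries are set to
# honour the published per-site domain assignments (see docs/methods.md) and
# approximate the domain-assignment literature.
name	start	end	kind
DCB	1	217	structured
linker between DCB and HUS	218	389	linker
HUS	390	562	structured
linker between HUS and Sec7d	563	710	linker
Sec7d	711	890	structured
linker between Sec7d and HDS1	891	910	linker
HDS1	911	1085	structured
linker between HDS1 and HDS2	1086	1090	linker
HDS2	1091	1270	structured
linker between HDS2 and HDS3	1271	1531	linker
HDS3	1532	1721	structured
C-terminal tail	1722	1859	linker
Sec7d:8	830	844	helix
Sec7d:9	846	860	helix
Sec7d:10	866	882	helix
HDS2:3	1195	1215	helix
HDS2:5	1248	1266	helix
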