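# Shipped default domain map for the 5696-residue AAA-ATPase reference
# protein: six N-terminal AAA modules, a long linker, a C-terminal MIDAS
# domain.  Residue boundaries are a synthetic configuration (no published
# per-residue annotation is bundled); report boundary-dependent results
# together with the map used.
protein_length: 5696
vicinity_window: 100
intervals:
- {label: AAA1, start: 211, end: 660}
- {label: AAA2, start: 661, end: 960}
- {label: AAA3, start: 961, end: 1310}
- {label: AAA4, start: 1311, end: 1650}
- {label: AAA5, start: 1651, end: 1990}
- {label: AAA6, start: 1991, end: 2320}
- {label: linker, start: 2321, end: 4770}
- {label: MIDAS, start: 5596, end: 5696}
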