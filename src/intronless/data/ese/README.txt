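# Predefined ESE motif sets are not bundled.
#
# The motif lists for RESCUE-ESE, ESR, Ke-ESE400, PESE and INT3 are
# published as supplements of the studies that defined them.  To make a
# predefined name loadable, place its list here as <NAME>.txt
# (e.g. RESCUE-ESE.txt), one hexamer per line, '#' comments allowed,
# RNA (U) accepted.  Alternatively pass any motif file directly via
# load_ese_set()/--ese-set.
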