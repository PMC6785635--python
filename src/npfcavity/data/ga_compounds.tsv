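# Gibberellin registry: formula-derived oxygen counts; monoprotic pKa default.
name	formula	pKa	external_conc_uM
GA1	C19H24O6	4.0	50.0
GA3	C19H22O6	4.0	50.0
GA4	C19H24O5	4.0	100.0
GA7	C19H22O5	4.0	50.0
GA8	C19H24O7	4.0	50.0
GA9	C19H24O4	4.0	50.0
GA12	C20H28O4	4.0	50.0
GA19	C20H26O6	4.0	50.0
GA24	C20H26O5	4.0	50.0
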