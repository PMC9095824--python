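rCRS
	M	T489C C10400T T14783C G15043A
		M2	A10102G C4014T
		M3	G7062A G15806T
		M4	G11099C G3711A
		M5	C11882T G4035T
		M6	G10186T A7515T
		M7	G9326A C14705G
		M8	A8327T T15772G
			C	A653G
			D	T3645G
		M9	C4477T A13981C
			E	T5743C
			G	T8732G
		M10	T2291G C14579G
		M11	C1075T A10884T
		M12	T6315G G16405C
		M18	G13189C C2751G
		M25	G6038C C4265G
		M30	G2206C T5982C
		M33	A1767T C7508G
		M39	T11676A G7660A
		M65	C14043A A7453G
		M67	G795T A6467C
	N	G8701A C9540T G10398A C10873T
		N5	A16148G C7463A
		N9	G7680T C13813T
		A	C3831G
		W	A5214T
		X	T10807A
		R	T12705C T16223C
			R0	C12009A A6024C
				HV	G15222A C7918A
					H	G12851C C1569T
					HV0	T2792G G8734T
						HV0e	T12987G G11268C
			R1	C13238T A4515T
			R2	C9900G T12589A
			R5	T9586C T4875G
			R6	A15047C A8325G
			R7	T12875C A8726T
			R8	A9381T A5652G
			R22	G14090A A4556G
			R30	G7372A G8440C
			R31	T7610C C11837A
			R32	C8546G G4255T
			B	A12596C
			F	G2572A
			JT	G3602C C3130A
				J	A10798T
				T	G3216C
			U	A11467G A12308G G12372A
				U1	G14771T C6161G
				U2	T15513A G6949A
					U2a	A9171T
					U2b	C6408T
				U3	T10508G T10596A
				U4	A8228G G13512T
				U5	A11442G C16180A
				U7	A13591G A8021T
				U8	T6889A A8216T
					K	C1402A
				U9	T3666C A3960C
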