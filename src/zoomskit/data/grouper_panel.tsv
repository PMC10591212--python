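# tolerance=0.2
name	chain	start	sequence	masses	states	species_specific_for	diagnostic	isobaric_in	note	E_aeneus	E_costae	E_marginatus	E_caninus
COL1a2 568	COL1a2	568	GEGGHRGPDGNAGR	1319.6		E_caninus	0		anomaly: printed mass is ~17 Da below the computed [M+H]+ of the printed sequence (~1336.6); mass also reported in a Caribbean comber (Serranus tigrinus) - use only in combination with other biomarkers				x
COL1a2 568	COL1a2	568	GEAGHRGPDGNAGR	1350.6			1					x	x	x	l
COL1a3 934	COL1a3	934	GFTGMQGLPGPAGAHGER	1755.78			1			x		x	x
COL1a3 934	COL1a3	934	GFTGMQGLPGPAGVHGER	1783.8/1799.8		E_costae	1				x
COL1a3 271	COL1a3	271	GEPGPAGVQGLSGPSGEEGKR	1965.9			1			l	l	x	l
COL1a3 271	COL1a3	271	GEPGPAGVQGLPGPSGEEGKR	1991.9			1			x	x		x
COL1a2 662	COL1a2	662	PSGPAGPAGQSGPPGASGPAGPTGAR	2157.0		E_caninus	1		begins with proline: implies a preceding K/R-P cleavage				x
COL1a1 793	COL1a1	793	GFSGLPGPAGEPGKPGPSGPGGER	2178.0			1		isobaric with GFPGLPGPAGEAGKPGPSGPGGER carrying one extra hydroxylation	l		x
COL1a1 793	COL1a1	793	GFPGLPGPAGEAGKPGPSGPGGER	2178.0			1		isobaric with GFSGLPGPAGEPGKPGPSGPGGER carrying one fewer hydroxylation	x		l
COL1a2 361	COL1a2	361	GLPGSPGSSGPPGKEGAAGPAGQDGR	2309.1			1			x*		x	x
COL1a2 361	COL1a2	361	GLPGSPGSSGPPGKEGPAGPSGQDGR	2351.1		E_costae	1				x
COL1a1 705	COL1a1	705	VGPPGPSGNPGPPGPAGGTGKEGPKGNR	2542.97		E_marginatus	1					x
COL1a1 705	COL1a1	705	VGPPGPSGNPGPPGPAGGPGKEGPKGNR	2537.6			1			x*	x*		x*
COL1a3 934	COL1a3	934	GFTGMQGLPGPAGAHGERGPAGASGPAGPR	2731.1			1			x		x	x
COL1a3 934	COL1a3	934	GFTGMQGLPGPAGVHGERGPAGASGPAGPR	2775.0		E_costae	1				x
COL1a1 586	COL1a1	586	GLTGPLGLPGPAGATGDKGEPGPAGPVGPGGAR	2851.34/2867.34			1				x	x	x
COL1a1 586	COL1a1	586	GLTGPLGLPGPAGATGDKGESGPAGPVGPAGAR	2855.33/2871.33		E_aeneus	1		most informative single marker: present only in E. aeneus	x
COL1a3 238	COL1a3	238	GPAGAQGAVGAPGPKGNSGDPGASGPKGEPGAK	2814.4		E_costae	1				x*
COL1a3 238	COL1a3	238	GPAGAQGAVGAPGPKGNNGDPGASGPKGEPGAK	2889.2			1			x*		x	x
COL1a1 817	COL1a1	817	GPPGPMGPPGLAGAPGEPGREGSPGNEGSAGR	2915.3		E_aeneus	1			x*
COL1a1 817	COL1a1	817	GPPGPMGPPGLAGAPGEPGREGSPGNEGSAGR	2947.3			1			x*	x	l
COL1a1 817	COL1a1	817	GPPGPMGPPGLAGAPGEPGREGSPGNEGSAGR	2867.3			1				x	l	x
COL1a1 817	COL1a1	817	GPPGPMGPPGLAGAPGEPGREGSPGSEGSAGR	2888.3		E_marginatus	1					x*
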