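gene	variant_id	position	wt	mut	wt_seq	mut_seq	expected
AGA	rs386833429	15	L	R	MARKSNLPVLLVPFLLCQALVRCS	MARKSNLPVLLVPFRLCQALVRCS	decay
CTSK	rs1057517252	7	L	P	MWGLKVLLLPVVSFAL	MWGLKVPLLPVVSFAL	decay
CTSK	rs1057517252	9	L	P	MWGLKVLLLPVVSFAL	MWGLKVLLPPVVSFAL	decay
GRN	rs63751243	9	A	D	MWTLVSWVALTAGLVAGT	MWTLVSWVDLTAGLVAGT	decay
INS	rs121908259	6	R	H	MALWMRLLPLLALLALWGPDPAAAF	MALWMHLLPLLALLALWGPDPAAAF	no_decay
INS	rs121908278	6	R	C	MALWMRLLPLLALLALWGPDPAAAF	MALWMCLLPLLALLALWGPDPAAAF	no_decay
LHCGR	rs4539842	16	L	Q	MKQRFSALQLLKLLLLLQPPLPRAL	MKQRFSALQLLKLLLQLQPPLPRAL	decay
LHCGR	rs917607255	10	L	P	MKQRFSALQLLKLLLLLQPPLPRAL	MKQRFSALQPLKLLLLLQPPLPRAL	no_decay
NDP	rs104894879	13	L	R	MRKHVLAASFSMLSLLVIMGDTDSK	MRKHVLAASFSMRSLLVIMGDTDSK	decay
POMC	rs779629993	15	A	G	MPRSCCSRSGALLLALLLQASMEVRGW	MPRSCCSRSGALLLGLLLQASMEVRGW	no_decay
PTH	rs104894271	18	C	R	MIPAKDMAKVMIVMLAICFLTKSDGK	MIPAKDMAKVMIVMLAIRFLTKSDGK	decay
SERPINE1	rs6092	15	A	T	MQMSPALTCLVLGLALVFGEGSAV	MQMSPALTCLVLGLTLVFGEGSAV	no_decay
TGFB1	rs1800470	10	P	L	MPPSGLRLLPLLLPLLWLLVLTPGRPAAGL	MPPSGLRLLLLLLPLLWLLVLTPGRPAAGL	no_decay
UGT1A1	rs111033541	15	L	R	MAVESQGGRPLVLGLLLCVLGPVVSHAG	MAVESQGGRPLVLGRLLCVLGPVVSHAG	decay
LIPA	rs1051338	16	T	P	MKMRFLGLVVCLVLWTLHSEGSGG	MKMRFLGLVVCLVLWPLHSEGSGG	no_decay
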