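streptococcaceae_class	lactobacillaceae_class	count	examples
universal	universal	5	CcpA, CopR, NagR, PurR, Rex
universal	mosaic	10	AdcR, ArgR, BirA, CtsR, FabT, FruR, GlnR, HrcA, MalR, NrdR
mosaic	universal	0	n/a
mosaic	mosaic	31	CcpB, CelR, FucR, GalR, GutR, LacR, MdxR, MleR, MntR, MtaR, MtlR, MurR, NiaR, NrtR, PadR, PerR, PflR, ScrR, TagR, TreR, UxuR
universal	absent	3	CmbR, CodY, PipR
mosaic	absent	20	AgaR, AlsR, CelQ, HomR, NanR, NmlR, PdxR, RegR, Rgg, RgrA, RliC, SczA, SgaR
absent	universal	1	LexA
absent	mosaic	32	AguR, AraR, CggR, DeoR, ExuR, FatR, HxlR, IolR, NihR, RbsR, RpiR, SdaR, XylR, Zur
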