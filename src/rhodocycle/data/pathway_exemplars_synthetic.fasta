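>blh_exemplar_synthetic gene=blh synthetic exemplar for homology screening
MHAYLSPADDKVRITAEKTYQDVNQETDLGSSGDAKLNTPHPFSHFVAAAEFTITGRYVI
SKVKLKKVAKPWIQQSNKMAVNAFFMEDKNQMHPLSLTATYAFSFQITRHTPSKVLTQLQ
MVDFASEACLYSEPFMAELLKELVSVNTLVGGTSDRSSKMLIATALMPYRGCGWGKHNKI
QIDHLATLDKRSIWVSHLEKPSHDREFEARLSIMTSVRFILSYCGIISTIPLSLKDPKYF
KRWRACVATAQITATESPDRDTFGKRDAVVVRPARRLAFLGSKPMAPGDQ
>crtE_exemplar_synthetic gene=crtE synthetic exemplar for homology screening
RSGGTPRASYSPRTSNKTVARTEDRSDLVNNSTENTVRTIRNPQDLHNKEESNRPYQQEV
DYYPLQLQKEAKMLQTLDFAYKFWIRTPWNQPDHLTPKITMKYAEPDPNHYCAQACSDNR
ERQGRFFQSVLSEHLIVEDYVLLPVLHYGICLGFTLTDKGIEVLGKRNKGVVEIKTHLSV
DVQAIFSEDQLDMSKIRIKATRLSSTIDWDDPVYYGCYLLVLTIHVGAEVAVFTCAEGRA
FVTKPQNTVLSKRKNGDTEPKGKDQQVEPSIAHGIGQAEMLNTIKFFLPSTIDDVNDLWA
>crtB_exemplar_synthetic gene=crtB synthetic exemplar for homology screening
EAFGKNKVVDVIHSAVISVLGTSDKKEKGDDPEVVGRDFLVAHPRPKDKSVGHMFHIRFS
LKKSIQISELSMELFGNFRDSFPKNQLTCFARIYHINEDDGPIIGSVNPASLPSPIRSGY
AMGQKHKHCNAAASREDLDAMKVKTITQESTLIVNLTAAHAPNQDFEREIVRKQVKYMAG
VAAVVDFSSTFFTAQVAEHVPVWGLSVPDGYNREPSGRRETELYAILLEGSLFENYKVEE
LTSSTVIETTHPKNTLSLTVIVVWYEFEEATATNGCFAGIRKKFLKYADVEALIQGIIPQ
LKETEERATM
>crtI_exemplar_synthetic gene=crtI synthetic exemplar for homology screening
IPSLILSIFGHKVGCELSKHVRGCTHVRLVGSETHHITGCDYFSELLDIKVSSGAVWMDV
GEEPLLVFSIENTLLWGVVTVVFGAVEKSELAKSLYNIIPRVFVLKVAMERKTVLGYDSY
GRRLLFFLRHRLRFHSLSVVFQQLMHTVLLNHTNRNLISDAPTSEHELLSIIKLLKLAPC
LMVLPKLRPNNESPLNPREDKWFDNLHPDTDLGLGEFEYRTLATGNPRTIKETYGQKVLM
EGIMEERLKAFYTGTVWGPALGLPMASFLSIHDPKDNTSLDYKRLLSQGVGSIDDVNPAQ
AAPIMGVLHGKAVGDQYLFQEFVETFKWLGVTNPGGSLLAKEHDRAPIVSYNEVMRRIDS
VGRSIYGGGGVWDTWGKANIMKSSEVHKKFLELDISPVADVKPQQAKQIQQLDKLFECVL
GEFFHRNSRQSSETKDSFQLVVLGSFDFHACDLDMVNDYLKSVTRLEISECKYEPQRLML
IPGIQKRLRI
>crtY_exemplar_synthetic gene=crtY synthetic exemplar for homology screening
RRSGSHRPAEAKDTDTAKTATNIVDQLIIIFFKAPTFEGYLCHREKENVIEYDPLRQGII
LIVHNFDGYFTCELEAVARESLELTDLGMAIDALGDLHIGLQIVSANVWEGEGWGLPNSE
TGALLYDRRRLLPKKPLTLSMELISGYAEIPTSKSGGGTGDRIFQLHWKNTGQDQIGVDR
AVLKRGPGAQEDHAFPTVEDFIGANPLNTVVETQPYSLLYAKIVLFFYKRVVKLTTADHA
RTRTAAHTEFGAKTAYENCANHDLGQTMGKSEGLGVLYLPSVFGKKQPGLEIQNKGWTLI
TIVILAFSSPGAAIREYYEVKLPPFAYATNMVLGNLVITLIRYETEGTSRRKVYLLTRSH
ISSLISQGLTFDGAVGISLL
>rhodopsin_exemplar gene=rhodopsin bacteriorhodopsin mature sequence as rhodopsin exemplar
QAQITGRPEWIWLALGTALMGLGTLYFLVKGMGVSDPDAKKFYAITTLVPAIAFTMYLSM
LLGYGLTMVPFGGEQNPIYWARYADWLFTTPLLLLDLALLVDADQGTILALVGADGIMIG
TGLVGALTKVYSYRFVWWAISTAAMLYILYVLFFGFTSKAESMRPEVASTFKVLRNVTVV
LWSAYPVVWLIGSEGAGIVPLNIETLLFMVLDVSAKVGFGLILLRSRAIFGEAEAPEPSA
GDGAAATSD
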