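species	leader	core	recognition	printed_mass	label	detected	expressed
A_rimosa	MSDINSTRLP	IWGIGCNP	SVGDEVTALLTRGEA	918.3541	alpha-amanitin	no	
A_rimosa	MSDINATRLP	IWGIGCNP	SVGDEVTALLASGEA	918.3541	alpha-amanitin	no	
A_rimosa	MSDINATRLP	IWGIGCDP	CVGDDVAALTTRGEA	919.3382	beta-amanitin	no	
A_rimosa	MSDINATRVP	AWLVDCP	CVGDDISRLLTRGEK	846.3217	phallacidin	no	
A_rimosa	MSDINATRLP	AWDSKHP	CVGDDVSRLLTRGE	821.3820		no	
A_rimosa	MSDINATRLP	AWDSKHP	CVGDDISRLLTRGE	821.3820		no	
A_rimosa	MSDINATRVP	AWLAECP	CVGDDISHLLTRGE	770.3421		no	
A_rimosa	MSDINASRLP	FFIIIVKP	CGNPYVSDDVNSTLTRGE	957.6052		no	
A_rimosa	MSDINTSRLP	FIPLGIITILP	CVSDDVNTTITRGD	1177.7475		yes	
A_rimosa	MSDINTACLP	FLFPVIPP	CLSEDANVVVLNSGE	910.5317		no	
A_rimosa	MSDINVTRLP	FFPIVFIPP	CI	1057.6000		no	
A_rimosa	MSDINIARLP	IFWFIYFP	CVGDDVDNTLSRGE	1113.5688		no	
A_rimosa	MSDINVTRLP	IFLIMFIPP	CIGDDAASILKQGE	1071.6191		no	
A_rimosa	MSDINTSCLP	IFIAFPIPP	CVSDDIQTVLTRGE	995.5844		no	
A_rimosa	MSDTNTACLP	IFIAFPIPP	CVSDDIQTVLTRGE	995.5844		no	
A_rimosa	MSDINASRLP	ILKKPWAP	SVCDDVNSTLTRGE	933.5800		no	
A_rimosa	MSDINVARLP	ISDPTAYP	CVGDDIQAVVKRGE	844.3967		yes	
A_rimosa	MSDINATRLP	IIIVLGLIIP	LCVSDIEMILTRGE	1044.7311		no	
A_rimosa	MSDINASRLP	IILAPIIP	CISDDVNTTLTCAE	830.5630		no	
A_rimosa	MSDINTTGLP	HFYNLMPP	CFSDDTGMVLVRGE	999.4637		no	
A_rimosa	MSDINATRLP	HPFPLGLQP	CAGDVDNFTLIKGE	986.5338		no	
A_rimosa	MSDINASCLP	LILVANGMAYV	SDDVSPTLTRGE	1144.6315		no	
A_rimosa	MSDINTARLP	SYIPFPPP	CLSEDTNAVLMLGE	898.4589		no	
A_rimosa	MSDINTARLP	SYIPFPPP	CLSEDTNAVLMLGE	898.4589		no	
A_rimosa	MSDINTSRFP	SYGYRAFP	CVGDDVEMVLMHGE	941.4396		no	
A_rimosa	MSDINVTRLP	VLVFIFFLP	CISDDAASIIKLGE	1075.6470		no	
A_rimosa	MSDIDTTRLP	LILFTLQP	SIGDDVNPTLTRGEK	925.5637		no	
A_rimosa	MSDIHAARLP	FPTRPVFP	SAGDDMIEVVLGRGE	941.5123		yes	
A_rimosa	MSDNNAARLP	FYFYLGIP	SDDAHPILTRGERLA	1000.5058		no	
A_rimosa	MSDTNTARLP	ILFIQLEIP	CISDDVHPVLTRGE	1066.6427		no	
A_rimosa	MSDVNTTRLP	FNFFRFPYP	CICDDSEKVLELGE	1215.5866		no	
A_rimosa	MSEINTARFP	NHGHRTIP	CVGDDIEMVLMHGE	912.4678		no	
A_rimosa	MSEINTSRLP	LVFIPPYFAP	CVSDDIQMVLTLGE	1144.6321		no	
A_rimosa	MFDMNTTCLP	GFIIYAYV	GDDVNHTLTRGE	926.4902		no	
A_rimosa	MLDINTARLP	FSLPTFPP	CVSDEIDVVLKRGE	886.4589		no	
A_rimosa	MLDINATRFP	LGRPTHLP	CVGDDVNYIL	871.5028		no	
A_rimosa	MTDINDARLP	ILLLIFFWIP	CANDDDENILNRG	1255.7733		no	
A_rimosa	MTDINDTRLP	FVWILWLWLA	CVGDDTSILNRGE	1327.7481		no	
A_rimosa	MPDINVTRLP	LLIIVLLTP	CISDDNNILNRGK	975.6732		no	
A_exitialis	MSDINATRLP	IWGIGCNP	CVGDDVTSVLTRGEA	918.3541	alpha-amanitin	no	
A_exitialis	MSDINATRLP	IWGIGCDP	CVGDDVTALLTRGEA	919.3382	beta-amanitin	no	
A_exitialis	MSDINATRLP	AWLVDCP	CVGDDVNRLLTRGE	846.3217	phallacidin	no	
A_exitialis	MSDINATRLP	AWLTDCP	CVGDDVNRLLTRGE	786.3371		no	
A_exitialis	MSDINTTRLP	FVFVASPP	CVGDDIAMVLTRGE	844.4483		yes	
A_exitialis	MSDINTARLP	FIWVFGIP	GDDIGTVLTRGEK	959.5269		no	
A_exitialis	MSDINLTRLP	GIIAIIP	CVGDDDDVNSTLTRGQ	677.4476		no	
A_exitialis	MSDINATRLP	IILAPVIP	CISDDNDPTLTRGQ	816.5473		no	
A_exitialis	MSDINTARLP	IPIPPFFFP	FVSDDIEIVLRRGEK	1055.5844		no	
A_exitialis	MSDINTARLP	IPIPPFFFP	FVSDDIEIVLRRGEK	1055.5844		no	
A_exitialis	MSDINATRLP	IGRPQLLP	CVGGDVNYILISGEK	874.5389		no	
A_exitialis	MSDINPTRLP	IFWFIYFP	CVSDVDSTLTRGE	1113.5688		no	
A_exitialis	MSDINTARLP	IYRPPFYALP	CVGDDIQAVLTRGE	1217.6597		no	
A_exitialis	MSDINTARLP	IIWIIGNP	CVSDDVERILTRGE	906.5327		no	
A_exitialis	MSDINVIRAP	LLILSILP	CVGDDIEVLRRGE	862.5892		no	
A_exitialis	MSDINATRLP	LFFPPDFRPP	CVGDADNFTLTRGEK	1213.6284		yes	
A_exitialis	MSDINATRLP	LFFPPDFRPP	CVGDADNFTLTRGE	1213.6284		yes	
A_exitialis	MSDINVIRLP	SMLTILPP	CVSDDASNTLTRGE	852.4779		no	
A_exitialis	MSDINTARLP	VFSLPVFFP	SDDIQAVLTRGE	1033.5637		yes	
A_exitialis	MSDINVTRLP	VFIFFFIPP	CVGDGTADIVRKGEK	1107.6157		no	
A_exitialis	MSDINATRLP	VWIGYSP	CVGDDCIALLTRGE	802.4014		no	
A_exitialis	MSDINATRLP	VWIGYSP	CVGDDCIALLTRGE	802.4014		no	
A_exitialis	MTDINDTRLP	FIWLLWIWLP	SVGDDNNILNRGEE	1367.7794		no	
A_subjunquillea	MSDINATCLP	IWGIGCNP	CVGDEVAALLTRGEALC	918.3541	alpha-amanitin	no	yes
A_subjunquillea	MSDINATRLP	IWGIGCDP	CVGDEVTALLTRGEALC	919.3382	beta-amanitin	no	yes
A_subjunquillea	MSDINATRLP	IWGIGCDP	CIGDDVTALLTRGEALC	919.3382	beta-amanitin	no	yes
A_subjunquillea	MSDINATRLP	AWLATCP	CAGDDVNPTLTRGESLC	788.3160	phalloidin	no	yes
A_subjunquillea	MSDINATRLP	AWLVDCP	CVGDDINRRVVSAFAC	846.3217	phallacidin	no	yes
A_subjunquillea	MSDMNATRLP	LIQRPFAP	CVSDDVDFALIRRCALVYAESSV	922.5389		no	yes
A_subjunquillea	MSDINTARLP	HFASFIPP	CIGDDIEMVLKRGESLC	896.4545		no	yes
A_subjunquillea	MSDINTARLP	TFLPPLFVPP	CVSDDIEMVLTRGESLC	1108.6321		yes	yes
A_subjunquillea	MSDINATRLP	LNILPFMLPP	CVGDDVNPTLTRGEDLC	1135.6464		no	yes
A_subjunquillea	MSDMNATRLP	LIQRPYAP	CVSDDVNSPLTRGESLC	938.5338		no	yes
A_subjunquillea	MSDINTARLP	IGRPESIP	CVGDDIEMILERGQKLC	849.4709		no	yes
A_subjunquillea	MSDINTARLP	LRLPPFMIPP	CVGDDIGMVLTRGENLC	1161.6733		no	yes
A_subjunquillea	MSDVNATRLP	FNFFRFPYP	CIGDDSASVLGLGESLC	1215.5866		no	yes
A_subjunquillea	MSDINATRLP	SSVLPRP	CVGDVDNIILTSREKLC	736.4232		no	yes
A_subjunquillea	MSDINTARLP	AFFPPFFIPP	CVSDDIEMVLTRGESLC	1160.6059		yes	yes
A_subjunquillea	MSDINATRLP	IPILPIPP	YCSDDANTTLTLGESLC	840.5473		no	yes
A_subjunquillea	MSDINATRLP	LFLLAALGIP	SDDADSTLTRGESLC	1008.6372		no	yes
A_subjunquillea	MSDTNDARLP	LFFWFWFLWP	SVSDDIDSVLNRGEDLC	1469.7325		no	yes
A_subjunquillea	MSDMNVARLP	ISDPTAYP	CVGGDIHAVLRRGE	844.3966		no	no
A_subjunquillea	MSDMNVARLP	ISDPTAYP	CVGGDIHAVLRRGE	844.3966		no	no
A_subjunquillea	MSDINVTCLP	FIFWFFWPP	CVGDDAASIIKGK	1267.6218		no	no
A_subjunquillea	MSDINAARLP	FIFPPFFIPP	CVSDDIEMVLTRGE	1202.6528		no	no
A_subjunquillea	MSDINTVCLP	LQKPWSRP	CVGDDIEMILERGE	992.5556		no	no
A_subjunquillea	MFDINITRLP	IFWFIYFP	CVGDDVTALLTRGE	1113.5689		no	no
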