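>MtHPT3_SYN synthetic stand-in: MtHPT3 stand-in
GTETICQMGQMHWRYQTGVSIWAAMYITSPECVYPWIRQLCSEPHRRMSAMLRAKTGTVK
TTFPVVAPLMKAYFSAHGVAVFCKIYTLPCEKLAEKCWRALMHEMVMEAFARVWYVKWEE
YGMCLLPTTHATYWMRWKCGQKWKMPIKI
>AHP1_SYN synthetic stand-in: AHP1 stand-in
GTQTTLIMGQMHWYYQTGRRIWAAMYITSYECVYIYIRYLTSEPHWRTSEWVRAKTGTVK
TTIPVCAPLMKAYFSAHGVAVFCKIYWLWCFKLAEKTWRALVHEMVMEAFARVWYVKWEK
YGMRLEPTTHAVYWMRWICGQKWKMPIKI
>OsttaHPT_SYN synthetic stand-in: O. tauri HPT outgroup stand-in
MTETICQFGQMHWWYQTLVSSWAAMYEASPFCRYPQPRQLMSEPLTRMWAMLRPKQVTVW
PQFWYVAWLMSAYYMGHGVAYFCKIYTGPIWGLAEMCWRALMCECVCEIMLVVWYCKREA
YGMCLLPTKTATYWMPWFCEQMWGIPYKG
>MtRRB3_SYN synthetic stand-in: MtRRB3 stand-in
YYMASRAFTCQMGTSFMSYICMMLVGVTGDQSGPYCMFSKPWRFSWKGMMSTQVPSRAQA
GQQDQKWMPMAQLWEVVICAERALIVGMSSPSELCKCEYTRMKPKLGTEDQSECEMIYEW
FPQMFFETSTWSIILTPIYIIFMVPWTMEMWWYYKMQLIFISTAYGKGRVAVRIIGVQML
AILYRVLFFCGDVWCMQMFVPMVAVTVQYMQFKIEQSMTYFMLPDMCTCKESWAPKCAWS
SEYSSSWQQE
>ARR1_SYN synthetic stand-in: ARR1 stand-in
YYMAERAFTCQPLTSFVSPICMCLVGVTGDQSEPTCMPSKPCRVSWKKMLEKQVQSRAQA
GQQDPKWMPKAQLWEVQICACCSSIVGPSSPSELCKIEYTRMIPTSGTEDQWWCEMIYEW
YPQMTFETSTWSIILTPITIIFMEPWTMEMWWYCKMGLIFIFTSYGPVRVAYRIIGVMML
AILYRVLFFCGDWWCMLMFVPMVAVTVQYMQFKIEQQMTYFSLPDACTCKESWWPKCAWS
VEYISSWQEE
>ARR6_SYN synthetic stand-in: ARR6 stand-in
YYMGLRALTCGMGVSFMSMWAMMLIGVTGDQSGVYCMCTKPWRFSWAGTMSKQVPSRAQA
GQVDPKWMPMMQLWEVVIAAEAAILVGMTSPSGKCKCPYYWMSTKLGKEDQAECEMIYEW
LGMWFIRMVSSWIPPSSWCSWFEPRREYPIWPKTGRCYQCCFIEMYEQATQPMPL
>ARR22_SYN synthetic stand-in: ARR22 stand-in
GYMASRAFSMQQGVSFMSYIYFFLVGVVSWCSGPYPMFSQFGRFSWKWMMCTQVESRRQQ
GQQDQLWKGYAQLWEVVICAERALIATMSSSSEKCKCEPTQSKWKYGLVDQYECETWKEW
KMYYRFRMGKCRYVIFEQWG
>AHK4_SYN synthetic stand-in: AHK4/CRE1 stand-in
LGYVSVWSFCQRTRGMKAEFGWYTQPAACQCIMQVRCWEPRMQMASVKCFECPFVGAPKR
FAPLCCQMLLRSSIVAFCKRPCTYQQELYGLYPYMEKQIWSVSMTMPYWQAYYGWREFFR
FSQQWCIIIRTPCQIKPVWHSFQEYYTKQGRWEKCQERQMCMWIEVITTGTQESTSLQFK
PSWCSLFMFCLWAVMPVAIYGVSMNMPPCTGYKGKMGLYPQKAQGYKCKGGWTFIEQPPR
FAWVPVCLMFMYEAQTECMVVTCLLGASEGCVEWEGRLFYFTQLQMSWMQFKEMGTGKRL
TEQVKPLVMGKIRKWFSLLFGRAGTRAWKLIYRWCEKVTLMRYYCESRSEPFQSQKRGWI
GQYECYWLYTTLTKGQWYTPIRLDQRFCEFRGSLLMSPEFSCAFPEPRMA
>AHK2_SYN synthetic stand-in: AHK2 stand-in
LGYAYVWSFFWRTRGMKAFFGPYTQPAACGLERQVRTIEPRLQMAFVKFFEPPFEGAPRR
FFPLCCQGLLRSSIVAFCKLMCTYQQELYSLYPRWVKQTWSVSMTMPKWQAYYGWREFFR
FSQMWCIIIPEPCQIKPVWHSFQEYYTKQTRWESCLERQMPCWIEVITVGTCESTSLQFK
KSWCKLFLFCLWEVMVWLIYGVQKNMPPCTGEKGIMGLYSQAWQGYKCKGPSTFIEQPPR
FWAVPVSLMFMYEAQTECMVVSCPLGASEGCVEWEGYLFYIVQKQGSWMQFKEMGTGKPL
FEQVKPLGMVKSRKWFSLLFGIAATRAWKLIYRACEKVELMLYYCIRRSELIQGQKCGFA
GQYEPKWCYTTLTKGQWYTPESWDVRFFQFRGSFLMSYEFSCAFPEPMVA
>AHK3_SYN synthetic stand-in: AHK3 stand-in
LGEISVWPFVQQTRGYWAEWGWYTWYALCQCIMQVRCWEFRSPQAMVKCFECPVVGAPKR
FAPCQCQMELRSSIVAFCKRPCKYQQELYGLYPAGEKQRFSVSMCMPAWQAYYQWREWFR
FSQVWCIIIRTPCQIKPVWHSFQEKYTKIGRWESCQEMQIGMWPEVITVGTIEGTSLQIK
PSWGSLFMRCCWCVMPVASYVLSMNMPPCTGCKGKMGSYAQKPQGYKCKGGWTFIPQGPF
WAWTTRCLQFMYEAQTECMVMTCLLYASEGCVEWEVRLFYFTQLQMSWMQQKICGTGKRQ
TIRIKGLVGGKARSWFSLLFGPAGTRAWKLRYRWCEKVTLMRYYCESRSEPFQSFARGWI
RQYECYWRYTGLSKGWWYTPIRLDQVFEEFRGSLLMSPEFSCAFPEPRMA
>AHK1_SYN synthetic stand-in: AHK1 osmosensor stand-in
FSSWWCIIIRTPCQIKVVWHSFQEYYWKQGRAGKCQSWQMCMMIEVITTGYQEVTPLQYK
PSWCSLFMFCTWAVMPVACVQVSCNMPPCTGYIGVMGLYPQKAQGYKCKGGWAFCGPPPR
FAWVGIYLMFMYEAQTECVEVWCQTGAFEGCVEWFCRLFKFTQYQMLWWGFEEMGTGKCL
TEFVKPLQMIKYRKWRSLLFCRAGTRAWKKIYRWYEKVTLMRYYSESRSERFVAQKFGWT
SQYECYWLFETLTKGQWYTPYRLDTRFCEFRPSWSMSPEFSCAFPGPRMA
>CKI1_SYN synthetic stand-in: CKI1 stand-in
FSQQWCTIIRTLCQIKPVWHSFQEYYTKQGGWELCQERQRCMWTVVITTGCQESAEFQFK
PSCCSFFMFQLWWVMPPAIVGVSMNMPPCKCYKGKLGGYPQKAQGYKCKGGWTFIEQPPR
FAWFAVCKMFMYEAQTERMFVYPLTGGSEGCVEWEGRLYYFTQLQMSRMQFKEIGTGKRL
MEQVKPLVMGTGAKFFSVLFGRAGTRAWLLIYRWCCKVGLMPYYCESRSEPFQSQKRVWV
GQYECYWLYTRLFLGLWETAIRLDQRFCIQWGSLLMSPEFFCAFPEPRMA
>CKI2_SYN synthetic stand-in: CKI2/AHK5 stand-in
FSAGVWICIRTPCYIKIVWHSFQEYETKQGRCEKMQERFMGMWIELITTGCQESTSLQFK
PTWCSLFMCCLPAVCPVAIYGVSMNMPPCTMYVGKWGVYPQKAVGYKCKGGPTLISQVPR
FEWVAVCVTFMYEAQTEIMFFTKLGGASEGCVEWETRLFMFTQYMIYWMQFKEMGSGARL
TERVKPLVMPLIRKWFSLLFFRWCTRAWKLIYQQCERFTLMRYYCESRSEPFQSQKRGWI
GQPEKYRLYTLLTKWQWYTTMAIDQRTCEFMPSQGSSPEFSCAFPEWRMA
>ETR1_SYN synthetic stand-in: ETR1 stand-in
LFMEKEILVAVTPGSMGRMPCAQPLTCSTTLTLRAIVQLSSSIYVQETQIQVWREIMLTP
MYKMQYSQWAFYMYAQWYSIFLRWPASLPIGYIISPYMYAARIPSVVPASARSEYYIVQQ
AMQQEVFYCIFPSFEIIIKCFLQLYQLWSQFSWVWCIYIRTPCCIKPVWHSFQCYYTKQG
PWSKCQGRQFCVWIETFTMGTTESTSLQFKPSSCSLVMFCQWAVYVVAIYFVSMNMPPCT
GYKGLMGLYPQKAWGYKCKGGWYAWPAPPRFAWVPVCGMFMYEAQTECEVMCELFGASEG
CVEWEGRLAEETQLQQSWMQFIEMQTGKPLTEQEKPLVAGKIRKWFWLLCGRAATRAWKL
SYRWCMQWTLMRYYCESRSEWAQRQKRGWIGQYECFWYYTTLTKGQWYMMRRLDQRSGEF
RESRLMSIEASQLIPESYAA
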