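year	screened	suspected	recalled	confirmed
2016	39602	435	348	8
2017	66399	839	671	13
2018	66037	657	598	16
2019	69372	1444	1302	14
2020	59439	1548	1396	20
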