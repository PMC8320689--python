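label	macro	variants
H	R	727:T>C,941:G>A,3849:G>A,5284:A>G,5501:A>G,6323:A>G,6642:A>G,7496:T>C,7554:G>A,7625:T>C,7771:A>G,7900:C>T,8495:A>G,8748:C>T,10109:A>G,10796:C>T,10828:T>C,11049:C>T,12632:C>T,12972:A>G,13721:T>C,15005:G>A
V	R	610:T>C,845:A>G,941:G>A,1127:A>G,2794:C>T,3076:A>G,3849:G>A,5274:G>A,6149:A>G,6822:T>C,7198:G>A,7353:A>G,7496:T>C,7771:A>G,8748:C>T,9690:G>A,10796:C>T,11166:G>A,12112:C>T,13721:T>C,14189:A>G,15005:G>A,15611:G>A,15885:C>T
J	R	42:T>C,737:C>T,941:G>A,1758:T>C,2198:A>G,3849:G>A,4896:T>C,6538:A>G,7034:C>T,7364:A>G,7496:T>C,7771:A>G,8748:C>T,9410:A>G,10796:C>T,13721:T>C,13877:A>G,14310:C>T,14411:A>G,15005:G>A,15113:A>G,15391:C>T,15700:C>T
T	R	941:G>A,958:C>T,1829:A>G,2518:A>G,3138:A>G,3168:C>T,3849:G>A,4789:G>A,5073:A>G,5830:A>G,7410:C>T,7496:T>C,7771:A>G,8691:A>G,8748:C>T,9214:A>G,9461:A>G,10208:T>C,10587:C>T,10796:C>T,11408:C>T,13080:C>T,13721:T>C,14151:T>C,15005:G>A,16447:C>T
U	R	632:C>T,941:G>A,3507:C>T,3849:G>A,6180:G>A,6403:C>T,7388:A>G,7496:T>C,7771:A>G,8693:A>G,8748:C>T,10500:G>A,10722:T>C,10796:C>T,13656:T>C,13721:T>C,14056:T>C,14275:C>T,15005:G>A,15782:C>T,15950:G>A,16375:C>T
K	R	941:G>A,1008:A>G,1158:T>C,2994:T>C,3849:G>A,5126:C>T,5355:C>T,6270:G>A,6416:A>G,6717:G>A,7496:T>C,7771:A>G,8748:C>T,9246:A>G,10796:C>T,12593:C>T,13120:C>T,13193:T>C,13721:T>C,14204:C>T,14345:T>C,14603:G>A,15005:G>A,15054:A>G,15336:T>C
I	N	183:A>G,710:T>C,767:C>T,1252:G>A,2777:G>A,3309:A>G,3432:C>T,4745:A>G,4897:A>G,5893:C>T,6425:T>C,7221:T>C,7622:A>G,7951:A>G,8507:A>G,8582:C>T,8877:T>C,9549:C>T,9637:T>C,11244:T>C,11587:C>T,11652:T>C,12191:C>T,13637:A>G,14187:C>T,15000:A>G,15291:A>G,15580:C>T,16403:C>T
W	N	183:A>G,2777:G>A,3189:C>T,3459:C>T,3467:A>G,3628:A>G,3989:A>G,4511:T>C,4897:A>G,5509:T>C,5893:C>T,6425:T>C,6450:C>T,6664:T>C,7225:C>T,7769:G>A,9130:C>T,11548:A>G,12191:C>T,12250:C>T,12645:C>T,13545:C>T,14024:C>T,14272:C>T,14438:G>A,15000:A>G,16396:T>C,16403:C>T,16453:C>T
X	N	183:A>G,535:C>T,875:T>C,2087:T>C,2170:G>A,2777:G>A,3075:G>A,3233:A>G,3338:T>C,4299:T>C,4897:A>G,5893:C>T,6425:T>C,6679:C>T,8452:A>G,11200:A>G,11664:T>C,12191:C>T,12316:G>A,12716:C>T,13090:A>G,13420:C>T,13658:C>T,15000:A>G,15499:C>T,16113:A>G,16403:C>T
C	M	972:G>A,1371:T>C,1944:C>T,2452:A>G,2497:T>C,2705:T>C,3366:A>G,3471:C>T,3604:C>T,4026:A>G,4739:C>T,5566:A>G,5979:G>A,7485:A>G,7803:T>C,8710:A>G,10987:A>G,11032:A>G,11289:T>C,11423:G>A,11909:A>G,12085:C>T,12996:A>G,13501:T>C,13556:G>A,13600:T>C,14436:C>T,15769:A>G,16124:T>C
D	M	141:C>T,972:G>A,1310:C>T,1333:G>A,1515:G>A,3678:C>T,3865:A>G,3883:A>G,4026:A>G,5918:T>C,7244:C>T,9042:C>T,10127:A>G,10423:A>G,11032:A>G,11349:T>C,11423:G>A,11613:T>C,11754:C>T,12339:A>G,12996:A>G,13244:C>T,13501:T>C,13600:T>C,13647:C>T,14436:C>T,16393:C>T
L2	L	1394:C>T,1596:A>G,2833:A>G,4215:A>G,5533:A>G,6051:A>G,6852:G>A,7297:T>C,7798:C>T,8179:A>G,8275:C>T,9655:G>A,9679:A>G,9709:T>C,10135:A>G,10420:A>G,10945:A>G,11835:G>A,12881:T>C,13483:A>G,14301:T>C,14503:T>C,14596:A>G,14980:C>T,15110:G>A
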