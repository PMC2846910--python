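name	scaffold	start	end	orientation	group
TRDV1a	ChrUn.139	314906	315465	+
TRDV1b	ChrUn.139	303549	304112	+
TRDV1c	ChrUn.139	356577	357146	+	g-sec5
TRDV1d	ChrUn.139	75036	75601	-	g-ast1
TRDV1e	ChrUn.139	16460	17025	+	g-ast1
TRDV1f	ChrUn.139	373301	373837	+
TRDV1g	ChrUn.298	28570	29136	+
TRDV1h	ChrUn.298	223460	224017	+
TRDV1i	ChrUn.298	206764	207325	+
TRDV1j	ChrUn.298	263421	263882	+
TRDV1k	ChrUn.1758	21943	22497	-
TRDV1l	ChrUn.1758	58028	58581	-
TRDV1m	ChrUn.221	6077	6638	-
TRDV1n	ChrUn.221	30283	30837	-
TRDV1o	ChrUn.221	174860	175436	-	g-ast4
TRDV1p	ChrUn.221	220755	221325	-
TRDV1q	ChrUn.221	240734	241302	-	g-sec3
TRDV1r	ChrUn.221	264437	265003	-
TRDV1s	ChrUn.41	188111	188668	-
TRDV1t	ChrUn.41	313360	313923	+	g-ast2
TRDV1u	ChrUn.41	294987	295550	+
TRDV1v	ChrUn.41	282485	282946	+	g-ast3
TRDV1w	ChrUn.41	272858	273319	+
TRDV1x	ChrUn.41	161524	162099	-
TRDV1y	ChrUn.41	661894	662457	+	g-ast2
TRDV1z	ChrUn.41	642343	642906	+
TRDV1aa	ChrUn.41	480039	480605	+
TRDV1ab	ChrUn.41	629990	630287	+	g-ast3
TRDV1ac	ChrUn.158	178923	179480	-
TRDV1ad	ChrUn.158	237111	237679	-
TRDV1ae	ChrUn.158	209540	210077	-
TRDV1af	ChrUn.129	414487	415056	+
TRDV1ag	ChrUn.129	331405	331977	+
TRDV1ah	ChrUn.129	300288	300855	+
TRDV1ai	ChrUn.129	390952	391528	+	g-ast4
TRDV1aj	ChrUn.129	5640	6395	+
TRDV1al	ChrUn.857	4172	4726	+	g-dia1
TRDV1am	ChrUn.857	19494	20055	+
TRDV1an	ChrUn.857	28383	28939	+	g-sec1
TRDV1ao	ChrUn.857	50213	50768	+	g-sec2
TRDV1ap	ChrUn.857	74024	74592	+
TRDV1aq	Chr10.28	20379	20949	-
TRDV1ar	Chr10.28	58187	58723	+	g-dia5
TRDV1as	Chr10.28	84670	85131	+
TRDV1at	Chr10.28	97187	97750	+	g-dia1
TRDV1au	Chr10.28	115470	116026	+	g-sec1
TRDV1av	Chr10.28	132846	133401	+	g-sec2
TRDV1aw	Chr10.28	198285	198854	-	g-sec4
TRDV1ax	Chr10.28	245707	246273	-
TRDV1ay	ChrUn.2578	31691	32259	-	g-sec3
TRDV1az	ChrUn.1227	79925	80480	-
TRDV1ba	ChrUn.1227	39695	40263	-
TRDV1bb	ChrUn.1227	62992	63563	-
TRDV1bc	ChrUn.2188	10476	11031	+	g-dia3
TRDV1bd	ChrUn.2188	33687	34255	+
TRDV1be	ChrUn.5529	9610	10170	-	g-sec4
TRDV1bf	ChrUn.4913	10675	11244	-	g-sec5
TRDV1bg	ChrUn.41	250250	250849	+
TRDV1bh	ChrUn.3566	5067	5528	+
TRDV1bi	ChrUn.3566	19054	19618	+	g-dia1
TRDV1bj	ChrUn.3620	538	1129	+	g-dia2
TRDV1bk	ChrUn.3793	3915	4506	+	g-dia2
TRDV1bl	ChrUn.3970	9390	9945	+	g-dia3
TRDV1bm	ChrUn.10149	1843	2409	-
TRDV1bn	ChrUn.3458	16972	17538	-	g-dia4
TRDV1bo	ChrUn.2982	15173	15739	+	g-dia4
TRDV1bp	ChrUn.4123	14961	15497	+	g-dia5
TRDV2-1	ChrUn.158	345140	345657	-
TRDV2-2	ChrUn.1907	43992	44509	+	g-cur1
TRDV2-2b	ChrUn.1948	11302	11819	+	g-cur1
TRDV3-1	ChrUn.7503	3142	3667	-	g-cur2
TRDV3-1b	ChrUn.1002	77577	78102	+	g-cur2
TRDV4	Chr10.30	396663	397245	+
TRDD1	Chr10.30	504600	504612	-
TRDD2	Chr10.30	488743	488757	-
TRDD3	Chr10.30	449660	449672	-
TRDD4	Chr10.30	441241	441249	-
TRDD5	Chr10.30	417750	417760	-
TRDJ1	Chr10.30	416717	416770	-
TRDJ2	Chr10.30	406656	406598	-
TRDJ3	Chr10.30	410369	410417	-
TRDC	Chr10.30	402706	403988	-
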