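id	component	ion	rt_min	in_vivo_mz	in_vivo_err_mda	in_vitro_mz	in_vitro_err_mda	fragments
M1	ART + O	C_15_H_22_O_6_ + H^+^	2.6	299.1487	-0.2	-	-	321, 299, 337, 281, 263, 253, 235, 217, 207
M2	ART + O	C_15_H_22_O_6_ + Na^+^	2.8	321.1301	-0.5	321.1312	0.3	321, 337, 299, 281, 263, 253, 235, 221, 207, 189
M3	ART + O	C_15_H_22_O_6_ + Na^+^	2.9	321.1301	-0.4	321.1309	0.1	321, 337, 299, 281, 263, 245, 235, 221, 217, 189, 175
M4	ART + O	C_15_H_22_O_6_ + Na^+^	3.0	321.1304	-0.4	321.1305	-0.3	321, 337, 299, 283, 265, 235, 223, 219, 207, 189, 147
M5	ART + O	C_15_H_22_O_6_ + Na^+^	3.5	321.1307	-0.1	321.1304	-0.5	321, 337, 281, 263, 245, 235, 217, 205, 189
M6	ART + O	C_15_H_22_O_6_ + Na^+^	3.7	321.1304	-0.4	321.1302	1.8	321, 337, 299, 281, 263, 235, 221, 207, 193, 189, 175
M7	ART + O	C_15_H_22_O_6_ + Na^+^	3.9	321.1301	-0.7	-	-	321, 299, 337, 281, 253, 245, 235, 223, 217, 177, 149
M8	ART + O	C_15_H_22_O_6_ + H^+^	4.0	299.1481	-0.8	321.1301	-0.8	321, 337, 283, 263, 253, 235, 221, 207, 189, 175
M9	ART + O	C_15_H_22_O_6_ + Na^+^	4.2	-	-	321.1306	-0.3	321, 337, 307, 267, 253, 249, 235, 207, 189, 175, 165
M10	ART + O	C_15_H_22_O_6_ + Na^+^	4.7	-	-	321.1301	-0.7	321, 299, 337, 283, 261, 237, 235, 219, 205, 177, 165
M11	ART + O	C_15_H_22_O_6_ + Na^+^	4.9	337.1038	-0.6	337.1039	-0.9	321, 299, 337, 281, 253, 235, 207, 189, 179
M12	ART + O	C_15_H_22_O_6_ + Na^+^	5.1	-	-	321.1296	-1.3	321, 337, 299, 281, 263, 253, 235, 207, 189, 175, 149
M13	ART + O	C_15_H_22_O_6_ + Na^+^	5.8	-	-	321.1304	-0.4	321, 337, 299, 281, 263, 235, 217, 207, 189, 175, 149
M14	ART + O2	C_15_H_22_O_7_ + Na^+^	2.0	337.1254	-0.4	337.1275	1.8	337, 353, 315, 297, 279, 261, 251, 233, 205
M15	ART + O2	C_15_H_22_O_7_ + Na^+^	2.2	-	-	337.1246	-1.1	337, 353, 277, 255, 237, 219, 209, 191, 163, 135
M16	ART + O2	C_15_H_22_O_7_ + Na^+^	2.2	337.1255	-0.2	-	-	337, 315, 267, 252, 226, 199, 176
M17	ART + O2	C_15_H_22_O_7_ + Na^+^	2.3	337.1259	0.1	-	-	337, 297, 279, 265, 247, 233, 217, 201, 189
M18	ART + O2	C_15_H_22_O_7_ + Na^+^	2.4	-	-	337.1256	-0.1	337, 353, 299, 299, 281, 277, 263, 255
M19	ART + O2	C_15_H_22_O_7_ + Na^+^	2.5	-	-	337.1247	-1.0	337, 353, 277, 253, 235, 219, 209, 207, 163, 135
M20	ART + O2	C_15_H_22_O_7_ + Na^+^	3.0	337.1274	1.7	-	-	337, 321, 299, 281, 279, 263, 252, 235, 207, 189, 147
M21	ART + O2	C_15_H_22_O_7_ + Na^+^	3.6	337.1281	-0.4	337.1068	-1.1	337, 353, 305, 297, 279, 233, 221, 177
M22	ART + O2	C_15_H_22_O_7_ + Na^+^	3.8			337.1244	-1.3	337, 353, 315, 297, 279, 261, 251, 233, 205, 191, 175
M23	de-ART	C_15_H_22_O_4_ + H^+^	8.3	267.1586	-0.5	267.1586	-0.5	289, 267, 305, 249, 239, 231, 221, 207, 203, 193, 179
M24	de-ART + O	C_15_H_22_O_5_ + Na^+^	4.5	-	-	305.1355	-0.5	305, 321, 283, 265, 247, 237, 219, 201, 189
M25	de-ART + O	C_15_H_22_O_5_ + H^+^	4.9	283.1536	-0.4	283.1535	-0.3	283, 305, 321, 265, 247, 239, 191
M26	de-ART + O	C_15_H_22_O_5_ + Na^+^	5.2	283.1531	-0.9	283.1355	-0.5	283, 305, 265, 247, 237, 219, 191, 177
M27	de-ART + O	C_15_H_22_O_5_ + Na^+^	5.4	-	-	305.1354	-0.6	305, 321, 267, 247, 219, 205, 177, 159
M28	de-ART + O	C_15_H_22_O_5_ + Na^+^	5.6	305.1355	-0.4	305.1358	-0.1	283, 305, 321, 265, 247, 219, 205, 177, 159
M29	de-ART + O	C_15_H_22_O_5_ + Na^+^	5.8	305.1358	-0.1	-	-	305, 283, 276, 249, 239, 231, 221, 207, 203, 193, 179
M30	de-ART + O	C_15_H_22_O_5_ + Na^+^	6.0	305.1353	-0.8	305.1353	-0.6	305, 321, 265, 247, 219, 205, 193, 149
M31	de-ART + O	C_15_H_22_O_5_ + Na^+^	7.2	-	-	305.1355	-0.5	305, 321, 283, 247, 223, 195, 167
M32	DHA	C_15_H_24_O_5_ + Na^+^	7.0	307.1505	-1.1	-	-	307, 323, 267, 249, 239, 231, 221, 203, 163
M33	DHA + O	C_15_H_24_O_6_ + Na^+^	2.2	-	-	323.1456	-1.0	323, 339, 283, 265, 247, 219, 189
M34	DHA + O	C_15_H_24_O_6_ + Na^+^	2.5	-	-	323.1458	-0.7	323, 339, 283, 265, 247, 219, 191
M35	DHA + O	C_15_H_24_O_6_ + Na^+^	3.1	-	-	323.1458	-0.8	323, 339, 285, 267, 249, 219, 191, 177
M36	DHA + O	C_15_H_24_O_6_ + Na^+^	3.7	323.1449	-1.6	323.1484	1.8	323, 283, 265, 253, 247, 237, 219, 209
M37	DHA + O	C_15_H_24_O_6_ + Na^+^	3.9	-	-	323.1456	-1.0	323, 285, 267, 249, 239, 235, 231, 221, 203
M38	DHA-O	C_15_H_24_O_6_ + Na^+^	6.6	-	-	291.1561	-0.3	291, 307, 279, 269, 251, 233, 223, 215, 205, 179
M39	DHA-O + O	C_15_H_24_O_5_ + Na^+^	5.8	307.1513	-0.4	307.1512	-0.5	307, 323, 267, 249, 239, 231, 221, 203, 179
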