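id,age,sex,hematemesis,melena,syncope,sbp,dbp,pulse,hemoglobin_g_dl,bun_value,bun_unit,hepatic_disease,cardiac_failure,nga,hrel,gbs
P001,,,,,,,,,,,,,,bloody,1,1
P002,,,,,,,,,,,,,,bloody,1,2
P003,,,,,,,,,,,,,,bloody,1,3
P004,,,,,,,,,,,,,,bloody,1,7
P005,,,,,,,,,,,,,,bloody,1,9
P006,,,,,,,,,,,,,,bloody,1,9
P007,,,,,,,,,,,,,,bloody,1,10
P008,,,,,,,,,,,,,,bloody,1,10
P009,,,,,,,,,,,,,,bloody,1,10
P010,,,,,,,,,,,,,,bloody,1,11
P011,,,,,,,,,,,,,,bloody,1,11
P012,,,,,,,,,,,,,,bloody,1,11
P013,,,,,,,,,,,,,,bloody,1,11
P014,,,,,,,,,,,,,,bloody,1,11
P015,,,,,,,,,,,,,,bloody,1,11
P016,,,,,,,,,,,,,,bloody,1,12
P017,,,,,,,,,,,,,,bloody,1,12
P018,,,,,,,,,,,,,,bloody,1,12
P019,,,,,,,,,,,,,,bloody,1,12
P020,,,,,,,,,,,,,,bloody,1,12
P021,,,,,,,,,,,,,,bloody,1,15
P022,,,,,,,,,,,,,,bloody,1,15
P023,,,,,,,,,,,,,,bloody,1,16
P024,,,,,,,,,,,,,,bloody,1,17
P025,,,,,,,,,,,,,,coffee_ground,1,10
P026,,,,,,,,,,,,,,coffee_ground,1,11
P027,,,,,,,,,,,,,,coffee_ground,1,12
P028,,,,,,,,,,,,,,coffee_ground,1,13
P029,,,,,,,,,,,,,,coffee_ground,1,13
P030,,,,,,,,,,,,,,coffee_ground,1,13
P031,,,,,,,,,,,,,,coffee_ground,1,14
P032,,,,,,,,,,,,,,coffee_ground,1,15
P033,,,,,,,,,,,,,,clear,1,15
P034,,,,,,,,,,,,,,clear,1,15
P035,,,,,,,,,,,,,,clear,1,16
P036,,,,,,,,,,,,,,bloody,0,3
P037,,,,,,,,,,,,,,bloody,0,6
P038,,,,,,,,,,,,,,bloody,0,6
P039,,,,,,,,,,,,,,bloody,0,7
P040,,,,,,,,,,,,,,bloody,0,7
P041,,,,,,,,,,,,,,bloody,0,9
P042,,,,,,,,,,,,,,bloody,0,11
P043,,,,,,,,,,,,,,bloody,0,11
P044,,,,,,,,,,,,,,bloody,0,12
P045,,,,,,,,,,,,,,bloody,0,13
P046,,,,,,,,,,,,,,bloody,0,15
P047,,,,,,,,,,,,,,coffee_ground,0,0
P048,,,,,,,,,,,,,,coffee_ground,0,0
P049,,,,,,,,,,,,,,coffee_ground,0,0
P050,,,,,,,,,,,,,,coffee_ground,0,1
P051,,,,,,,,,,,,,,coffee_ground,0,2
P052,,,,,,,,,,,,,,coffee_ground,0,2
P053,,,,,,,,,,,,,,coffee_ground,0,3
P054,,,,,,,,,,,,,,coffee_ground,0,3
P055,,,,,,,,,,,,,,coffee_ground,0,3
P056,,,,,,,,,,,,,,coffee_ground,0,3
P057,,,,,,,,,,,,,,coffee_ground,0,3
P058,,,,,,,,,,,,,,coffee_ground,0,4
P059,,,,,,,,,,,,,,coffee_ground,0,6
P060,,,,,,,,,,,,,,coffee_ground,0,6
P061,,,,,,,,,,,,,,coffee_ground,0,6
P062,,,,,,,,,,,,,,coffee_ground,0,6
P063,,,,,,,,,,,,,,coffee_ground,0,7
P064,,,,,,,,,,,,,,coffee_ground,0,7
P065,,,,,,,,,,,,,,coffee_ground,0,7
P066,,,,,,,,,,,,,,coffee_ground,0,7
P067,,,,,,,,,,,,,,coffee_ground,0,7
P068,,,,,,,,,,,,,,coffee_ground,0,8
P069,,,,,,,,,,,,,,coffee_ground,0,8
P070,,,,,,,,,,,,,,coffee_ground,0,9
P071,,,,,,,,,,,,,,coffee_ground,0,9
P072,,,,,,,,,,,,,,coffee_ground,0,9
P073,,,,,,,,,,,,,,coffee_ground,0,9
P074,,,,,,,,,,,,,,coffee_ground,0,10
P075,,,,,,,,,,,,,,coffee_ground,0,10
P076,,,,,,,,,,,,,,coffee_ground,0,10
P077,,,,,,,,,,,,,,coffee_ground,0,10
P078,,,,,,,,,,,,,,coffee_ground,0,10
P079,,,,,,,,,,,,,,coffee_ground,0,10
P080,,,,,,,,,,,,,,coffee_ground,0,10
P081,,,,,,,,,,,,,,coffee_ground,0,10
P082,,,,,,,,,,,,,,coffee_ground,0,10
P083,,,,,,,,,,,,,,coffee_ground,0,11
P084,,,,,,,,,,,,,,coffee_ground,0,11
P085,,,,,,,,,,,,,,coffee_ground,0,11
P086,,,,,,,,,,,,,,coffee_ground,0,11
P087,,,,,,,,,,,,,,coffee_ground,0,11
P088,,,,,,,,,,,,,,coffee_ground,0,11
P089,,,,,,,,,,,,,,coffee_ground,0,11
P090,,,,,,,,,,,,,,coffee_ground,0,11
P091,,,,,,,,,,,,,,bile_like,0,12
P092,,,,,,,,,,,,,,bile_like,0,12
P093,,,,,,,,,,,,,,bile_like,0,12
P094,,,,,,,,,,,,,,bile_like,0,12
P095,,,,,,,,,,,,,,bile_like,0,12
P096,,,,,,,,,,,,,,bile_like,0,12
P097,,,,,,,,,,,,,,clear,0,12
P098,,,,,,,,,,,,,,clear,0,12
P099,,,,,,,,,,,,,,clear,0,12
P100,,,,,,,,,,,,,,clear,0,13
P101,,,,,,,,,,,,,,clear,0,13
P102,,,,,,,,,,,,,,clear,0,13
P103,,,,,,,,,,,,,,clear,0,13
P104,,,,,,,,,,,,,,clear,0,13
P105,,,,,,,,,,,,,,clear,0,13
P106,,,,,,,,,,,,,,clear,0,14
P107,,,,,,,,,,,,,,clear,0,14
P108,,,,,,,,,,,,,,clear,0,14
P109,,,,,,,,,,,,,,clear,0,15
P110,,,,,,,,,,,,,,clear,0,15
P111,,,,,,,,,,,,,,clear,0,16
P112,,,,,,,,,,,,,,clear,0,16
P113,,,,,,,,,,,,,,clear,0,16
P114,,,,,,,,,,,,,,clear,0,16
P115,,,,,,,,,,,,,,clear,0,17
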