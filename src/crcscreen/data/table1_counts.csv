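sex,round,eligible,invited,participants,positives,colonoscopies,detected_advanced_adenoma,detected_advanced_neoplasia,detected_crc,crc_stage_i_ii,crc_stage_iii_iv,crc_stage_unknown
female,1,298896,288775,200422,10421,9720,3063,3583,520,320,157,43
male,1,286054,273317,174968,15671,14678,7487,8533,1046,716,279,51
female,2,154183,149234,108776,4659,4282,1094,1257,163,112,45,6
male,2,143960,137705,93368,6422,5842,2504,2796,292,206,76,10
female,3,41770,40397,30095,1245,1176,300,342,42,22,20,0
male,3,36670,34988,24427,1717,1595,696,764,68,38,25,5
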