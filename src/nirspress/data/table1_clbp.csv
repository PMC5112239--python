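subject,pain_detect_current,pain_detect_ave4w,pain_detect_total,rmd,ppt
Patient 01,3,4.3,3,2,75
Patient 02,2,4.3,5,4,40
Patient 03,0,3.3,2,4,60
Patient 04,3,5.3,8,11,65
Patient 05,1,2.7,3,1,57
Patient 06,3,4.3,5,5,55
Patient 07,2,4.3,5,2,25
Patient 08,3,3.7,1,3,45
Patient 09,0,3.7,14,6,20
Patient 10,2,4.0,11,1,20
Patient 11,2,4.3,7,1,40
Patient 12,2,3.3,6,4,32
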