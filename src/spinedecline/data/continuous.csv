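source,endpoint,age_low,age_high,n,mean,sd
crawford,MF+ES (C),20,29,20,12.4,3.7
crawford,MF+ES (C),30,39,20,15.9,5.0
crawford,MF+ES (C),40,49,20,15.7,4.5
crawford,MF+ES (C),50,60,20,18.1,7.8
crawford,MF (C),20,29,20,16.3,5.3
crawford,MF (C),30,39,20,20.8,6.4
crawford,MF (C),40,49,20,21.6,6.1
crawford,MF (C),50,60,20,24.1,8.7
crawford,ES (C),20,29,20,10.1,4.7
crawford,ES (C),30,39,20,12.9,4.3
crawford,ES (C),40,49,20,12.4,3.4
crawford,ES (C),50,60,20,14.7,7.3
valentin,psoas (V),18,25,12,35.7,2.0
valentin,psoas (V),45,60,12,37.1,1.5
valentin,MF+ES (V),18,25,12,40.2,3.0
valentin,MF+ES (V),45,60,12,42.8,2.9
valentin,MF (V),18,25,12,40.7,3.4
valentin,MF (V),45,60,12,43.9,3.7
valentin,ES (V),18,25,12,39.6,2.8
valentin,ES (V),45,60,12,41.8,2.3
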