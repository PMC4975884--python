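source,endpoint,age_low,age_high,n,prevalence_pct,assumed_n
brinjikji,disk degeneration,20,29,273,37,0
brinjikji,disk degeneration,30,39,604,52,0
brinjikji,disk degeneration,40,49,415,68,0
brinjikji,disk degeneration,50,59,311,80,0
brinjikji,disk signal loss,20,29,46,17,0
brinjikji,disk signal loss,30,39,142,33,0
brinjikji,disk signal loss,40,49,352,54,0
brinjikji,disk signal loss,50,59,73,73,0
brinjikji,disk height loss,20,29,15,24,0
brinjikji,disk height loss,30,39,163,34,0
brinjikji,disk height loss,40,49,186,45,0
brinjikji,disk height loss,50,59,208,56,0
brinjikji,disk bulge,20,29,55,30,0
brinjikji,disk bulge,30,39,101,40,0
brinjikji,disk bulge,40,49,151,50,0
brinjikji,disk bulge,50,59,123,60,0
brinjikji,disk protrusion,20,29,87,29,0
brinjikji,disk protrusion,30,39,468,31,0
brinjikji,disk protrusion,40,49,490,33,0
brinjikji,disk protrusion,50,59,363,36,0
brinjikji,annular fissure,20,29,167,19,0
brinjikji,annular fissure,30,39,350,20,0
brinjikji,annular fissure,40,49,426,22,0
brinjikji,annular fissure,50,59,53,23,0
brinjikji,facet degeneration,20,29,100,4,1
brinjikji,facet degeneration,30,39,100,9,1
brinjikji,facet degeneration,40,49,596,18,0
brinjikji,facet degeneration,50,59,53,32,0
brinjikji,spondylolisthesis,20,29,100,3,1
brinjikji,spondylolisthesis,30,39,100,5,1
brinjikji,spondylolisthesis,40,49,31,8,0
brinjikji,spondylolisthesis,50,59,53,14,0
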