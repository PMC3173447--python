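patient,ktrans_change_theoretical,ktrans_change_measured,ve_change_theoretical,ve_change_measured,size_change,clinical,sataloff
1,-70,-23,-73,-80,0,PR,C
2,-35,-20,-4,-52,57,SD,C
3,-2,108,-89,-91,-100,PR,C
4,-71,-22,-46,-48,-84,SD,C
5,223,166,-76,-74,-100,PR,C
6,-97,-84,23,-29,158,PR,C
7,-85,-67,-78,-64,-72,PR,C
8,-93,93,-15,-52,-99,CR,C
9,-98,-98,-50,-38,-65,PR,D
10,-90,-82,-50,-59,-100,PR,C
11,-97,-89,-49,193,-62,PR,C
12,-85,-95,-61,-73,-71,CR,B
13,-99,-86,-65,-77,-73,PR,B
14,-54,-89,-57,-48,-100,SD,B
15,-94,-95,-75,-75,-33,SD,B
16,65,-52,-68,-72,-100,PR,B
17,-96,-84,-72,-85,-91,PR,B
18,-97,-97,-77,-91,-29,PR,B
19,0,27,-89,-89,-40,PR,A
20,-15,-91,-62,-95,-99,CR,A
21,4,-54,-89,-91,-100,CR,A
22,-29,-98,-51,-73,-100,CR,A
23,-99,-100,-95,-94,-96,CR,A
24,-94,-99,-75,-87,-97,PR,A
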