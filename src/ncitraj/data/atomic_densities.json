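{
 "version": 1,
 "units": {
  "coefficient": "e/bohr^3",
  "decay_length": "bohr"
 },
 "elements": {
  "H": [
   [
    0.3183098861837907,
    0.5
   ]
  ],
  "C": [
   [
    116.21162463821982,
    0.0881414493979939
   ],
   [
    3.845012844729678,
    0.4095892666442637
   ]
  ],
  "N": [
   [
    188.4951291531203,
    0.07501762914284857
   ],
   [
    12.463143944052105,
    0.32186642963517686
   ]
  ],
  "O": [
   [
    285.89673491843945,
    0.06529205134566918
   ],
   [
    31.818557025680544,
    0.26788218124955615
   ]
  ],
  "S": [
   [
    2389.5087256420775,
    0.0321731688640941
   ],
   [
    5.659563908882332,
    0.4322932936218042
   ]
  ]
 }
}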