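{
 "G": [],
 "A": [],
 "S": [
  {
   "chi": [
    -60
   ],
   "p": 0.5
  },
  {
   "chi": [
    180
   ],
   "p": 0.3
  },
  {
   "chi": [
    60
   ],
   "p": 0.2
  }
 ],
 "C": [
  {
   "chi": [
    -60
   ],
   "p": 0.5
  },
  {
   "chi": [
    180
   ],
   "p": 0.3
  },
  {
   "chi": [
    60
   ],
   "p": 0.2
  }
 ],
 "T": [
  {
   "chi": [
    -60
   ],
   "p": 0.5
  },
  {
   "chi": [
    180
   ],
   "p": 0.3
  },
  {
   "chi": [
    60
   ],
   "p": 0.2
  }
 ],
 "V": [
  {
   "chi": [
    -60
   ],
   "p": 0.5
  },
  {
   "chi": [
    180
   ],
   "p": 0.3
  },
  {
   "chi": [
    60
   ],
   "p": 0.2
  }
 ],
 "L": [
  {
   "chi": [
    -60,
    180
   ],
   "p": 0.6
  },
  {
   "chi": [
    180,
    60
   ],
   "p": 0.3
  },
  {
   "chi": [
    -170,
    65
   ],
   "p": 0.1
  }
 ],
 "I": [
  {
   "chi": [
    -60,
    170
   ],
   "p": 0.6
  },
  {
   "chi": [
    60,
    170
   ],
   "p": 0.25
  },
  {
   "chi": [
    -60,
    -60
   ],
   "p": 0.15
  }
 ],
 "F": [
  {
   "chi": [
    -65,
    90
   ],
   "p": 0.5
  },
  {
   "chi": [
    180,
    80
   ],
   "p": 0.3
  },
  {
   "chi": [
    62,
    90
   ],
   "p": 0.2
  }
 ],
 "Y": [
  {
   "chi": [
    -65,
    90
   ],
   "p": 0.5
  },
  {
   "chi": [
    180,
    80
   ],
   "p": 0.3
  },
  {
   "chi": [
    62,
    90
   ],
   "p": 0.2
  }
 ],
 "W": [
  {
   "chi": [
    -65,
    95
   ],
   "p": 0.5
  },
  {
   "chi": [
    180,
    -105
   ],
   "p": 0.3
  },
  {
   "chi": [
    62,
    90
   ],
   "p": 0.2
  }
 ],
 "H": [
  {
   "chi": [
    -65,
    -70
   ],
   "p": 0.5
  },
  {
   "chi": [
    180,
    60
   ],
   "p": 0.3
  },
  {
   "chi": [
    62,
    80
   ],
   "p": 0.2
  }
 ],
 "D": [
  {
   "chi": [
    -70,
    -15
   ],
   "p": 0.5
  },
  {
   "chi": [
    180,
    15
   ],
   "p": 0.3
  },
  {
   "chi": [
    -170,
    40
   ],
   "p": 0.2
  }
 ],
 "N": [
  {
   "chi": [
    -70,
    -20
   ],
   "p": 0.5
  },
  {
   "chi": [
    180,
    30
   ],
   "p": 0.3
  },
  {
   "chi": [
    -170,
    40
   ],
   "p": 0.2
  }
 ],
 "P": [
  {
   "chi": [
    -25,
    35
   ],
   "p": 0.6
  },
  {
   "chi": [
    25,
    -30
   ],
   "p": 0.4
  }
 ],
 "M": [
  {
   "chi": [
    -65,
    180,
    -70
   ],
   "p": 0.4
  },
  {
   "chi": [
    -60,
    180,
    180
   ],
   "p": 0.35
  },
  {
   "chi": [
    180,
    180,
    75
   ],
   "p": 0.25
  }
 ],
 "E": [
  {
   "chi": [
    -65,
    180,
    -10
   ],
   "p": 0.4
  },
  {
   "chi": [
    -60,
    180,
    30
   ],
   "p": 0.35
  },
  {
   "chi": [
    180,
    180,
    0
   ],
   "p": 0.25
  }
 ],
 "Q": [
  {
   "chi": [
    -65,
    180,
    -25
   ],
   "p": 0.4
  },
  {
   "chi": [
    -60,
    180,
    60
   ],
   "p": 0.35
  },
  {
   "chi": [
    180,
    180,
    0
   ],
   "p": 0.25
  }
 ],
 "K": [
  {
   "chi": [
    -60,
    180,
    180,
    180
   ],
   "p": 0.5
  },
  {
   "chi": [
    180,
    180,
    180,
    180
   ],
   "p": 0.3
  },
  {
   "chi": [
    -60,
    180,
    -60,
    180
   ],
   "p": 0.2
  }
 ],
 "R": [
  {
   "chi": [
    -60,
    180,
    180,
    180
   ],
   "p": 0.5
  },
  {
   "chi": [
    180,
    180,
    180,
    180
   ],
   "p": 0.3
  },
  {
   "chi": [
    -60,
    180,
    -60,
    180
   ],
   "p": 0.2
  }
 ]
}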