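{
 "instrument": "RULA (Rapid Upper Limb Assessment)",
 "note": "Lookup tables transcribed from the published instrument. Table A maps (upper_arm, lower_arm, wrist, wrist_twist); Table B maps (neck, trunk, legs); Table C maps (score_c clipped to 8, score_d clipped to 7) to the grand score 1-7.",
 "table_a": [
  [
   [
    [
     1,
     2
    ],
    [
     2,
     2
    ],
    [
     2,
     3
    ],
    [
     3,
     3
    ]
   ],
   [
    [
     2,
     2
    ],
    [
     2,
     2
    ],
    [
     3,
     3
    ],
    [
     3,
     3
    ]
   ],
   [
    [
     2,
     3
    ],
    [
     3,
     3
    ],
    [
     3,
     3
    ],
    [
     4,
     4
    ]
   ]
  ],
  [
   [
    [
     2,
     3
    ],
    [
     3,
     3
    ],
    [
     3,
     4
    ],
    [
     4,
     4
    ]
   ],
   [
    [
     3,
     3
    ],
    [
     3,
     3
    ],
    [
     3,
     4
    ],
    [
     4,
     4
    ]
   ],
   [
    [
     3,
     4
    ],
    [
     4,
     4
    ],
    [
     4,
     4
    ],
    [
     5,
     5
    ]
   ]
  ],
  [
   [
    [
     3,
     3
    ],
    [
     4,
     4
    ],
    [
     4,
     4
    ],
    [
     5,
     5
    ]
   ],
   [
    [
     3,
     4
    ],
    [
     4,
     4
    ],
    [
     4,
     4
    ],
    [
     5,
     5
    ]
   ],
   [
    [
     4,
     4
    ],
    [
     4,
     4
    ],
    [
     4,
     5
    ],
    [
     5,
     5
    ]
   ]
  ],
  [
   [
    [
     4,
     4
    ],
    [
     4,
     4
    ],
    [
     4,
     5
    ],
    [
     5,
     5
    ]
   ],
   [
    [
     4,
     4
    ],
    [
     4,
     4
    ],
    [
     4,
     5
    ],
    [
     5,
     5
    ]
   ],
   [
    [
     4,
     4
    ],
    [
     4,
     5
    ],
    [
     5,
     5
    ],
    [
     6,
     6
    ]
   ]
  ],
  [
   [
    [
     5,
     5
    ],
    [
     5,
     5
    ],
    [
     5,
     6
    ],
    [
     6,
     7
    ]
   ],
   [
    [
     5,
     6
    ],
    [
     6,
     6
    ],
    [
     6,
     7
    ],
    [
     7,
     7
    ]
   ],
   [
    [
     6,
     6
    ],
    [
     6,
     7
    ],
    [
     7,
     7
    ],
    [
     7,
     8
    ]
   ]
  ],
  [
   [
    [
     7,
     7
    ],
    [
     7,
     7
    ],
    [
     7,
     8
    ],
    [
     8,
     9
    ]
   ],
   [
    [
     8,
     8
    ],
    [
     8,
     8
    ],
    [
     8,
     9
    ],
    [
     9,
     9
    ]
   ],
   [
    [
     9,
     9
    ],
    [
     9,
     9
    ],
    [
     9,
     9
    ],
    [
     9,
     9
    ]
   ]
  ]
 ],
 "table_b": [
  [
   [
    1,
    3
   ],
   [
    2,
    3
   ],
   [
    3,
    4
   ],
   [
    5,
    5
   ],
   [
    6,
    6
   ],
   [
    7,
    7
   ]
  ],
  [
   [
    2,
    3
   ],
   [
    2,
    3
   ],
   [
    4,
    5
   ],
   [
    5,
    5
   ],
   [
    6,
    7
   ],
   [
    7,
    7
   ]
  ],
  [
   [
    3,
    3
   ],
   [
    3,
    4
   ],
   [
    4,
    5
   ],
   [
    5,
    6
   ],
   [
    6,
    7
   ],
   [
    7,
    7
   ]
  ],
  [
   [
    5,
    5
   ],
   [
    5,
    6
   ],
   [
    6,
    7
   ],
   [
    7,
    7
   ],
   [
    7,
    7
   ],
   [
    8,
    8
   ]
  ],
  [
   [
    7,
    7
   ],
   [
    7,
    7
   ],
   [
    7,
    8
   ],
   [
    8,
    8
   ],
   [
    8,
    8
   ],
   [
    8,
    8
   ]
  ],
  [
   [
    8,
    8
   ],
   [
    8,
    8
   ],
   [
    8,
    8
   ],
   [
    8,
    9
   ],
   [
    9,
    9
   ],
   [
    9,
    9
   ]
  ]
 ],
 "table_c": [
  [
   1,
   2,
   3,
   3,
   4,
   5,
   5
  ],
  [
   2,
   2,
   3,
   4,
   4,
   5,
   5
  ],
  [
   3,
   3,
   3,
   4,
   4,
   5,
   6
  ],
  [
   3,
   3,
   3,
   4,
   5,
   6,
   6
  ],
  [
   4,
   4,
   4,
   5,
   6,
   7,
   7
  ],
  [
   4,
   4,
   5,
   6,
   6,
   7,
   7
  ],
  [
   5,
   5,
   6,
   6,
   7,
   7,
   7
  ],
  [
   5,
   5,
   6,
   7,
   7,
   7,
   7
  ]
 ]
}
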