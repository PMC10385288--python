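[
 {
  "name": "toy_pathway_01",
  "nodes": [
   "M04",
   "M05",
   "M13",
   "M20",
   "M23",
   "M30"
  ],
  "edges": [
   [
    "M30",
    "M23"
   ],
   [
    "M23",
    "M20"
   ],
   [
    "M20",
    "M04"
   ],
   [
    "M04",
    "M13"
   ],
   [
    "M13",
    "M05"
   ]
  ]
 },
 {
  "name": "toy_pathway_02",
  "nodes": [
   "M01",
   "M06",
   "M12",
   "M17",
   "M21",
   "M28"
  ],
  "edges": [
   [
    "M17",
    "M06"
   ],
   [
    "M06",
    "M21"
   ],
   [
    "M21",
    "M01"
   ],
   [
    "M01",
    "M12"
   ],
   [
    "M12",
    "M28"
   ]
  ]
 },
 {
  "name": "toy_pathway_03",
  "nodes": [
   "M02",
   "M08",
   "M10",
   "M15",
   "M16",
   "M22"
  ],
  "edges": [
   [
    "M08",
    "M22"
   ],
   [
    "M22",
    "M10"
   ],
   [
    "M10",
    "M16"
   ],
   [
    "M16",
    "M15"
   ],
   [
    "M15",
    "M02"
   ]
  ]
 },
 {
  "name": "toy_pathway_04",
  "nodes": [
   "M07",
   "M14",
   "M18",
   "M26",
   "M27",
   "M29"
  ],
  "edges": [
   [
    "M26",
    "M27"
   ],
   [
    "M27",
    "M07"
   ],
   [
    "M07",
    "M18"
   ],
   [
    "M18",
    "M29"
   ],
   [
    "M29",
    "M14"
   ]
  ]
 },
 {
  "name": "toy_pathway_05",
  "nodes": [
   "M03",
   "M09",
   "M11",
   "M19",
   "M24",
   "M25"
  ],
  "edges": [
   [
    "M25",
    "M11"
   ],
   [
    "M11",
    "M19"
   ],
   [
    "M19",
    "M24"
   ],
   [
    "M24",
    "M03"
   ],
   [
    "M03",
    "M09"
   ]
  ]
 }
]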