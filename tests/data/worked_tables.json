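{
 "cutoff": 1.1,
 "ica": {
  "GO:0000001": -0.0,
  "GO:0000002": 0.470004,
  "GO:0000003": 0.470004,
  "GO:0000004": 0.693147,
  "GO:0000005": 0.980829,
  "GO:0000006": 1.386294,
  "GO:0000007": 1.386294,
  "GO:0000008": 2.079442,
  "GO:0000009": 1.386294,
  "GO:0000010": 1.386294,
  "GO:0000011": 2.079442,
  "GO:0000012": 2.079442,
  "GO:0000013": 0.693147,
  "GO:0000014": 0.470004
 },
 "icm": {
  "GO:0000001": -0.0,
  "GO:0000002": 0.678072,
  "GO:0000003": 0.678072,
  "GO:0000004": 1.0,
  "GO:0000013": 1.0,
  "GO:0000014": 0.678072
 },
 "ics": {
  "GO:0000001|GO:0000001": 0.0,
  "GO:0000002|GO:0000002": 1.0,
  "GO:0000003|GO:0000003": 0.226024,
  "GO:0000003|GO:0000005": 0.471679,
  "GO:0000003|GO:0000006": 0.666667,
  "GO:0000003|GO:0000007": 0.666667,
  "GO:0000003|GO:0000008": 1.0,
  "GO:0000004|GO:0000004": 0.333333,
  "GO:0000004|GO:0000009": 0.666667,
  "GO:0000004|GO:0000010": 0.666667,
  "GO:0000004|GO:0000011": 1.0,
  "GO:0000004|GO:0000012": 1.0,
  "GO:0000013|GO:0000013": 1.0,
  "GO:0000014|GO:0000014": 1.0
 },
 "ict": {
  "GO:0000001": -0.0,
  "GO:0000002": 0.693147,
  "GO:0000003": 1.029619,
  "GO:0000004": 1.029619,
  "GO:0000005": 1.540445,
  "GO:0000006": 2.639057,
  "GO:0000007": 1.94591,
  "GO:0000008": 2.639057,
  "GO:0000009": 1.94591,
  "GO:0000010": 1.94591,
  "GO:0000011": 2.639057,
  "GO:0000012": 2.639057,
  "GO:0000013": 0.847298,
  "GO:0000014": 0.847298
 },
 "roots": [
  "GO:0000001",
  "GO:0000002",
  "GO:0000003",
  "GO:0000004",
  "GO:0000013",
  "GO:0000014"
 ]
}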