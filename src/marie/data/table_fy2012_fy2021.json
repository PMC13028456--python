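{
  "provenance": "FY2012-FY2021",
  "anchor_points": 35,
  "step_rate": "1/10",
  "anchor": {
    "More than 2,000,000": 80,
    "1,000,000 to 2,000,000": 160,
    "500,000 to 1,000,000": 200,
    "300,000 to 500,000": 200,
    "100,000 to 300,000": 310,
    "50,000 to 100,000": 930,
    "30,000 to 50,000": 1100,
    "10,000 to 30,000": 5000,
    "5000 to 10,000": 10100,
    "3000 to 5000": 10800,
    "1000 to 3000": 21200,
    "500 to 1000": 23100,
    "100 to 500": 43600,
    "10 to 100": 51200,
    "1 to 10": 92500
  }
}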