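{
  "provenance": "FY2015-FY2024",
  "anchor_points": 35,
  "step_rate": "1/10",
  "anchor": {
    "More than 2,000,000": 80,
    "1,000,000 to 2,000,000": 200,
    "500,000 to 1,000,000": 200,
    "300,000 to 500,000": 210,
    "100,000 to 300,000": 450,
    "50,000 to 100,000": 990,
    "30,000 to 50,000": 1200,
    "10,000 to 30,000": 5000,
    "5000 to 10,000": 8400,
    "3000 to 5000": 8500,
    "1000 to 3000": 23900,
    "500 to 1000": 28700,
    "100 to 500": 53900,
    "10 to 100": 51200,
    "1 to 10": 141100
  }
}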