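{
  "name": "Phar-A3D2R1",
  "max_omitted": 0,
  "canonical_geometry": false,
  "note": "Feature composition (3 HBA, 2 HBD, 1 AR) follows the published NEP inhibitor model; the 3-D geometry below is a documented approximation laid out to a plausible catalytic-pocket scale, not the original coordinates, which were never published numerically.",
  "features": [
    {"id": "A1", "kind": "HBA", "center": [0.0, 0.0, 0.0], "tolerance": 1.6, "weight": 1.0},
    {"id": "A2", "kind": "HBA", "center": [4.1, 1.2, -0.8], "tolerance": 1.6, "weight": 1.0},
    {"id": "A3", "kind": "HBA", "center": [6.9, -1.5, 1.1], "tolerance": 1.6, "weight": 1.0},
    {"id": "D1", "kind": "HBD", "center": [2.2, -2.9, 0.6], "tolerance": 1.6, "weight": 1.0},
    {"id": "D2", "kind": "HBD", "center": [5.3, 2.8, 1.9], "tolerance": 1.6, "weight": 1.0},
    {"id": "R1", "kind": "AR", "center": [3.0, 0.4, 2.7], "tolerance": 1.6, "weight": 1.0}
  ]
}
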