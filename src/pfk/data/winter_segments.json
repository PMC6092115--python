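{
  "name": "winter-sagittal-5-marker",
  "description": "Sagittal segmental model over five hemibody markers (fifth metatarsophalangeal joint, lateral malleolus, lateral knee joint center, greater trochanter, shoulder rotation axis). Bilateral limb segments carry count 2 under the symmetric-displacement assumption; HAT = head-arms-trunk. mass_fraction is the fraction of total body mass per segment instance; com_fraction is the segment COM position measured from the proximal marker toward the distal marker.",
  "segments": [
    {"name": "foot", "proximal_marker": "malleolus", "distal_marker": "meta5", "mass_fraction": 0.0145, "com_fraction": 0.5, "count": 2},
    {"name": "shank", "proximal_marker": "knee", "distal_marker": "malleolus", "mass_fraction": 0.0465, "com_fraction": 0.433, "count": 2},
    {"name": "thigh", "proximal_marker": "trochanter", "distal_marker": "knee", "mass_fraction": 0.1, "com_fraction": 0.433, "count": 2},
    {"name": "hat", "proximal_marker": "trochanter", "distal_marker": "shoulder", "mass_fraction": 0.678, "com_fraction": 0.626, "count": 1}
  ]
}
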