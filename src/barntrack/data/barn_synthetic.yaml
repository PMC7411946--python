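# Synthetic free-stall barn of the general geometry of a small research
# barn: 9.8 m across, usable alley span y = 3..42 m, feeding area at the
# near end, two cubicle sections in the middle, waiting yard and milking
# robot at the far end.  Stations sit on barn structures at 3-5 m height.
extents: {xmin: 0.0, xmax: 9.8, ymin: 3.0, ymax: 42.0}
resolution: 1.0
tag_height: 1.5
max_step: 3.0
stations:
  - {id: s00, x: 2.45, y: 5.0, z: 4.5}
  - {id: s01, x: 7.35, y: 5.0, z: 3.5}
  - {id: s02, x: 2.45, y: 13.0, z: 4.0}
  - {id: s03, x: 7.35, y: 13.0, z: 5.0}
  - {id: s04, x: 2.45, y: 22.0, z: 3.0}
  - {id: s05, x: 7.35, y: 22.0, z: 4.5}
  - {id: s06, x: 2.45, y: 31.0, z: 5.0}
  - {id: s07, x: 7.35, y: 31.0, z: 3.5}
  - {id: s08, x: 2.45, y: 39.0, z: 4.0}
  - {id: s09, x: 7.35, y: 39.0, z: 4.5}
obstacles:
  # feed fence separating the feeding alley, passage open at the right
  - {kind: wall, points: [[0.0, 9.5], [6.5, 9.5]]}
  # divider between the two cubicle sections, passage open at the left
  - {kind: wall, points: [[3.3, 19.5], [9.8, 19.5]]}
  # fence in front of the waiting yard, passage open at the right
  - {kind: wall, points: [[0.0, 31.5], [5.5, 31.5]]}
  # milking-robot enclosure walls (entrance from the waiting yard side)
  - {kind: wall, points: [[6.5, 36.5], [9.8, 36.5]]}
  - {kind: wall, points: [[6.5, 36.5], [6.5, 40.0]]}
zones:
  - {label: feeding, polygon: [[0.0, 3.0], [9.8, 3.0], [9.8, 9.4], [0.0, 9.4]]}
  - {label: cubicles, polygon: [[0.0, 9.6], [9.8, 9.6], [9.8, 28.0], [0.0, 28.0]]}
  - {label: waiting_yard, polygon: [[1.0, 32.0], [5.0, 32.0], [5.0, 37.0], [1.0, 37.0]]}
  - {label: robot, polygon: [[6.6, 36.6], [9.8, 36.6], [9.8, 42.0], [6.6, 42.0]]}
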