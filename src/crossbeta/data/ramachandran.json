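{
  "_comment": "Coarse polygonal approximations of published Ramachandran contour levels (general / glycine / proline; favored and allowed). Vertices are [phi, psi] in degrees. Allowed polygons are supersets of favored ones; glycine contours are near mirror-symmetric and admit the positive-psi bridge that is an outlier for non-glycine residues.",
  "general": {
    "favored": [
      [[-180, 180], [-45, 180], [-45, 160], [-60, 140], [-90, 115], [-140, 100], [-180, 110]],
      [[-155, -60], [-55, -60], [-50, -40], [-60, 0], [-100, 20], [-155, -20]],
      [[40, 20], [80, 20], [80, 80], [40, 80]]
    ],
    "allowed": [
      [[-180, 180], [-40, 180], [-40, 145], [-55, 135], [-90, 120], [-140, 90], [-180, 85]],
      [[-180, -180], [-45, -180], [-45, -160], [-180, -150]],
      [[-180, 35], [-110, 45], [-55, 10], [-45, -40], [-55, -75], [-180, -75]],
      [[30, -10], [90, -10], [90, 100], [30, 100]]
    ]
  },
  "glycine": {
    "favored": [
      [[-180, 180], [-45, 180], [-45, 100], [-180, 100]],
      [[45, -100], [180, -100], [180, -180], [45, -180]],
      [[-110, -60], [-45, -60], [-45, 0], [-110, 0]],
      [[45, 0], [110, 0], [110, 60], [45, 60]]
    ],
    "allowed": [
      [[-180, 180], [-35, 180], [-35, 45], [-180, 45]],
      [[35, -45], [180, -45], [180, -180], [35, -180]],
      [[35, 100], [180, 100], [180, 180], [35, 180]],
      [[-180, -100], [-35, -100], [-35, -180], [-180, -180]],
      [[-180, 30], [-35, 30], [-35, -110], [-180, -110]],
      [[35, 110], [130, 110], [130, -50], [35, -50]]
    ]
  },
  "proline": {
    "favored": [
      [[-95, 180], [-50, 180], [-50, 100], [-95, 100]],
      [[-95, -10], [-50, -10], [-50, -70], [-95, -70]]
    ],
    "allowed": [
      [[-110, 180], [-40, 180], [-40, 85], [-110, 85]],
      [[-110, 10], [-40, 10], [-40, -80], [-110, -80]],
      [[-110, -160], [-40, -160], [-40, -180], [-110, -180]]
    ]
  }
}
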