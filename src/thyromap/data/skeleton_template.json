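{
  "version": "1.0",
  "description": "Cartilage skeleton landmark template in canonical mm coordinates. Front view: X mediolateral (+X toward the animal's left lobe), Y craniocaudal (+Y cranial, origin at the junction of the thyroid-cartilage upper border and the anterior middle ridge). Section view: X mediolateral, Z anteroposterior (+Z dorsal, origin at the anterior tangent point of the cricoid ring). Only the 0.9 mm lateral-fossa offset and the axis incidences are normative; outline shapes are illustrative, digitized to be proportion-consistent with an adult mouse larynx.",
  "front_landmarks": {
    "upper_border_1": [-1.5, 0.0],
    "upper_border_2": [1.5, 0.0],
    "midline_1": [0.0, 0.0],
    "midline_2": [0.0, -3.0],
    "lateral_fossa_L": [0.9, -1.6],
    "lateral_fossa_R": [-0.9, -1.6]
  },
  "section_landmarks": {
    "lamina_1": [-0.9, 1.8],
    "lamina_2": [0.9, 1.8],
    "anterior_tangent": [0.0, 0.0]
  },
  "front_outlines": {
    "thyroid_cartilage": [
      [-1.5, 0.0], [-1.6, -0.5], [-1.4, -1.1], [-0.9, -1.6], [-0.4, -1.9],
      [0.0, -2.0], [0.4, -1.9], [0.9, -1.6], [1.4, -1.1], [1.6, -0.5],
      [1.5, 0.0], [0.8, -0.2], [0.0, -0.3], [-0.8, -0.2], [-1.5, 0.0]
    ],
    "cricoid_ring_front": [
      [-1.0, -2.1], [-1.05, -2.5], [-1.0, -2.9], [1.0, -2.9], [1.05, -2.5],
      [1.0, -2.1], [-1.0, -2.1]
    ]
  },
  "section_outlines": {
    "cricoid_ring": [
      [0.0, 0.0], [0.5, 0.1], [0.9, 0.45], [1.05, 0.9], [1.0, 1.4],
      [0.9, 1.8], [0.0, 1.95], [-0.9, 1.8], [-1.0, 1.4], [-1.05, 0.9],
      [-0.9, 0.45], [-0.5, 0.1], [0.0, 0.0]
    ]
  }
}
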