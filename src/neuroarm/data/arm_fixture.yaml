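# Default 2-link, 6-muscle planar arm fixture (synthetic parameter set).
#
# This is the package's own stand-in musculoskeletal parameterization: segment
# lengths follow common anthropometric tables for an adult arm; masses and
# inertias sit at the heavy end of those tables so that the arm's endpoint
# inertia (about 2.7-4.3 kg across directions at the start posture) brackets
# the 3 kg point mass of the high-level internal model -- the hierarchy
# presumes the brain's abstraction is calibrated to the body it controls.
# The six
# straight-line muscle paths were placed to give physiological moment arms
# (roughly 2-4 cm) with correct agonist/antagonist signs over the workspace
# used by the bundled reaching scenarios (q1 in [15, 85] deg, q2 in [60, 135]
# deg). All values are overridable; nothing downstream depends on the exact
# numbers, only on their qualitative structure.
#
# Units: m, kg, kg m^2, s.  Frames: torso points are relative to the shoulder
# in the world frame; upper-arm points are in the upper-arm frame (origin at
# the shoulder, x along the segment); forearm points are in the forearm frame
# (origin at the elbow, x along the segment).
#
# l0: auto  ->  optimal fiber length = path length at reference_posture.

arm:
  l1: 0.30
  l2: 0.33
  m1: 3.0
  m2: 2.5
  d1: 0.15
  d2: 0.26
  I1: 0.080
  I2: 0.130
  shoulder: [0.0, 0.0]

# hand 0.40 m anterior of the shoulder, counterclockwise (flexed) elbow
reference_posture: [0.6284809774047355, 1.768547312495882]

muscles:
  - name: shoulder_flexor
    origin_segment: torso
    origin: [-0.0340, 0.0295]
    insertion_segment: upper
    insertion: [0.14, 0.0]
    l0: auto
    fmax: 800.0
  - name: shoulder_extensor
    origin_segment: torso
    origin: [0.0340, -0.0295]
    insertion_segment: upper
    insertion: [0.14, 0.0]
    l0: auto
    fmax: 800.0
  - name: elbow_flexor
    origin_segment: upper
    origin: [0.255, 0.0]
    insertion_segment: fore
    insertion: [0.045, 0.0]
    l0: auto
    fmax: 700.0
  - name: elbow_extensor
    origin_segment: upper
    origin: [0.19, -0.02]
    insertion_segment: fore
    insertion: [-0.035, -0.012]
    l0: auto
    fmax: 700.0
  - name: biarticular_flexor
    origin_segment: torso
    origin: [-0.0176, 0.0243]
    insertion_segment: fore
    insertion: [0.05, 0.0]
    l0: auto
    fmax: 600.0
  - name: biarticular_extensor
    origin_segment: torso
    origin: [0.0176, -0.0243]
    insertion_segment: fore
    insertion: [-0.035, -0.012]
    l0: auto
    fmax: 600.0
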