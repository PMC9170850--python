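blood_spheres:
- center:
  - 61.0
  - 104.0
  - 36.0
  radius_mm: 8.0
- center:
  - 61.0
  - 104.0
  - 54.0
  radius_mm: 8.0
centerline: ph/centerline.json
ct: ph/ct.nii.gz
exclusion:
  points:
  - - 97.0
    - 63.0
    - 6.0
  - - 97.0
    - 63.0
    - 154.0
  radius_mm: 19.0
methods:
- tbr
- ama
options:
  threshold: true
  variable_radius: true
pet: ph/pet.nii.gz
subject: phantom-01
threshold_spheres:
  aneurysm:
    center:
    - 42.5
    - 63.0
    - 120.0
    radius_mm: 4.0
  neck:
    center:
    - 50.804704447321654
    - 63.0
    - 80.0
    radius_mm: 4.0
  suprarenal:
    center:
    - 52.4078010034612
    - 63.0
    - 55.0
    radius_mm: 4.0
  thoracic:
    center:
    - 52.49955077650483
    - 63.0
    - 25.0
    radius_mm: 4.0
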