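# Default ten-trait schema for Mediterranean benthic species.
# Nominal categories are coded with lowercase letters, ordinal with "1".."5"
# (the listed order is the rank order).
traits:
  - code: A
    name: feeding
    kind: nominal
    categories: [a, b, c, d, e, f, g]
    category_labels:
      - autotroph (no feeding)
      - active filter feeder with cilia
      - active filter feeder by pumping
      - passive filter feeder
      - herbivore / grazer
      - carnivore
      - detritivore
  - code: B
    name: maximum_longevity
    kind: ordinal
    categories: ["1", "2", "3", "4", "5"]
    category_labels:
      - "<1-1 year"
      - "2-5 years"
      - "5-10 years"
      - "10-20 years"
      - ">=20 years"
  - code: C
    name: coloniality
    kind: nominal
    categories: ["1", "2"]
    category_labels:
      - solitary
      - colonial / modular / gregarious
  - code: D
    name: morphological_form
    kind: nominal
    categories: [a, b, c, d, e, f, g, h, i, j, k, l]
    category_labels:
      - boring
      - encrusting
      - filamentous
      - stolonial
      - foliose-erect
      - articulated
      - coarse branched
      - cup-like
      - massive encrusting
      - massive hemispheric
      - massive-erect
      - tree-like
  - code: E
    name: carbon_storage
    kind: nominal
    categories: [a, b, c]
    category_labels: ["yes", "potentially", "no"]
  - code: F
    name: energetic_resource
    kind: nominal
    categories: [a, b, c]
    category_labels:
      - photosynthetic autotroph
      - photo-heterotroph
      - heterotroph
  - code: G
    name: height
    kind: ordinal
    categories: ["1", "2", "3", "4", "5"]
    category_labels:
      - "very small (<2 cm)"
      - "small (2-5 cm)"
      - "medium (5-20 cm)"
      - "large (20-50 cm)"
      - "very large (>50 cm)"
  - code: H
    name: growth_rate
    kind: ordinal
    categories: ["1", "2", "3", "4", "5"]
    category_labels:
      - "extreme slow (<1 cm/yr)"
      - "slow (ca. 1 cm/yr)"
      - "moderate (1-5 cm/yr)"
      - "high (5-10 cm/yr)"
      - "very high (>10 cm/yr)"
  - code: I
    name: calcification
    kind: nominal
    categories: [a, b]
    category_labels:
      - without calcareous structures
      - with calcareous structures
  - code: J
    name: motility
    kind: nominal
    categories: [a, b]
    category_labels: [sessile, vagile]
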