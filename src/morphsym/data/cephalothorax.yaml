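# Dorsal cephalothorax landmark map: 33 landmarks = 15 bilateral pairs
# + 3 midline landmarks on the axis of bilateral symmetry.
# Indices are 1-based.  Pair labels are "left-right" (left side carries the
# higher index); landmark 1 is the anterior midline point anchoring the
# left-right triangle construction.
landmarks: 33
pairs:
  - [28, 2]   # orbital sinuses
  - [27, 3]
  - [26, 4]   # tips of the anterolateral spines
  - [25, 5]   # hepatic lobules 1
  - [24, 6]
  - [23, 7]   # tips of hepatic lobe 2
  - [22, 8]   # tips of hepatic lobe 3
  - [21, 9]
  - [20, 10]  # tips of the epibranchial spines
  - [19, 11]
  - [18, 12]  # branchial line x linea aeglica lateralis
  - [17, 13]  # distal extremes of the branchial area
  - [16, 14]
  - [31, 29]  # inflections of the cervical groove
  - [32, 30]
midline: [1, 15, 33]
axis_reference: 1
# anterior-to-posterior pair order (positions into the pairs list above)
longitudinal_order: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]

# Modularity hypotheses.  "developmental" splits the cephalothorax at the
# cervical groove (cephalic vs thoracic); "gonadic" isolates the landmarks
# over the female reproductive space; "agonistic" isolates the frontal and
# lateral spiny processes; the anatomical models subdivide by the map of
# dorsal lines.
partitions:
  uniform:
    all: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17,
          18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33]
  developmental:
    cephalic: [1, 2, 3, 4, 5, 6, 7, 8, 22, 23, 24, 25, 26, 27, 28]
    thoracic: [9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21,
               29, 30, 31, 32, 33]
  gonadic:
    gonadic: [13, 14, 15, 16, 17, 29, 30, 31, 32, 33]
    other: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12,
            18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28]
  agonistic:
    agonistic: [1, 2, 3, 4, 10, 20, 26, 27, 28]
    other: [5, 6, 7, 8, 9, 11, 12, 13, 14, 15, 16, 17, 18, 19,
            21, 22, 23, 24, 25, 29, 30, 31, 32, 33]
  anatomical-I:
    cephalic: [1, 2, 3, 4, 5, 6, 7, 8, 22, 23, 24, 25, 26, 27, 28]
    branchial: [11, 12, 13, 17, 18, 19]
    cardiac: [9, 10, 14, 15, 16, 20, 21, 29, 30, 31, 32, 33]
  anatomical-II:
    frontal: [1, 2, 3, 4, 26, 27, 28]
    hepatic: [5, 6, 7, 8, 22, 23, 24, 25]
    posterior: [9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21,
                29, 30, 31, 32, 33]
  anatomical-III:
    cephalic: [1, 2, 3, 4, 5, 6, 7, 8, 22, 23, 24, 25, 26, 27, 28]
    anterothoracic: [9, 10, 11, 12, 18, 19, 20, 21, 29, 31]
    posterothoracic: [13, 14, 15, 16, 17, 30, 32, 33]
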